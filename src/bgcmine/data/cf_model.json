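{
 "emissions": {
  "background": {
   "A": 0.0016216216216216215,
   "ABC_tran": 0.11,
   "ACP": 0.0016216216216216215,
   "APE_KS": 0.0016216216216216215,
   "AT": 0.0016216216216216215,
   "ATd": 0.0016216216216216215,
   "Bacteriocin": 0.0016216216216216215,
   "Branching": 0.0016216216216216215,
   "C": 0.0016216216216216215,
   "CAL": 0.0016216216216216215,
   "CHS": 0.0016216216216216215,
   "Crotonase": 0.0016216216216216215,
   "DH": 0.0016216216216216215,
   "DarB": 0.0016216216216216215,
   "E": 0.0016216216216216215,
   "ER": 0.0016216216216216215,
   "EctC": 0.0016216216216216215,
   "FabF": 0.0016216216216216215,
   "FabH": 0.0016216216216216215,
   "GGDEF": 0.11,
   "Glycos_transf": 0.0016216216216216215,
   "HTH_reg": 0.11,
   "KR": 0.0016216216216216215,
   "KS": 0.0016216216216216215,
   "Ladderane": 0.0016216216216216215,
   "LanB": 0.0016216216216216215,
   "LanC": 0.0016216216216216215,
   "LanM": 0.0016216216216216215,
   "MFS_1": 0.11,
   "MT": 0.0016216216216216215,
   "P450": 0.0016216216216216215,
   "PCP": 0.0016216216216216215,
   "PUFA_KS": 0.0016216216216216215,
   "PyranSynthase": 0.0016216216216216215,
   "Siderophore": 0.0016216216216216215,
   "Sugar_epim": 0.0016216216216216215,
   "TD": 0.0016216216216216215,
   "TE": 0.0016216216216216215,
   "Terpene": 0.0016216216216216215,
   "UNKNOWN": 0.5,
   "t2clf": 0.0016216216216216215,
   "t2ks": 0.0016216216216216215
  },
  "bgc": {
   "A": 0.024324324324324326,
   "ABC_tran": 0.005,
   "ACP": 0.024324324324324326,
   "APE_KS": 0.024324324324324326,
   "AT": 0.024324324324324326,
   "ATd": 0.024324324324324326,
   "Bacteriocin": 0.024324324324324326,
   "Branching": 0.024324324324324326,
   "C": 0.024324324324324326,
   "CAL": 0.024324324324324326,
   "CHS": 0.024324324324324326,
   "Crotonase": 0.024324324324324326,
   "DH": 0.024324324324324326,
   "DarB": 0.024324324324324326,
   "E": 0.024324324324324326,
   "ER": 0.024324324324324326,
   "EctC": 0.024324324324324326,
   "FabF": 0.024324324324324326,
   "FabH": 0.024324324324324326,
   "GGDEF": 0.005,
   "Glycos_transf": 0.024324324324324326,
   "HTH_reg": 0.005,
   "KR": 0.024324324324324326,
   "KS": 0.024324324324324326,
   "Ladderane": 0.024324324324324326,
   "LanB": 0.024324324324324326,
   "LanC": 0.024324324324324326,
   "LanM": 0.024324324324324326,
   "MFS_1": 0.005,
   "MT": 0.024324324324324326,
   "P450": 0.024324324324324326,
   "PCP": 0.024324324324324326,
   "PUFA_KS": 0.024324324324324326,
   "PyranSynthase": 0.024324324324324326,
   "Siderophore": 0.024324324324324326,
   "Sugar_epim": 0.024324324324324326,
   "TD": 0.024324324324324326,
   "TE": 0.024324324324324326,
   "Terpene": 0.024324324324324326,
   "UNKNOWN": 0.08000000000000063,
   "t2clf": 0.024324324324324326,
   "t2ks": 0.024324324324324326
  }
 },
 "initial": [
  0.2,
  0.8
 ],
 "states": [
  "bgc",
  "background"
 ],
 "transitions": [
  [
   0.9,
   0.1
  ],
  [
   0.05,
   0.95
  ]
 ]
}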