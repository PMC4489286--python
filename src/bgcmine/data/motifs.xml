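<?xml version="1.0" encoding="UTF-8"?>
<!-- Default active-site and key-residue motifs over the bundled toy
     profiles. Positions are 1-based consensus columns of the target
     profile. Patterns are editable data, not hard-coded truths; the
     residue choices echo the usual literature assignments (catalytic
     Cys of ketosynthases, GHSxG Ser of acyltransferases, the LDD region
     read for ketoreductase D-/L- stereochemistry, the tyrosine read for
     enoylreductase 2S/2R, the tryptophan read for beta-branching carrier
     proteins). -->
<motifs version="1.0">
  <motif id="KS_active_site" target="KS" annotation_key="active_site"
         required="true">
    <description>ketosynthase catalytic cysteine</description>
    <positions>7</positions>
    <pattern>C</pattern>
  </motif>
  <motif id="AT_active_site" target="AT" annotation_key="active_site"
         required="true">
    <description>acyltransferase catalytic serine (GHSxG)</description>
    <positions>8,9,10,12</positions>
    <pattern>GHS[GE]</pattern>
  </motif>
  <motif id="DH_active_site" target="DH" annotation_key="active_site"
         required="true">
    <description>dehydratase catalytic histidine</description>
    <positions>3</positions>
    <pattern>H</pattern>
  </motif>
  <motif id="KR_active_site" target="KR" annotation_key="active_site"
         required="true">
    <description>ketoreductase catalytic tyrosine</description>
    <positions>8</positions>
    <pattern>Y</pattern>
  </motif>
  <motif id="ACP_active_site" target="ACP" annotation_key="active_site">
    <description>acyl carrier protein phosphopantetheine serine</description>
    <positions>4,5,6</positions>
    <pattern>DS[LIV]</pattern>
  </motif>
  <motif id="TE_active_site" target="TE" annotation_key="active_site">
    <description>thioesterase catalytic serine</description>
    <positions>3</positions>
    <pattern>S</pattern>
  </motif>
  <motif id="P450_active_site" target="P450" annotation_key="active_site">
    <description>cytochrome P450 heme-ligating cysteine</description>
    <positions>8</positions>
    <pattern>C</pattern>
  </motif>
  <motif id="ACP_branching" target="ACP" annotation_key="prediction">
    <description>acyl carrier protein beta-branching type</description>
    <positions>11</positions>
    <outcomes>
      <outcome pattern="^W$" label="beta-branching"/>
      <outcome pattern=".*" label="non-branching"/>
    </outcomes>
  </motif>
  <motif id="KR_stereochemistry" target="KR" annotation_key="prediction">
    <description>ketoreductase product stereochemistry</description>
    <positions>12,13,14,15</positions>
    <outcomes>
      <outcome pattern="^LDD" label="B-type (D-configured)"/>
      <outcome pattern=".*" label="A-type (L-configured)"/>
    </outcomes>
  </motif>
  <motif id="ER_stereochemistry" target="ER" annotation_key="prediction">
    <description>enoylreductase methyl-branch stereochemistry</description>
    <positions>13</positions>
    <outcomes>
      <outcome pattern="^Y$" label="2S"/>
      <outcome pattern=".*" label="2R"/>
    </outcomes>
  </motif>
  <motif id="AT_specificity" target="AT" annotation_key="prediction">
    <description>acyltransferase extender unit choice</description>
    <positions>17,18,19,20</positions>
    <outcomes>
      <outcome pattern="^HAFH$" label="mal"/>
      <outcome pattern="^YASH$" label="mmal"/>
    </outcomes>
  </motif>
</motifs>
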