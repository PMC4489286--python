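"""Bundled data: toy profile set, default rules, motifs, models, tables.

The toy profiles are deterministic stand-ins for a production profile
collection (which is payload, not part of the engine): each domain family
gets a strong consensus, optionally with designated low-information
"variable" columns where product-determining residues are read (adenylation
pocket code, acyltransferase extender choice, ketoreductase/enoylreductase
stereochemistry, acyl-carrier branching).  The structural profiles carry
consensus strings echoing the family's textbook motif (DTACSSS for
ketosynthases, GHSLGE for acyltransferases, GxDSL for carrier proteins,
SGTTGKPKG for adenylation domains, ...); the remaining families use seeded
random consensus, which keeps the shipped payload tiny while exercising the
same code paths.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Optional

import numpy as np

from ..hmm import ProfileModel
from ..records import AMINO_ACIDS

#: handcrafted consensus strings; value = (consensus, variable 1-based cols)
_STRUCTURED = {
    "KS": ("GPIDTACSSSLVAVHLA", ()),            # catalytic C at column 7
    # variable columns are flanked by strong anchors so local alignment
    # never trims them off the envelope
    "AT": ("QPVLFAVGHSLGEYAAVVVVW", (17, 18, 19, 20)),  # S col 10; code 17-20
    "DH": ("TPHLVLLDRA", ()),                   # catalytic H at column 3
    "KR": ("GGTGALGYEVAVVVVW", (12, 13, 14, 15)),  # Y col 8; stereo 12-15
    "ER": ("AAAGGVGMAAVQVW", (13,)),            # stereo residue col 13
    "ACP": ("LGLDSLTAVEVW", (11,)),             # S col 5; branching col 11
    "TE": ("GYSAGGALAY", ()),                   # catalytic S at column 3
    "P450": ("FGHGAHQCLG", ()),                 # heme-ligating C at column 8
    "C": ("HHLISDGVSW", ()),                    # HHxxxDG core
    "A": ("SGTTGKPKGVVVVVVVVDLAV", tuple(range(10, 18))),  # code cols 10-17
    "PCP": ("DFFELGGHSL", ()),
    "CAL": ("MLDAYGMTET", ()),
    "TD": ("NPNPWLRAAV", ()),
    "ATd": ("WLDRLEAQVR", ()),
}

#: remaining families get deterministic pseudo-random consensus of this length
_GENERATED = (
    "MT", "E", "Branching", "Crotonase", "PyranSynthase",
    "Terpene", "LanB", "LanC", "LanM", "Bacteriocin", "Siderophore",
    "EctC", "APE_KS", "DarB", "Ladderane", "PUFA_KS",
    "t2ks", "t2clf", "CHS",
    "Glycos_transf", "Sugar_epim", "FabH", "FabF",
    "ABC_tran", "MFS_1", "GGDEF", "HTH_reg",
)

_GENERATED_LENGTH = 12

#: smCOG-style family labels for the bundled family profiles
FAMILY_LABELS = {
    "MT": "SAM-dependent methyltransferase",
    "P450": "cytochrome P450 oxygenase",
    "ABC_tran": "ABC transporter ATP-binding protein",
    "MFS_1": "major facilitator superfamily transporter",
    "Glycos_transf": "glycosyltransferase",
}

#: profile names whose presence marks a gene as core biosynthetic
CORE_PROFILE_NAMES = frozenset({"KS", "C", "A"})

#: maps toy profile names to canonical assembly-line domain names (identity)
DOMAIN_NAME_MAP = {name: name for name in _STRUCTURED}


def _seeded_consensus(name: str, length: int) -> str:
    digest = hashlib.sha256(f"bgcmine-toy-{name}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "big"))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def build_toy_profile(name: str, consensus: str,
                      variable_cols: tuple = (),
                      cutoff_bits: float = 20.0,
                      consensus_weight: float = 0.9) -> ProfileModel:
    """A strong-consensus profile with flat emissions at variable columns."""
    length = len(consensus)
    match = np.full((length, 20), (1 - consensus_weight) / 19)
    for c, aa in enumerate(consensus):
        match[c, AMINO_ACIDS.index(aa)] = consensus_weight
    for col in variable_cols:
        match[col - 1] = 1 / 20
    insert = np.full((length, 20), 1 / 20)
    transitions = np.tile(
        np.array([0.95, 0.025, 0.025, 0.5, 0.5, 0.5, 0.5]), (length, 1))
    null = np.full(20, 1 / 20)
    return ProfileModel(name, length, match, insert, transitions, null,
                        cutoff_bits)


_CACHE: Optional[dict] = None


def toy_profiles() -> dict:
    """The full bundled profile set, name -> ProfileModel (cached)."""
    global _CACHE
    if _CACHE is None:
        profiles = {}
        for name, (consensus, variable) in _STRUCTURED.items():
            profiles[name] = build_toy_profile(name, consensus, variable)
        for name in _GENERATED:
            profiles[name] = build_toy_profile(
                name, _seeded_consensus(name, _GENERATED_LENGTH))
        _CACHE = profiles
    return dict(_CACHE)


def family_profiles() -> list:
    """Profiles participating in smCOG-style family assignment."""
    profiles = toy_profiles()
    return [profiles[name] for name in sorted(FAMILY_LABELS)]


def data_path(filename: str):
    """importlib.resources path for a bundled data file."""
    return resources.files("bgcmine.data") / filename


def default_rules_path():
    return data_path("cluster_rules.txt")


def default_cf_model_path():
    return data_path("cf_model.json")


def default_motifs_path():
    return data_path("motifs.xml")
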