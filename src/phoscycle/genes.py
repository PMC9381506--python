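"""Gene registry for the phosphonate-cycling survey.

Fourteen phosphonate-cycling gene families are screened: five for
biosynthesis (pepM is the universal entry point, forming the C-P bond),
six for substrate-specific catabolism (mostly of 2-aminoethylphosphonate,
2-AEP), and three marker subunits of the broad-specificity C-P lyase
operon.  Five conserved single-copy housekeeping genes serve as the
community-size proxy for relative-abundance normalization.
"""

from __future__ import annotations

PRODUCTION_GENES: tuple[str, ...] = ("pepM", "aepY", "phpC", "mpnS", "hepD")
SUBSTRATE_CATABOLISM_GENES: tuple[str, ...] = (
    "palA",
    "phnA",
    "phnW",
    "phnX",
    "phnY",
    "phnZ",
)
CP_LYASE_GENES: tuple[str, ...] = ("phnI", "phnJ", "phnM")

PHOSPHONATE_GENES: tuple[str, ...] = (
    PRODUCTION_GENES + SUBSTRATE_CATABOLISM_GENES + CP_LYASE_GENES
)

MARKER_GENES: tuple[str, ...] = ("recA", "atpD", "tufA", "gyrB", "hsp70")

ALL_GENES: tuple[str, ...] = PHOSPHONATE_GENES + MARKER_GENES

#: Minimum percent identity for a translated-search hit to count, per gene.
#: Chosen per family to give a reliable homology cut-off on short reads.
DEFAULT_MIN_IDENTITY_PCT: dict[str, float] = {
    "pepM": 50.0,
    "aepY": 50.0,
    "phnA": 50.0,
    "phnW": 50.0,
    "phnX": 50.0,
    "phnZ": 50.0,
    "phnI": 50.0,
    "phnM": 55.0,
    "phpC": 60.0,
    "mpnS": 60.0,
    "hepD": 60.0,
    "palA": 60.0,
    "phnJ": 60.0,
    "phnY": 65.0,
}

#: Minimum alignment length (aa) by sequencing read length (bp):
#: 100 bp reads translate to ~33 aa, 125 bp to ~41 aa.
MIN_ALN_LENGTH_BY_READ_LENGTH: dict[int, int] = {100: 32, 125: 40}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

TAXONOMY_RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
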