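"""Shared constants for the eight-library early-development profiling design.

The study design this package models is a multiplexed 454 run over seven
early developmental stages of the abalone *Haliotis diversicolor* (two-cell
through postlarva) plus one adult intestine library. Stage labels, default
per-library sequencing depths (non-redundant reads, the normalization
denominator) and default multiplex identifier (MID) barcodes live here so
every module agrees on axis order.
"""

from __future__ import annotations

# Stage order: seven early developmental stages, then the adult tissue library.
EARLY_STAGES: tuple[str, ...] = (
    "2CELL",   # two-cell embryo, 0.5 hpf
    "MORU",    # morula, 3.2 hpf
    "TROC",    # trochophore, 9.5 hpf (hatching, free swimming begins)
    "19VEL",   # 19 hpf veliger
    "58VEL",   # 58 hpf veliger
    "74VEL",   # 74 hpf late competent veliger
    "144PL",   # postlarva, 144 hpf (benthic, 3 days post settlement)
)
ADULT_STAGE = "INTE"  # adult intestine, reference-library tissue
ALL_STAGES: tuple[str, ...] = EARLY_STAGES + (ADULT_STAGE,)

# Default per-library depths: non-redundant read counts of the eight
# libraries in the study design being emulated.
DEFAULT_LIBRARY_DEPTHS: dict[str, int] = {
    "2CELL": 38_923,
    "MORU": 33_423,
    "TROC": 41_160,
    "19VEL": 30_296,
    "58VEL": 22_441,
    "74VEL": 14_853,
    "144PL": 67_916,
    "INTE": 58_026,
}

# Standard Roche RL-MID barcodes 1-8; any distinct set may be supplied instead.
DEFAULT_MIDS: dict[str, str] = {
    "2CELL": "ACGAGTGCGT",
    "MORU": "ACGCTCGACA",
    "TROC": "AGACGCACTC",
    "19VEL": "AGCACTGTAG",
    "58VEL": "ATCAGACACG",
    "74VEL": "ATATCGCGAG",
    "144PL": "CGTGTCTCTA",
    "INTE": "CTCGCGTGTC",
}

# Amplification-primer fragment (ending in the 454 TCAG key) used as the
# synthetic adaptor between the MID and the cDNA insert. Long enough that
# chance interior occurrences, which the cleaner treats as 3' read-through,
# are negligible.
DEFAULT_ADAPTOR = "GCCTCCCTCGCGCCATCAG"

# Dixon Q-test (r10 statistic) critical values for n = 7, from the standard
# Dean-Dixon tables; confidence level -> critical value.
DIXON_CRITICAL_N7: dict[int, float] = {90: 0.507, 95: 0.568, 99: 0.680}

# Internal control genes (stably expressed reference genes) of the design.
DEFAULT_ICGS: tuple[str, ...] = ("YB1", "OAZ1")


class ParameterError(ValueError):
    """A function argument is outside its admissible domain."""


class ConfigError(ValueError):
    """A configuration is internally inconsistent (e.g. duplicate MIDs)."""


class ConsistencyError(ValueError):
    """Two inputs that must align (axes, read ids) do not."""


class ParseError(ValueError):
    """An input record could not be parsed; carries the offending line number."""
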