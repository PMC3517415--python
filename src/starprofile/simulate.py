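"""Synthetic data generator for the eight-library developmental profiling design.

Everything downstream of the sequencer is testable against ground truth
produced here: a reference transcript set, per-gene expression programs drawn
from developmental archetypes, multinomial read counts at realistic library
depths, MID-decorated read pools with duplicates and substitution errors, and
noisy qPCR panels.

Archetypes
----------
``maternal_decay``
    Maternally deposited transcripts: highest at the two-cell stage, dropping
    steeply by the morula (configured fold, default 40-80x) and decaying
    thereafter.
``trochophore_spike``
    Transcripts specific to the hatching trochophore; the trochophore level
    exceeds every other stage by at least the configured floor (default 30x).
``postlarval_rise``
    Benthic/juvenile program transcripts peaking in the postlarva, at least
    the configured floor (default 25x) over any earlier stage. With
    ``benthic_shift`` enabled the late competent veliger already carries a
    substantial share of this program (anticipatory development).
``housekeeping``
    Stably expressed genes; max/min ratio across the seven early stages is
    kept within 1.5.
``background``
    Low, unstructured expression. Background genes also absorb per-library
    column-total differences so that the configured archetype fold ratios
    survive the per-library normalization of abundances exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import (
    ALL_STAGES,
    DEFAULT_ADAPTOR,
    DEFAULT_ICGS,
    DEFAULT_LIBRARY_DEPTHS,
    DEFAULT_MIDS,
    EARLY_STAGES,
    ConfigError,
    ConsistencyError,
    ParameterError,
)

_BASES = np.array(list("ACGT"))

ARCHETYPES = (
    "maternal_decay",
    "trochophore_spike",
    "postlarval_rise",
    "housekeeping",
    "background",
)

DEFAULT_ARCHETYPE_PROPORTIONS = {
    "maternal_decay": 0.08,
    "trochophore_spike": 0.08,
    "postlarval_rise": 0.08,
    "housekeeping": 0.16,
    "background": 0.60,
}

# (low, high) fold-magnitude ranges per archetype. For housekeeping the value
# is the maximum tolerated max/min ratio across the seven early stages.
DEFAULT_FOLD_PARAMS = {
    "maternal_decay": (40.0, 80.0),
    "trochophore_spike": (30.0, 120.0),
    "postlarval_rise": (25.0, 60.0),
    "housekeeping": (1.0, 1.5),
}


@dataclass
class ExpressionProgram:
    """Ground-truth expression of one gene across the eight libraries.

    ``true_abundance`` holds the relative transcript fraction per library in
    :data:`~starprofile.constants.ALL_STAGES` order; across a full program set
    each library's fractions sum to one.
    """

    gene_id: str
    archetype: str
    true_abundance: np.ndarray  # shape (8,), aligned to ALL_STAGES

    def series(self) -> pd.Series:
        return pd.Series(self.true_abundance, index=list(ALL_STAGES), name=self.gene_id)


@dataclass
class SimConfig:
    """Parameters of one simulated sequencing study."""

    n_genes: int = 300
    archetype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_PROPORTIONS)
    )
    library_depths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LIBRARY_DEPTHS)
    )
    fold_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FOLD_PARAMS)
    )
    # Multiplicative lognormal jitter (sigma of log) applied to unconstrained
    # stage levels; the within-stage biological variance of real embryos is
    # unknown, so this is a free parameter of the generator.
    stage_jitter_sd: float = 0.15
    # Anticipatory development: when enabled, late competent veligers (74VEL)
    # pre-express the postlarval program, so the rise-archetype fold floor then
    # applies to the stages before 74VEL only.
    benthic_shift: bool = False
    error_rate: float = 0.0
    dup_rate: float = 0.0
    length_range: tuple[int, int] = (300, 600)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        props = self.archetype_proportions
        unknown = set(props) - set(ARCHETYPES)
        if unknown:
            raise ParameterError(f"unknown archetypes: {sorted(unknown)}")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"archetype proportions sum to {total}, expected 1")
        if any(p < 0 for p in props.values()):
            raise ParameterError("archetype proportions must be non-negative")
        for lib, depth in self.library_depths.items():
            if depth <= 0:
                raise ParameterError(f"library depth for {lib} must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ParameterError("error_rate must be in [0, 1)")
        if not 0.0 <= self.dup_rate < 1.0:
            raise ParameterError("dup_rate must be in [0, 1)")


def load_config(path: str) -> SimConfig:
    """Read a :class:`SimConfig` from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "fold_params" in raw:
        raw["fold_params"] = {k: tuple(v) for k, v in raw["fold_params"].items()}
    if "length_range" in raw:
        raw["length_range"] = tuple(raw["length_range"])
    cfg = SimConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Reference transcripts
# ---------------------------------------------------------------------------

def generate_reference(
    n_genes: int, length_range: tuple[int, int] = (300, 600), seed: int = 0
) -> list[SeqRecord]:
    """Generate ``n_genes`` random transcript sequences.

    Lengths are uniform in ``length_range`` (inclusive), which must lie within
    [100, 4000] — the realistic unigene length regime for a 454 assembly.
    Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    lo, hi = length_range
    if not (100 <= lo <= hi <= 4000):
        raise ParameterError(f"length_range {length_range} must be within [100, 4000]")
    rng = np.random.default_rng(seed)
    records = []
    width = len(str(n_genes))
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        bases = "".join(rng.choice(_BASES, size=length))
        gid = f"GENE{i + 1:0{width}d}"
        records.append(SeqRecord(Seq(bases), id=gid, description=""))
    return records


# ---------------------------------------------------------------------------
# Expression programs
# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    if sd <= 0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, sd, size=n))


def _raw_profile(archetype: str, fold: float, rng: np.random.Generator, sd: float) -> np.ndarray:
    """One gene's unnormalized stage profile in ALL_STAGES order."""
    idx = {s: i for i, s in enumerate(ALL_STAGES)}
    p = np.ones(len(ALL_STAGES))
    if archetype == "maternal_decay":
        # decay after the morula; the 2CELL/MORU ratio is exactly `fold`
        tail = np.array([0.5, 0.3, 0.2, 0.15, 0.1]) * _jitter(rng, 5, sd)
        tail = np.minimum(tail, 0.95)  # keep MORU the post-2CELL maximum
        p[idx["MORU"]] = 1.0
        p[idx["2CELL"]] = fold
        p[2:7] = tail
        p[idx["INTE"]] = 0.1 * _jitter(rng, 1, sd)[0]
    elif archetype == "trochophore_spike":
        others = _jitter(rng, len(ALL_STAGES), sd)
        p[:] = others
        p[idx["TROC"]] = fold * max(np.delete(p, idx["TROC"]).max(), 1e-12)
    elif archetype == "postlarval_rise":
        others = _jitter(rng, len(ALL_STAGES), sd)
        p[:] = others
        earlier = p[[idx[s] for s in EARLY_STAGES[:-1]]]
        p[idx["144PL"]] = fold * earlier.max()
        p[idx["INTE"]] = 0.5 * p[idx["144PL"]]
    elif archetype == "housekeeping":
        # uniform jitter in [0.9, 1.1]: max/min <= 1.222 < 1.5 by construction
        p[:] = rng.uniform(0.9, 1.1, size=len(ALL_STAGES)) if sd > 0 else 1.0
    elif archetype == "background":
        p[:] = 0.3 * np.exp(rng.normal(0.0, 0.5, size=len(ALL_STAGES)))
    else:  # pragma: no cover - guarded by SimConfig.validate
        raise ParameterError(f"unknown archetype {archetype!r}")
    return p


def build_program(config: SimConfig) -> list[ExpressionProgram]:
    """Draw per-gene stage programs and normalize them to library fractions.

    Gene counts per archetype follow the configured proportions (largest
    remainder rounding). When background genes are present, their mass is
    rescaled per library to equalize column totals before normalization so
    that the configured fold ratios of the structured archetypes are exact in
    the normalized abundances.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    # Largest-remainder apportionment of genes to archetypes.
    props = {a: config.archetype_proportions.get(a, 0.0) for a in ARCHETYPES}
    quotas = {a: props[a] * n for a in ARCHETYPES}
    counts = {a: int(np.floor(q)) for a, q in quotas.items()}
    short = n - sum(counts.values())
    for a in sorted(ARCHETYPES, key=lambda a: quotas[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1

    labels: list[str] = []
    for a in ARCHETYPES:
        labels.extend([a] * counts[a])

    width = len(str(n))
    raw = np.zeros((n, len(ALL_STAGES)))
    for i, archetype in enumerate(labels):
        lo, hi = config.fold_params.get(archetype, DEFAULT_FOLD_PARAMS.get(archetype, (1.0, 1.0)))
        fold = float(rng.uniform(lo, hi))
        raw[i] = _raw_profile(archetype, fold, rng, config.stage_jitter_sd)

    if config.benthic_shift:
        # anticipatory development: competent veligers pre-express part of the
        # postlarval program, so the 74VEL and 144PL columns share structure.
        # The share is kept below the level at which a second elevated point
        # would mask the postlarval outlier from the r10 gap statistic.
        i74 = ALL_STAGES.index("74VEL")
        ipl = ALL_STAGES.index("144PL")
        for i, archetype in enumerate(labels):
            if archetype == "postlarval_rise":
                raw[i, i74] = 0.3 * raw[i, ipl]

    bg = np.array([a == "background" for a in labels])
    col_sums = raw.sum(axis=0)
    if bg.any():
        # equalize column totals through the background mass so normalization
        # preserves the structured genes' cross-stage ratios exactly
        target = 1.1 * col_sums.max()
        bg_sums = raw[bg].sum(axis=0)
        deficit = target - col_sums
        raw[np.ix_(bg, range(len(ALL_STAGES)))] *= 1.0 + deficit / bg_sums

    fractions = raw / raw.sum(axis=0)
    return [
        ExpressionProgram(
            gene_id=f"GENE{i + 1:0{width}d}",
            archetype=labels[i],
            true_abundance=fractions[i],
        )
        for i in range(n)
    ]


def programs_to_frame(programs: list[ExpressionProgram]) -> pd.DataFrame:
    """Gene x library DataFrame of true abundances."""
    return pd.DataFrame(
        {p.gene_id: p.true_abundance for p in programs}, index=list(ALL_STAGES)
    ).T


# ---------------------------------------------------------------------------
# Count sampling
# ---------------------------------------------------------------------------

def sample_counts(
    programs: list[ExpressionProgram],
    library_depths: dict[str, int] | None = None,
    seed: int = 0,
):
    """One multinomial draw per library: size = depth, probabilities = abundances.

    Returns a :class:`~starprofile.profiling.CountMatrix`; column sums equal
    the configured depths exactly.
    """
    from .profiling import CountMatrix  # local import to avoid a cycle

    depths = dict(library_depths or DEFAULT_LIBRARY_DEPTHS)
    for lib, d in depths.items():
        if d <= 0:
            raise ParameterError(f"depth for {lib} must be positive")
    rng = np.random.default_rng(seed)
    frame = programs_to_frame(programs)
    libs = [s for s in ALL_STAGES if s in depths] + [
        s for s in depths if s not in ALL_STAGES
    ]
    counts = {}
    for lib in libs:
        p = frame[lib].to_numpy(float)
        p = p / p.sum()
        counts[lib] = rng.multinomial(depths[lib], p)
    df = pd.DataFrame(counts, index=frame.index)
    return CountMatrix(df, pd.Series(depths)[libs])


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def _mutate(bases: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return bases
    arr = np.frombuffer(bases.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def emit_reads(
    counts,
    reference: list[SeqRecord],
    mid_map: dict[str, str] | None = None,
    adaptor: str = DEFAULT_ADAPTOR,
    error_rate: float = 0.0,
    dup_rate: float = 0.0,
    seed: int = 0,
    read_length_range: tuple[int, int] = (50, 600),
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Emit a pooled decorated read set realizing a count matrix.

    For every counted (gene, library) read a distinct subsequence of the
    source transcript is drawn (length uniform in ``read_length_range``,
    clipped to the transcript), substitution errors are applied to the insert
    at ``error_rate``, and the library MID plus the adaptor are prefixed.
    Exact extra copies are appended with geometric tail probability
    ``dup_rate`` per copy, so the duplicate fraction of the pool is
    ``dup_rate`` and exact-duplicate removal recovers the counted reads.

    Returns ``(reads, truth)`` where ``truth`` maps read id to its library,
    source gene and duplicate flag.
    """
    mid_map = dict(mid_map or DEFAULT_MIDS)
    if len(set(mid_map.values())) != len(mid_map):
        raise ConfigError("MID collision: barcodes must be distinct")
    ref = {r.id: str(r.seq) for r in reference}
    rng = np.random.default_rng(seed)
    lo, hi = read_length_range

    reads: list[SeqRecord] = []
    rows = []
    serial = 0
    df = counts.counts if hasattr(counts, "counts") else counts
    for lib in df.columns:
        if lib not in mid_map:
            raise ConfigError(f"no MID configured for library {lib}")
        prefix = mid_map[lib] + adaptor
        for gene, n_reads in df[lib].items():
            n_reads = int(n_reads)
            if n_reads == 0:
                continue
            if gene not in ref:
                raise ConsistencyError(f"counted gene {gene!r} absent from the reference")
            transcript = ref[gene]
            tlen = len(transcript)
            seen: set[tuple[int, int]] = set()
            for _ in range(n_reads):
                # draw a distinct (start, length) so counted reads stay unique
                # within the library and survive exact-duplicate removal
                for _try in range(200):
                    length = int(rng.integers(lo, min(hi, tlen) + 1))
                    start = int(rng.integers(0, tlen - length + 1))
                    if (start, length) not in seen:
                        break
                seen.add((start, length))
                insert = _mutate(transcript[start : start + length], error_rate, rng)
                serial += 1
                rid = f"read{serial:07d}"
                reads.append(_as_record(rid, prefix + insert))
                rows.append((rid, lib, gene, False))
                n_extra = 0
                while dup_rate > 0 and rng.random() < dup_rate:
                    n_extra += 1
                for j in range(n_extra):
                    serial += 1
                    did = f"read{serial:07d}"
                    reads.append(_as_record(did, prefix + insert))
                    rows.append((did, lib, gene, True))
    truth = pd.DataFrame(rows, columns=["read_id", "library", "gene_id", "is_duplicate"])
    return reads, truth


def _as_record(rid: str, bases: str) -> SeqRecord:
    rec = SeqRecord(Seq(bases), id=rid, description="")
    rec.letter_annotations["phred_quality"] = [40] * len(bases)
    return rec


# ---------------------------------------------------------------------------
# qPCR panels
# ---------------------------------------------------------------------------

def simulate_qpcr(
    programs: list[ExpressionProgram],
    gene_ids: list[str],
    noise_sd: float = 0.1,
    seed: int = 0,
    include_icgs: bool = True,
) -> pd.DataFrame:
    """Simulate qPCR relative-expression series over the seven early stages.

    Each gene's per-stage level is its true abundance times lognormal noise
    (sigma ``noise_sd`` on the log scale). Flat internal control genes
    (default YB1 and OAZ1) are appended so ICG normalization can be exercised.
    Levels are raw (not yet min-scaled); see
    :func:`starprofile.concordance.qpcr_relative`.
    """
    by_id = {p.gene_id: p for p in programs}
    missing = [g for g in gene_ids if g not in by_id]
    if missing:
        raise KeyError(f"genes not in program: {missing}")
    rng = np.random.default_rng(seed)
    early_idx = [ALL_STAGES.index(s) for s in EARLY_STAGES]
    rows = {}
    for g in gene_ids:
        truth = by_id[g].true_abundance[early_idx]
        noise = np.exp(rng.normal(0.0, noise_sd, size=len(early_idx))) if noise_sd > 0 else 1.0
        rows[g] = truth * noise
    if include_icgs:
        for icg in DEFAULT_ICGS:
            noise = np.exp(rng.normal(0.0, noise_sd, size=len(early_idx))) if noise_sd > 0 else 1.0
            rows[icg] = np.ones(len(early_idx)) * noise
    return pd.DataFrame(rows, index=list(EARLY_STAGES)).T
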