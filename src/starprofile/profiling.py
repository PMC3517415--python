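"""Read-to-gene assignment, count matrices and per-million normalization.

Each non-redundant read is matched to its best reference contig/scaffold —
either from externally computed BLASTn tabular hits (the route real data
takes) or from the bundled minimal k-mer mapper — subject to an E-value
ceiling (default 1e-30). Per-library hit counts form the gene x library
count matrix, and relative expression is

    expression = 1e6 * count / (total non-redundant reads of the library)

with the library's FULL non-redundant read count (not the mapped count) as
the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .constants import ConfigError, ConsistencyError, ParameterError, ParseError

# BLAST tabular "outfmt 6" default columns.
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass
class CountMatrix:
    """Raw non-redundant read counts, genes x libraries, plus library totals.

    ``library_totals`` are the per-library non-redundant read counts — the
    normalization denominators — and may exceed the column sums because not
    every read maps.
    """

    counts: pd.DataFrame
    library_totals: pd.Series

    def __post_init__(self):
        self.counts = self.counts.astype(int)
        self.library_totals = self.library_totals.astype(int)
        missing = [c for c in self.counts.columns if c not in self.library_totals.index]
        if missing:
            raise ConsistencyError(f"libraries without totals: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ParameterError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_labels(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, counts_path: str, totals_path: str) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.library_totals.rename("nonredundant_reads").to_csv(
            totals_path, sep="\t", index_label="library"
        )

    @classmethod
    def from_tsv(cls, counts_path: str, totals_path: str) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        totals = pd.read_csv(totals_path, sep="\t", index_col="library")[
            "nonredundant_reads"
        ]
        return cls(counts, totals)


# ---------------------------------------------------------------------------
# Hit handling
# ---------------------------------------------------------------------------

def read_blast6(path: str) -> pd.DataFrame:
    """Parse BLAST tabular (outfmt 6) hits into a hit-record frame.

    Returns columns read_id, contig_id, evalue, score (bitscore). Malformed
    lines raise :class:`ParseError` naming the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST6_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(BLAST6_COLUMNS)} columns, got {len(parts)}"
                )
            try:
                rows.append((parts[0], parts[1], float(parts[10]), float(parts[11])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=["read_id", "contig_id", "evalue", "score"])


def resolve_best_hits(hits: pd.DataFrame, evalue_max: float = 1e-30) -> pd.DataFrame:
    """Keep, per read, the single best hit below the E-value ceiling.

    Hits with ``evalue >= evalue_max`` are discarded. The best hit minimizes
    the E-value; ties go to the higher score, then to the lexicographically
    smaller contig id.
    """
    required = {"read_id", "contig_id", "evalue", "score"}
    if not required.issubset(hits.columns):
        raise ParameterError(f"hit frame must have columns {sorted(required)}")
    if (hits["evalue"] < 0).any():
        raise ParameterError("negative E-value in hit records")
    passing = hits[hits["evalue"] < evalue_max]
    if passing.empty:
        return passing.reset_index(drop=True)
    ordered = passing.sort_values(
        ["read_id", "evalue", "score", "contig_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("read_id", keep="first").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Internal mapper
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer position index over a reference sequence set."""

    def __init__(self, reference, k: int = 15):
        self.k = k
        self.seqs: dict[str, str] = {r.id: str(r.seq).upper() for r in reference}
        if not self.seqs:
            raise ConfigError("empty reference")
        self.index: dict[str, list[tuple[str, int]]] = {}
        for cid, seq in self.seqs.items():
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((cid, pos))


def map_reads_internal(
    reads,
    reference,
    kmer: int = 15,
    min_identity: float = 0.95,
    min_overlap: int = 50,
) -> pd.DataFrame:
    """Minimal k-mer-seeded ungapped mapper producing hit records.

    For each read, shared k-mers propose (contig, offset) placements; each
    placement is scored ungapped over the full overlap. A hit is emitted when
    identity >= ``min_identity`` and overlap >= ``min_overlap``; its score is
    matches - mismatches and a surrogate E-value 2**(-score) (monotone
    decreasing in score) is attached so :func:`resolve_best_hits` applies
    unchanged. Substitution-only: no indels, no reverse strand.
    """
    idx = reference if isinstance(reference, KmerIndex) else KmerIndex(reference, kmer)
    k = idx.k
    rows = []
    for read in reads:
        bases = read.bases if hasattr(read, "bases") else str(read.seq).upper()
        rid = read.id
        if len(bases) < k:
            continue
        placements: set[tuple[str, int]] = set()
        for rpos in range(0, len(bases) - k + 1, k):  # non-overlapping seed stride
            for cid, cpos in idx.index.get(bases[rpos : rpos + k], ()):
                placements.add((cid, cpos - rpos))
        for cid, offset in placements:
            ref = idx.seqs[cid]
            r_lo = max(0, -offset)
            r_hi = min(len(bases), len(ref) - offset)
            overlap = r_hi - r_lo
            if overlap < min_overlap:
                continue
            seg_read = bases[r_lo:r_hi]
            seg_ref = ref[r_lo + offset : r_hi + offset]
            matches = sum(a == b for a, b in zip(seg_read, seg_ref))
            identity = matches / overlap
            if identity < min_identity:
                continue
            score = matches - (overlap - matches)
            # surrogate E-value: monotone decreasing in score, and scaled to sit
            # below the default BLAST-domain ceiling (1e-30) for every hit the
            # mapper's own identity/overlap gates accept
            evalue = 1e-35 * 2.0 ** (-min(score, 900))
            rows.append((rid, cid, evalue, float(score)))
    return pd.DataFrame(rows, columns=["read_id", "contig_id", "evalue", "score"])


# ---------------------------------------------------------------------------
# Counting and normalization
# ---------------------------------------------------------------------------

def build_count_matrix(
    best_hits: pd.DataFrame,
    libraries,
    gene_ids: Iterable[str] | None = None,
) -> CountMatrix:
    """Count best hits per (gene, library).

    ``libraries`` maps library label -> ReadLibrary (its non-redundant reads
    and counts) or label -> iterable of read ids; in the latter case totals
    default to the id-set sizes. Every hit read id must belong to exactly one
    library. ``gene_ids``, when given, fixes the row universe (zero rows kept).
    """
    members: dict[str, set[str]] = {}
    totals: dict[str, int] = {}
    for label, lib in libraries.items():
        if hasattr(lib, "reads"):
            ids = {r.id for r in lib.reads}
            totals[label] = lib.n_nonredundant if lib.n_nonredundant is not None else len(ids)
        else:
            ids = set(lib)
            totals[label] = len(ids)
        members[label] = ids

    read_to_lib: dict[str, str] = {}
    for label, ids in members.items():
        for rid in ids:
            if rid in read_to_lib:
                raise ConsistencyError(f"read {rid} appears in two libraries")
            read_to_lib[rid] = label

    labels = list(libraries)
    if best_hits.empty:
        counts = pd.DataFrame(0, index=list(gene_ids or []), columns=labels)
        return CountMatrix(counts, pd.Series(totals)[labels])

    lib_of = best_hits["read_id"].map(read_to_lib)
    if lib_of.isna().any():
        bad = best_hits.loc[lib_of.isna(), "read_id"].iloc[0]
        raise ConsistencyError(f"hit read {bad!r} belongs to no library")
    counts = (
        pd.crosstab(best_hits["contig_id"], lib_of)
        .reindex(columns=labels, fill_value=0)
    )
    if gene_ids is not None:
        counts = counts.reindex(index=list(gene_ids), fill_value=0)
    counts.index.name = "gene_id"
    return CountMatrix(counts, pd.Series(totals)[labels])


def normalize_per_million(cm: CountMatrix, denominator: str = "total") -> pd.DataFrame:
    """Reads-per-million expression: 1e6 * count / library total, no pseudocounts.

    ``denominator='total'`` (default) uses the library's full non-redundant
    read count, following the profiling convention this package implements;
    ``'mapped'`` uses the mapped-read column sums instead, for sensitivity
    analysis.
    """
    if denominator == "total":
        denom = cm.library_totals[cm.counts.columns]
    elif denominator == "mapped":
        denom = cm.counts.sum(axis=0)
    else:
        raise ParameterError("denominator must be 'total' or 'mapped'")
    zero = denom[denom <= 0]
    if len(zero):
        raise ZeroDivisionError(f"zero library total for: {list(zero.index)}")
    return 1e6 * cm.counts / denom
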