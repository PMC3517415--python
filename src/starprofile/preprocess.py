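"""Read preprocessing: MID demultiplexing, cleaning and exact-duplicate removal.

Pooled multiplexed reads are segregated into per-stage libraries by their 5'
MID barcode, adaptors are trimmed, short (<50 bp by default) and low-quality
reads are dropped, and exact duplicates — reads with the same sequence AND
the same length, the signature of non-balanced amplification rather than of
independent sonication fragments — are collapsed to one representative per
library. The surviving "non-redundant" read counts are the denominators of
all downstream per-million normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import ConfigError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class SequencingRead:
    id: str
    bases: str
    qualities: list[int] | None = None

    def __post_init__(self):
        if not self.bases:
            raise ParameterError(f"read {self.id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ParameterError(f"read {self.id}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadLibrary:
    """A per-stage read set with its bookkeeping counts (raw >= clean >= non-redundant)."""

    label: str
    mid: str
    reads: list[SequencingRead] = field(default_factory=list)
    n_raw: int = 0
    n_clean: int | None = None
    n_nonredundant: int | None = None


def reads_from_records(records: Iterable[SeqRecord]) -> list[SequencingRead]:
    """Convert Biopython records (FASTA or FASTQ) to internal reads."""
    out = []
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality")
        out.append(SequencingRead(rec.id, str(rec.seq).upper(), list(quals) if quals else None))
    return out


def read_pool(path: str, fmt: str | None = None) -> list[SequencingRead]:
    """Load a pooled read file; format inferred from the extension unless given."""
    if fmt is None:
        fmt = "fastq" if str(path).lower().endswith(("fastq", "fq")) else "fasta"
    return reads_from_records(SeqIO.parse(path, fmt))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[SequencingRead],
    mid_map: dict[str, str],
    max_mismatches: int = 0,
) -> tuple[dict[str, ReadLibrary], list[SequencingRead]]:
    """Segregate pooled reads into libraries by 5'-anchored MID matching.

    A read is assigned iff exactly one MID matches its prefix within
    ``max_mismatches``; the matching prefix is stripped. Ambiguous matches and
    non-matches go to the unassigned pool (assigned + unassigned = input).
    """
    if max_mismatches < 0:
        raise ParameterError("max_mismatches must be >= 0")
    if len(set(mid_map.values())) != len(mid_map):
        raise ConfigError("duplicate MID sequences in the barcode map")
    libraries = {label: ReadLibrary(label=label, mid=mid) for label, mid in mid_map.items()}
    unassigned: list[SequencingRead] = []
    for read in reads:
        matches = [
            label
            for label, mid in mid_map.items()
            if len(read.bases) >= len(mid)
            and _hamming(read.bases[: len(mid)], mid) <= max_mismatches
        ]
        if len(matches) == 1:
            label = matches[0]
            cut = len(mid_map[label])
            lib = libraries[label]
            quals = read.qualities[cut:] if read.qualities else None
            lib.reads.append(SequencingRead(read.id, read.bases[cut:], quals))
            lib.n_raw += 1
        else:
            unassigned.append(read)
    return libraries, unassigned


def _quality_cut(qualities: list[int] | None, window: int, min_mean_q: float) -> int | None:
    """Index of the first sliding window whose mean quality drops below threshold."""
    if not qualities or window < 1:
        return None
    for start in range(0, max(len(qualities) - window + 1, 0)):
        if sum(qualities[start : start + window]) / window < min_mean_q:
            return start
    return None


def clean_reads(
    library: ReadLibrary,
    adaptors: Iterable[str] = (),
    min_len: int = 50,
    window: int = 10,
    min_mean_q: float = 20.0,
) -> ReadLibrary:
    """Trim adaptors and low-quality 3' tails, drop reads shorter than ``min_len``.

    Adaptor handling: a leading adaptor is stripped; any later occurrence is
    taken as 3' read-through and the read is truncated there. The quality
    filter is skipped for reads with no quality scores. Read order is
    preserved; the rule is strictly "shorter than", so a ``min_len``-long read
    survives.
    """
    if min_len < 1:
        raise ParameterError("min_len must be >= 1")
    adaptors = [a for a in adaptors if a]
    out = ReadLibrary(label=library.label, mid=library.mid, n_raw=library.n_raw or len(library.reads))
    kept = []
    for read in library.reads:
        bases, quals = read.bases, read.qualities
        for ad in adaptors:
            if bases.startswith(ad):
                bases = bases[len(ad):]
                quals = quals[len(ad):] if quals else None
        for ad in adaptors:
            pos = bases.find(ad)
            if pos >= 0:
                bases = bases[:pos]
                quals = quals[:pos] if quals else None
        cut = _quality_cut(quals, window, min_mean_q)
        if cut is not None:
            bases, quals = bases[:cut], quals[:cut] if quals else None
        if len(bases) >= min_len:
            kept.append(SequencingRead(read.id, bases, quals))
    out.reads = kept
    out.n_clean = len(kept)
    logger.info("%s: %d raw -> %d clean", out.label, out.n_raw, out.n_clean)
    return out


def dedup(library: ReadLibrary) -> ReadLibrary:
    """Remove exact duplicates (same sequence, hence same length) within a library.

    The first-encountered representative is kept, so the operation is
    order-stable and idempotent. A read that is a proper substring of another
    has a different length and is NOT redundant.
    """
    seen: set[str] = set()
    kept = []
    for read in library.reads:
        if read.bases not in seen:
            seen.add(read.bases)
            kept.append(read)
    out = ReadLibrary(
        label=library.label,
        mid=library.mid,
        reads=kept,
        n_raw=library.n_raw,
        n_clean=library.n_clean if library.n_clean is not None else len(library.reads),
        n_nonredundant=len(kept),
    )
    logger.info("%s: %d clean -> %d non-redundant", out.label, out.n_clean, out.n_nonredundant)
    return out


def preprocess_pool(
    reads: Iterable[SequencingRead],
    mid_map: dict[str, str],
    adaptors: Iterable[str] = (),
    max_mismatches: int = 0,
    min_len: int = 50,
    window: int = 10,
    min_mean_q: float = 20.0,
) -> tuple[dict[str, ReadLibrary], list[SequencingRead]]:
    """Full preprocessing: demultiplex, clean, dedup each library."""
    libraries, unassigned = demultiplex(reads, mid_map, max_mismatches)
    processed = {
        label: dedup(clean_reads(lib, adaptors, min_len, window, min_mean_q))
        for label, lib in libraries.items()
    }
    return processed, unassigned


def summary_table(libraries: dict[str, ReadLibrary]):
    """Per-library raw/clean/non-redundant counts as a DataFrame (one row each)."""
    import pandas as pd

    labels = list(libraries)
    return pd.DataFrame(
        {
            label: {
                "raw_reads": libraries[label].n_raw,
                "clean_reads": libraries[label].n_clean,
                "nonredundant_reads": libraries[label].n_nonredundant,
            }
            for label in labels
        }
    )[labels]


def write_library(library: ReadLibrary, path: str, fmt: str = "fasta") -> None:
    records = []
    for r in library.reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = r.qualities or [40] * len(r.bases)
        records.append(rec)
    SeqIO.write(records, path, fmt)
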