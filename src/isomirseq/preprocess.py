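"""Read-level preprocessing: quality filter, 3' adapter trim, tag collapsing.

Mirrors the standard small RNA-seq front end for 36-cycle single-end
libraries: reads failing a mean base-quality threshold are removed, the 3'
sequencing adapter is trimmed by seed-and-extend prefix matching, inserts
shorter than 15 nt are discarded, and surviving reads are collapsed into
unique tags with per-library counts. Read-count conservation across the
stages is asserted and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

DEFAULT_MIN_MEAN_Q = 20
DEFAULT_MIN_LEN = 15
DEFAULT_MIN_OVERLAP = 6
DEFAULT_MAX_MISMATCH_RATE = 0.1

_VALID = set("ACGT")


class FastqParseError(ValueError):
    pass


@dataclass(frozen=True)
class ReadTag:
    """A unique trimmed read sequence with its count in one library."""

    sequence: str
    count: int
    library_id: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")
        if not set(self.sequence) <= _VALID:
            raise ValueError(f"tag contains non-ACGT characters: {self.sequence!r}")


@dataclass
class PreprocessStats:
    """Per-library read accounting; conserves the input read count."""

    library_id: str
    reads_in: int = 0
    removed_quality: int = 0
    no_adapter: int = 0  # kept whole, flagged
    rejected_empty: int = 0  # adapter at position 0
    removed_length: int = 0
    reads_out: int = 0

    def assert_conserved(self) -> None:
        total = (
            self.removed_quality
            + self.rejected_empty
            + self.removed_length
            + self.reads_out
        )
        if total != self.reads_in:
            raise AssertionError(
                f"{self.library_id}: read conservation violated "
                f"({total} accounted of {self.reads_in})"
            )


def read_fastq(path) -> list[tuple[str, str, float]]:
    """Parse a Sanger FASTQ into (read_id, sequence, mean_quality) triples.

    Sequences are uppercased with U normalised to T. A malformed record
    raises :class:`FastqParseError` naming the record index.
    """
    out = []
    it = SeqIO.parse(str(path), "fastq")
    i = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            break
        except ValueError as exc:
            raise FastqParseError(f"malformed FASTQ record at index {i}: {exc}") from exc
        seq = str(rec.seq).upper().replace("U", "T")
        qual = rec.letter_annotations["phred_quality"]
        out.append((rec.id, seq, float(np.mean(qual)) if qual else 0.0))
        i += 1
    return out


def records_to_reads(records) -> list[tuple[str, str, float]]:
    """In-memory analogue of :func:`read_fastq` for Biopython SeqRecords."""
    out = []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        qual = rec.letter_annotations["phred_quality"]
        out.append((rec.id, seq, float(np.mean(qual)) if qual else 0.0))
    return out


def quality_filter(
    reads: list[tuple[str, str, float]], min_mean_q: int = DEFAULT_MIN_MEAN_Q
) -> tuple[list[tuple[str, str, float]], int]:
    """Remove reads with mean Phred quality below ``min_mean_q``."""
    kept = [r for r in reads if r[2] >= min_mean_q]
    return kept, len(reads) - len(kept)


def trim_adapter(
    read: str,
    adapter3: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> tuple[str | None, bool]:
    """Trim the 3' adapter from one read.

    The leftmost position where a prefix of ``adapter3`` of length >=
    ``min_overlap`` aligns to the read suffix with a mismatch rate <=
    ``max_mismatch_rate`` is truncated. Returns ``(insert, found)``; the
    insert is ``None`` when the adapter starts at position 0 (empty insert,
    read rejected) and the whole read with ``found=False`` when no adapter
    is detected.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    n = len(read)
    for i in range(n - min_overlap + 1):
        overlap = min(n - i, len(adapter3))
        if overlap < min_overlap:
            break
        mm = sum(a != b for a, b in zip(read[i : i + overlap], adapter3[:overlap]))
        if mm / overlap <= max_mismatch_rate:
            return (read[:i] if i > 0 else None), True
    return read, False


def length_filter(sequences: list[str], min_len: int = DEFAULT_MIN_LEN) -> list[str]:
    """Discard sequences shorter than ``min_len`` nucleotides."""
    return [s for s in sequences if len(s) >= min_len]


def collapse_tags(sequences: list[str], library_id: str) -> pd.DataFrame:
    """Collapse reads into unique tags with counts (order-independent).

    Returns a table with columns sequence, count, library_id sorted by
    descending count then sequence; the count column sums to the number of
    input reads.
    """
    counts = pd.Series(sequences, dtype=str).value_counts()
    df = counts.rename_axis("sequence").reset_index(name="count")
    df["library_id"] = library_id
    return df.sort_values(
        ["count", "sequence"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def preprocess_library(
    reads: list[tuple[str, str, float]],
    library_id: str,
    min_mean_q: int = DEFAULT_MIN_MEAN_Q,
    adapter3: str | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[pd.DataFrame, PreprocessStats]:
    """Full preprocessing of one library: quality, adapter, length, collapse.

    ``reads`` are (read_id, sequence, mean_quality) triples from
    :func:`read_fastq`. With ``adapter3=None`` the trimming stage is a
    no-op (pre-trimmed input). Returns the collapsed tag table and the
    conservation-checked stats.
    """
    stats = PreprocessStats(library_id=library_id, reads_in=len(reads))
    kept, stats.removed_quality = quality_filter(reads, min_mean_q)
    inserts: list[str] = []
    for _, seq, _ in kept:
        if adapter3 is None:
            inserts.append(seq)
            continue
        insert, found = trim_adapter(seq, adapter3, min_overlap, max_mismatch_rate)
        if insert is None:
            stats.rejected_empty += 1
            continue
        if not found:
            stats.no_adapter += 1
        inserts.append(insert)
    surviving = length_filter(inserts, min_len)
    stats.removed_length = len(inserts) - len(surviving)
    stats.reads_out = len(surviving)
    stats.assert_conserved()
    if not surviving:
        tags = pd.DataFrame(columns=["sequence", "count", "library_id"])
        tags["count"] = tags["count"].astype(np.int64)
        return tags, stats
    return collapse_tags(surviving, library_id), stats
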