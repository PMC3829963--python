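"""Ungapped matching of read tags to miRNA hairpin precursors.

Tags are placed on the precursor by exhaustive sliding-window Hamming
comparison (no indels) and accepted as isomiRs of an annotated mature
miRNA when both termini fall within ``window`` nucleotides of the mature
ends and the placement carries at most ``max_mismatches`` substitutions.
Accepted hits are labelled with the 5p/3p arm of the hairpin.

Coordinates are 0-based half-open on the precursor sequence throughout;
GFF3 input (1-based inclusive) is converted at the boundary by
:mod:`isomirseq.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: per-terminus offset window of the isomiR acceptance rule (nt)
DEFAULT_WINDOW = 4
#: maximum Hamming mismatches of an accepted placement
DEFAULT_MAX_MISMATCHES = 1

MULTIMAP_POLICIES = ("all", "fractional", "unique-only")


class MatcherError(ValueError):
    pass


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA product annotated on its hairpin precursor.

    ``p_start``/``p_end`` are 0-based half-open positions on the precursor
    sequence. ``arm`` is '5p' or '3p'; when not provided it is assigned from
    the position of the mature midpoint relative to the hairpin midpoint.
    """

    id: str
    arm: str
    p_start: int
    p_end: int
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise MatcherError(f"arm must be 5p or 3p, got {self.arm!r}")
        if not 16 <= self.p_end - self.p_start <= 28:
            raise MatcherError(
                f"mature {self.id}: length {self.p_end - self.p_start} outside [16, 28]"
            )


@dataclass(frozen=True)
class Precursor:
    """A miRNA hairpin with genomic location and 1-2 annotated mature arms."""

    id: str
    sequence: str
    chrom: str
    start: int  # 0-based half-open genomic
    end: int
    strand: str
    matures: tuple[MatureAnnotation, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise MatcherError(f"precursor {self.id}: bad strand {self.strand!r}")
        if not 1 <= len(self.matures) <= 2:
            raise MatcherError(f"precursor {self.id}: needs 1-2 matures")
        arms = [m.arm for m in self.matures]
        if len(set(arms)) != len(arms):
            raise MatcherError(f"precursor {self.id}: duplicate arm annotation")
        for m in self.matures:
            if not (0 <= m.p_start < m.p_end <= len(self.sequence)):
                raise MatcherError(
                    f"mature {m.id} outside precursor {self.id} bounds"
                )

    def mature_sequence(self, mature: MatureAnnotation) -> str:
        return self.sequence[mature.p_start : mature.p_end]


@dataclass(frozen=True)
class IsomiRHit:
    """An accepted placement of a tag within the mature region of a hairpin.

    ``offset5`` is the tag 5' end minus the mature 5' end and ``offset3`` the
    tag 3' end minus the mature 3' end, both in precursor coordinates, so the
    canonical mature product has ``offset5 == offset3 == 0``.
    """

    tag_sequence: str
    precursor_id: str
    mature_id: str
    offset5: int
    offset3: int
    mismatches: int
    arm: str


def assign_arm(p_start: int, p_end: int, precursor_length: int) -> str:
    """5p if the mature midpoint lies before the hairpin midpoint, else 3p."""
    return "5p" if (p_start + p_end) / 2 < precursor_length / 2 else "3p"


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def scan_precursor(
    tag: str, precursor: Precursor, max_mismatches: int = DEFAULT_MAX_MISMATCHES
) -> list[tuple[int, int]]:
    """Every ungapped placement of ``tag`` on the precursor.

    Returns ``(start, mismatches)`` pairs, sorted by start, for all
    placements with Hamming distance <= ``max_mismatches``; exhaustive over
    the full precursor (equivalent to a brute-force sliding window). A tag
    longer than the precursor yields no placements.
    """
    n, m = len(precursor.sequence), len(tag)
    if m > n or m == 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(
        _as_bytes(precursor.sequence), m
    )
    mismatches = (windows != _as_bytes(tag)).sum(axis=1)
    starts = np.nonzero(mismatches <= max_mismatches)[0]
    return [(int(s), int(mismatches[s])) for s in starts]


def classify_isomir(
    tag: str,
    start: int,
    mismatches: int,
    precursor: Precursor,
    window: int = DEFAULT_WINDOW,
) -> list[IsomiRHit]:
    """Accept a placement as an isomiR of each mature whose ends it matches.

    Acceptance requires both terminal offsets in ``[-window, +window]``; a
    placement overlapping no mature within the window yields no hits.
    """
    end = start + len(tag)
    hits = []
    for mature in precursor.matures:
        off5 = start - mature.p_start
        off3 = end - mature.p_end
        if abs(off5) <= window and abs(off3) <= window:
            hits.append(
                IsomiRHit(
                    tag_sequence=tag,
                    precursor_id=precursor.id,
                    mature_id=mature.id,
                    offset5=off5,
                    offset3=off3,
                    mismatches=mismatches,
                    arm=mature.arm,
                )
            )
    return hits


def match_tag(
    tag: str,
    precursors: list[Precursor],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    window: int = DEFAULT_WINDOW,
) -> list[IsomiRHit]:
    """All accepted isomiR hits of one tag, best placement per precursor.

    Within one precursor only the placement with fewest mismatches is kept
    (ties: smallest ``|offset5| + |offset3|``, then 5'-most start).
    """
    hits: list[IsomiRHit] = []
    for prec in precursors:
        candidates = []
        for start, mm in scan_precursor(tag, prec, max_mismatches):
            for hit in classify_isomir(tag, start, mm, prec, window):
                candidates.append((mm, abs(hit.offset5) + abs(hit.offset3), start, hit))
        if candidates:
            candidates.sort(key=lambda c: c[:3])
            hits.append(candidates[0][3])
    return hits


def resolve_multimap(
    hits: list[IsomiRHit], policy: str = "all"
) -> list[tuple[IsomiRHit, float]]:
    """Attribute one tag's count across the distinct matures it hits.

    ``all``
        the full count goes to every distinct mature (identical paralogs
        share counts; column sums may exceed the library total).
    ``fractional``
        each of the ``k`` distinct matures receives ``1/k`` of the count.
    ``unique-only``
        tags hitting more than one distinct mature are discarded.
    """
    if policy not in MULTIMAP_POLICIES:
        raise MatcherError(f"unknown multimap policy {policy!r}")
    if not hits:
        return []
    # one hit per distinct mature: keep the best-supported placement
    by_mature: dict[str, IsomiRHit] = {}
    for hit in hits:
        prev = by_mature.get(hit.mature_id)
        key = (hit.mismatches, abs(hit.offset5) + abs(hit.offset3))
        if prev is None or key < (prev.mismatches, abs(prev.offset5) + abs(prev.offset3)):
            by_mature[hit.mature_id] = hit
    distinct = list(by_mature.values())
    if policy == "unique-only" and len(distinct) > 1:
        return []
    weight = 1.0 if policy in ("all", "unique-only") else 1.0 / len(distinct)
    return [(hit, weight) for hit in distinct]


# ---------------------------------------------------------------------------
# batch path: scan many tags against all precursors at once
# ---------------------------------------------------------------------------


class _PrecursorIndex:
    """Concatenated precursor sequences for vectorised window scans."""

    def __init__(self, precursors: list[Precursor]):
        self.precursors = precursors
        self.offsets = np.cumsum([0] + [len(p.sequence) for p in precursors])
        self.concat = _as_bytes("".join(p.sequence for p in precursors))

    def windows(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        """All valid window starts of ``length`` and their precursor index."""
        if length > len(self.concat):
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        starts = []
        prec_idx = []
        for i, prec in enumerate(self.precursors):
            lo, hi = self.offsets[i], self.offsets[i + 1]
            n = hi - lo - length + 1
            if n > 0:
                starts.append(np.arange(lo, lo + n))
                prec_idx.append(np.full(n, i))
        if not starts:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(starts), np.concatenate(prec_idx)


def match_tag_table(
    tags: pd.DataFrame,
    precursors: list[Precursor],
    policy: str = "all",
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    window: int = DEFAULT_WINDOW,
    chunk: int = 256,
) -> pd.DataFrame:
    """Match a collapsed tag table against a precursor set.

    ``tags`` needs columns ``sequence``, ``count``, ``library_id``. Returns
    the assigned-hits table (one row per tag x mature after multimap
    resolution) with columns: sequence, count, library_id, precursor_id,
    mature_id, arm, offset5, offset3, mismatches, weight. Equivalent to
    calling :func:`match_tag` + :func:`resolve_multimap` per tag; vectorised
    over tags of equal length.
    """
    index = _PrecursorIndex(precursors)
    rows: list[dict] = []
    for length, group in tags.groupby(tags["sequence"].str.len()):
        starts, prec_idx = index.windows(int(length))
        if len(starts) == 0:
            continue
        win = np.lib.stride_tricks.sliding_window_view(index.concat, int(length))[starts]
        seqs = group["sequence"].to_numpy()
        tag_bytes = np.frombuffer(
            "".join(seqs).encode("ascii"), dtype=np.uint8
        ).reshape(len(seqs), int(length))
        for c0 in range(0, len(seqs), chunk):
            block = tag_bytes[c0 : c0 + chunk]
            mm = (win[None, :, :] != block[:, None, :]).sum(axis=2)
            ti, wi = np.nonzero(mm <= max_mismatches)
            for t, w in zip(ti, wi):
                row = group.iloc[c0 + t]
                prec = precursors[prec_idx[w]]
                start = int(starts[w] - index.offsets[prec_idx[w]])
                for hit in classify_isomir(
                    row["sequence"], start, int(mm[t, w]), prec, window
                ):
                    rows.append(
                        {
                            "sequence": row["sequence"],
                            "count": row["count"],
                            "library_id": row["library_id"],
                            "_sort": (
                                hit.mismatches,
                                abs(hit.offset5) + abs(hit.offset3),
                                start,
                            ),
                            "precursor_id": hit.precursor_id,
                            "mature_id": hit.mature_id,
                            "arm": hit.arm,
                            "offset5": hit.offset5,
                            "offset3": hit.offset3,
                            "mismatches": hit.mismatches,
                        }
                    )
    if not rows:
        return _empty_hits_table()
    df = pd.DataFrame(rows)
    # best placement per (tag, precursor): fewest mismatches, then smallest
    # |offset5|+|offset3|, then 5'-most
    df = (
        df.sort_values(["sequence", "precursor_id", "_sort"], kind="stable")
        .groupby(["sequence", "precursor_id"], as_index=False, sort=False)
        .first()
    )
    # best placement per (tag, mature) across precursors, then multimap policy
    df["_rank"] = df["mismatches"] * 100 + (df["offset5"].abs() + df["offset3"].abs())
    df = (
        df.sort_values(["sequence", "mature_id", "_rank"], kind="stable")
        .groupby(["sequence", "mature_id"], as_index=False, sort=False)
        .first()
    )
    n_matures = df.groupby("sequence")["mature_id"].transform("nunique")
    if policy == "unique-only":
        df = df[n_matures == 1].copy()
        df["weight"] = 1.0
    elif policy == "fractional":
        df = df.copy()
        df["weight"] = 1.0 / n_matures
    elif policy == "all":
        df = df.copy()
        df["weight"] = 1.0
    else:
        raise MatcherError(f"unknown multimap policy {policy!r}")
    df = df.drop(columns=["_sort", "_rank"]).reset_index(drop=True)
    return df[list(_HITS_COLUMNS)]


_HITS_COLUMNS = (
    "sequence",
    "count",
    "library_id",
    "precursor_id",
    "mature_id",
    "arm",
    "offset5",
    "offset3",
    "mismatches",
    "weight",
)


def _empty_hits_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            c: pd.Series(dtype=d)
            for c, d in zip(
                _HITS_COLUMNS,
                [str, np.int64, str, str, str, str, np.int64, np.int64, np.int64, float],
            )
        }
    )
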