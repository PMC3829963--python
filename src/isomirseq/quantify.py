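"""Per-miRNA abundance: low-count filtering, isomiR aggregation, RPM.

Two abundance estimators are computed for every mature miRNA in every
library: the count of its single most abundant isomiR (dominant) and the
sum over all accepted isomiRs. Both are normalised to reads per million
using the same denominator — the library's total mapped read count after
low-count filtering, with every mapped tag counted once — so any difference
between the normalised estimators reflects the numerator choice only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MIN_COUNT = 2


class QuantifyError(ValueError):
    pass


def filter_low_count(tags: pd.DataFrame, min_count: int = DEFAULT_MIN_COUNT) -> pd.DataFrame:
    """Drop tags observed fewer than ``min_count`` times in their library."""
    return tags[tags["count"] >= min_count].reset_index(drop=True)


def mapped_total(hits: pd.DataFrame) -> int:
    """Total mapped read count of a hits table, each tag counted once."""
    if hits.empty:
        return 0
    return int(hits.drop_duplicates("sequence")["count"].sum())


def aggregate_isomirs(hits: pd.DataFrame, library_id: str) -> pd.DataFrame:
    """Aggregate accepted isomiR hits into per-mature expression records.

    ``sum_count`` is the (multimap-weighted) sum of isomiR tag counts;
    ``dominant_count`` the largest single isomiR's weighted count, ties
    broken by canonical-ness (smallest ``|offset5| + |offset3|``) then
    lexicographic sequence. Columns: mature_id, library_id, dominant_count,
    sum_count, n_isomirs, dominant_sequence.
    """
    if hits.empty:
        return pd.DataFrame(
            columns=[
                "mature_id",
                "library_id",
                "dominant_count",
                "sum_count",
                "n_isomirs",
                "dominant_sequence",
            ]
        )
    df = hits.copy()
    df["wcount"] = df["count"] * df["weight"]
    df["_canon"] = df["offset5"].abs() + df["offset3"].abs()
    records = []
    for mature_id, grp in df.groupby("mature_id", sort=True):
        grp = grp.sort_values(
            ["wcount", "_canon", "sequence"],
            ascending=[False, True, True],
            kind="stable",
        )
        top = grp.iloc[0]
        records.append(
            {
                "mature_id": mature_id,
                "library_id": library_id,
                "dominant_count": top["wcount"],
                "sum_count": grp["wcount"].sum(),
                "n_isomirs": len(grp),
                "dominant_sequence": top["sequence"],
            }
        )
    out = pd.DataFrame(records)
    bad = out["dominant_count"] > out["sum_count"] + 1e-9
    assert not bad.any(), "dominant_count exceeds sum_count"
    return out


def rpm_normalize(records: pd.DataFrame, total_mapped: int, library_id: str) -> pd.DataFrame:
    """Add dominant_rpm and sum_rpm columns (reads per million mapped).

    The same denominator is applied to both estimators. Raises on a zero
    mapped total, naming the library.
    """
    if total_mapped <= 0:
        raise QuantifyError(f"library {library_id!r}: zero mapped reads")
    out = records.copy()
    out["dominant_rpm"] = out["dominant_count"] * 1e6 / total_mapped
    out["sum_rpm"] = out["sum_count"] * 1e6 / total_mapped
    return out


def length_histogram(hits: pd.DataFrame) -> pd.Series:
    """Mapped read counts by tag length (each tag counted once).

    Returns a Series indexed by length; ``.idxmax()`` is the modal length.
    """
    if hits.empty:
        return pd.Series(dtype=np.int64, name="reads")
    uniq = hits.drop_duplicates("sequence")
    return (
        uniq.groupby(uniq["sequence"].str.len())["count"]
        .sum()
        .rename("reads")
        .rename_axis("length")
        .sort_index()
    )


def quantify_library(
    hits: pd.DataFrame,
    library_id: str,
    min_count: int = DEFAULT_MIN_COUNT,
) -> tuple[pd.DataFrame, int, pd.Series]:
    """Low-count filter, aggregate, and RPM-normalise one library's hits.

    Returns (expression table, mapped total, length histogram); the mapped
    total and the histogram are computed after the low-count filter.
    """
    filtered = filter_low_count(hits, min_count)
    total = mapped_total(filtered)
    records = aggregate_isomirs(filtered, library_id)
    if not records.empty:
        records = rpm_normalize(records, total, library_id)
    else:
        records["dominant_rpm"] = pd.Series(dtype=float)
        records["sum_rpm"] = pd.Series(dtype=float)
    return records, total, length_histogram(filtered)
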