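"""Fold-change-based differential expression between two pooled libraries.

With one pooled library per condition there is no replication, so no
p-values are computed: a miRNA is called up- or down-regulated purely on
the log2 ratio of its case RPM to its control RPM exceeding a threshold
(default |log2 FC| > 2, i.e. a 4-fold change; the commonly used 2-fold
reading corresponds to ``threshold=1.0``). Both abundance estimators are
carried through so their fold-change estimates can be compared per miRNA.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 2.0  # on the log2 scale
DEFAULT_PSEUDOCOUNT = 0.5  # RPM, applied when one condition is undetected

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"
STATUS_UNDETECTED = "undetected"


class DifferentialError(ValueError):
    pass


def log2fc(rpm_case: float, rpm_control: float, pseudocount: float = 0.0) -> float:
    """log2((case + pc) / (control + pc)); antisymmetric in its arguments."""
    if pseudocount < 0:
        raise DifferentialError("pseudocount must be >= 0")
    if pseudocount == 0 and (rpm_case <= 0 or rpm_control <= 0):
        raise DifferentialError(
            "log2 fold change undefined for zero abundance without a pseudocount"
        )
    return math.log2((rpm_case + pseudocount) / (rpm_control + pseudocount))


def classify(fc: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """up if fc > threshold, down if fc < -threshold, else unchanged.

    The inequalities are strict: a fold change exactly at the threshold is
    unchanged.
    """
    if np.isnan(fc):
        return STATUS_UNDETECTED
    if fc > threshold:
        return STATUS_UP
    if fc < -threshold:
        return STATUS_DOWN
    return STATUS_UNCHANGED


def differential_table(
    expr_case: pd.DataFrame,
    expr_control: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    estimator: str = "sum",
    all_matures: list[str] | None = None,
) -> pd.DataFrame:
    """Per-miRNA log2 fold changes under both estimators and a status call.

    Expression tables come from :func:`isomirseq.quantify.quantify_library`.
    The pseudocount is added only when a miRNA is undetected in exactly one
    condition (both detected -> plain ratio). miRNAs undetected in both
    conditions are listed with status ``undetected`` only when
    ``all_matures`` supplies the annotation universe; they are never
    zero-filled. ``status`` is derived from the configured estimator's fold
    change ('sum' by default, 'dominant' selectable).
    """
    if estimator not in ("sum", "dominant"):
        raise DifferentialError(f"unknown estimator {estimator!r}")
    cols = ["mature_id", "dominant_rpm", "sum_rpm"]

    def _indexed(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return pd.DataFrame(columns=cols).set_index("mature_id")
        return df[cols].set_index("mature_id")

    case = _indexed(expr_case)
    control = _indexed(expr_control)
    detected = sorted(set(case.index) | set(control.index))

    rows = []
    for mid in detected:
        vals = {}
        for est in ("dominant", "sum"):
            a = float(case[f"{est}_rpm"].get(mid, 0.0))
            b = float(control[f"{est}_rpm"].get(mid, 0.0))
            pc = 0.0 if (a > 0 and b > 0) else pseudocount
            vals[est] = log2fc(a, b, pc)
        rows.append(
            {
                "mature_id": mid,
                "rpm_case_sum": float(case["sum_rpm"].get(mid, 0.0)),
                "rpm_control_sum": float(control["sum_rpm"].get(mid, 0.0)),
                "log2fc_dominant": vals["dominant"],
                "log2fc_sum": vals["sum"],
                "estimator_divergence": abs(vals["dominant"] - vals["sum"]),
                "status": classify(vals[estimator], threshold),
            }
        )
    if all_matures is not None:
        for mid in sorted(set(all_matures) - set(detected)):
            rows.append(
                {
                    "mature_id": mid,
                    "rpm_case_sum": np.nan,
                    "rpm_control_sum": np.nan,
                    "log2fc_dominant": np.nan,
                    "log2fc_sum": np.nan,
                    "estimator_divergence": np.nan,
                    "status": STATUS_UNDETECTED,
                }
            )
    return pd.DataFrame(rows)


def compare_estimators(diff: pd.DataFrame, top_n: int = 10) -> dict[str, pd.DataFrame]:
    """Estimator-comparison report and ranked up/down lists.

    Returns a dict with ``comparison`` (per-miRNA fold changes under both
    estimators and their divergence, sorted by |log2fc_sum| descending) and
    ``top_up`` / ``top_down`` (the ``top_n`` strongest calls in each
    direction, ranked by the sum estimator).
    """
    comp = diff[diff["status"] != STATUS_UNDETECTED].copy()
    comp = comp.sort_values(
        "log2fc_sum", key=lambda s: s.abs(), ascending=False, kind="stable"
    ).reset_index(drop=True)
    up = comp[comp["status"] == STATUS_UP].sort_values(
        "log2fc_sum", ascending=False, kind="stable"
    )
    down = comp[comp["status"] == STATUS_DOWN].sort_values(
        "log2fc_sum", ascending=True, kind="stable"
    )
    return {
        "comparison": comp,
        "top_up": up.head(top_n).reset_index(drop=True),
        "top_down": down.head(top_n).reset_index(drop=True),
    }
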