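"""miRNA gene clusters, gene families, and dysregulation concordance.

Clusters are genomically proximal hairpins (single-linkage chaining on the
same chromosome and strand within a maximum gap, default 10 kb — the
prevailing miRNA-cluster window). Families are matures sharing an identical
seed (positions 2-8) unless an explicit family map is supplied. The
concordance statistic captures the observation that co-located and
homologous miRNAs tend to shift in the same direction even when their fold
changes differ: it is the fraction of detected members whose log2
fold-change sign agrees with the majority sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matcher import Precursor

DEFAULT_MAX_GAP = 10_000


@dataclass
class MiRNAGroup:
    group_id: str
    kind: str  # 'cluster' or 'family'
    member_ids: list[str]  # mature ids
    precursor_ids: list[str] = field(default_factory=list)


def build_clusters(
    precursors: list[Precursor], max_gap: int = DEFAULT_MAX_GAP
) -> list[list[Precursor]]:
    """Single-linkage genomic clustering of hairpin loci.

    Precursors on the same chromosome and strand are chained while the gap
    between consecutive loci (next start minus previous end) is at most
    ``max_gap``. Singletons are not clusters. Order-independent: input is
    sorted internally.
    """
    clusters: list[list[Precursor]] = []
    key = lambda p: (p.chrom, p.strand)
    groups: dict[tuple[str, str], list[Precursor]] = {}
    for p in precursors:
        groups.setdefault(key(p), []).append(p)
    for (_, _), members in sorted(groups.items()):
        members = sorted(members, key=lambda p: (p.start, p.end, p.id))
        chain = [members[0]]
        for p in members[1:]:
            if p.start - chain[-1].end <= max_gap:
                chain.append(p)
            else:
                if len(chain) >= 2:
                    clusters.append(chain)
                chain = [p]
        if len(chain) >= 2:
            clusters.append(chain)
    return clusters


def cluster_groups(
    precursors: list[Precursor], max_gap: int = DEFAULT_MAX_GAP
) -> list[MiRNAGroup]:
    out = []
    for i, chain in enumerate(build_clusters(precursors, max_gap)):
        out.append(
            MiRNAGroup(
                group_id=f"cluster{i + 1}",
                kind="cluster",
                member_ids=[m.id for p in chain for m in p.matures],
                precursor_ids=[p.id for p in chain],
            )
        )
    return out


def build_families(
    precursors: list[Precursor],
    family_map: pd.DataFrame | None = None,
    min_size: int = 2,
) -> list[MiRNAGroup]:
    """Group matures into families by map or by shared seed.

    A provided family map (two columns: family_id, mature_id, miRBase
    style) takes precedence; otherwise matures sharing the identical seed
    sequence (positions 2-8 of the mature, 1-based) are grouped. Groups
    smaller than ``min_size`` are dropped.
    """
    members: dict[str, list[str]] = {}
    if family_map is not None:
        for fam, mid in family_map.iloc[:, :2].itertuples(index=False):
            members.setdefault(str(fam), []).append(str(mid))
    else:
        by_seed: dict[str, list[str]] = {}
        for prec in precursors:
            for m in prec.matures:
                seed = prec.mature_sequence(m)[1:8]
                by_seed.setdefault(seed, []).append(m.id)
        for i, (seed, mids) in enumerate(sorted(by_seed.items())):
            members[f"seed:{seed}"] = mids
    return [
        MiRNAGroup(group_id=fam, kind="family", member_ids=sorted(set(mids)))
        for fam, mids in sorted(members.items())
        if len(set(mids)) >= min_size
    ]


def concordance(member_log2fcs: list[float]) -> float:
    """Fraction of members whose fold-change sign matches the majority sign.

    Members with undefined (NaN) or exactly zero fold change cast no vote.
    An equal split of signs scores 0.5; fewer than two voting members gives
    NaN. Always in [0, 1]; equals 1 iff all voting members share a sign.
    """
    signs = [np.sign(fc) for fc in member_log2fcs if not np.isnan(fc) and fc != 0]
    if len(signs) < 2:
        return float("nan")
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = len(signs) - n_pos
    if n_pos == n_neg:
        return 0.5
    return max(n_pos, n_neg) / len(signs)


def group_report(
    groups: list[MiRNAGroup],
    diff: pd.DataFrame,
    expr_by_library: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-group concordance and expression span.

    ``expression_span`` is the log2 ratio of the largest to the smallest
    member mean sum-RPM (mean across libraries, detected members only),
    capturing how unevenly expressed a concordant group can be. Member fold
    changes use the sum estimator.
    """
    fc = diff.set_index("mature_id")["log2fc_sum"]
    rpm = pd.concat(expr_by_library.values(), ignore_index=True)
    mean_rpm = rpm.groupby("mature_id")["sum_rpm"].mean() if not rpm.empty else pd.Series(dtype=float)
    rows = []
    for g in groups:
        member_fc = [float(fc.get(m, np.nan)) for m in g.member_ids]
        detected_rpm = [float(mean_rpm[m]) for m in g.member_ids if m in mean_rpm.index]
        positive = [r for r in detected_rpm if r > 0]
        span = (
            float(np.log2(max(positive) / min(positive))) if len(positive) >= 2 else np.nan
        )
        rows.append(
            {
                "group_id": g.group_id,
                "kind": g.kind,
                "n_members": len(g.member_ids),
                "n_detected": int(np.sum(~np.isnan(member_fc))),
                "concordance": concordance(member_fc),
                "expression_span": span,
                "member_ids": ";".join(g.member_ids),
                "member_log2fc": ";".join(
                    "NA" if np.isnan(v) else f"{v:.4f}" for v in member_fc
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "kind",
            "n_members",
            "n_detected",
            "concordance",
            "expression_span",
            "member_ids",
            "member_log2fc",
        ],
    )
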