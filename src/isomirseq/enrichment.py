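"""Target mapping and hypergeometric pathway over-representation.

Differential miRNAs are mapped to experimentally validated target genes
(user-supplied two-column table, e.g. a miRTarBase export) and the pooled
target set is tested for over-representation in pathway gene sets (GMT)
with the one-sided hypergeometric tail P(X >= k), Benjamini-Hochberg
adjusted across pathways. The background defaults to every gene in the
target table and can be overridden.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


def load_target_table(path) -> pd.DataFrame:
    """Load and deduplicate a two-column (mature_id, gene) target table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise EnrichmentError("target table needs two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["mature_id", "gene"]
    return df.drop_duplicates().reset_index(drop=True)


def map_targets(
    mirna_ids: list[str], target_table: pd.DataFrame
) -> dict[str, set[str]]:
    """Union of validated targets of the query miRNAs, with provenance.

    Returns gene -> set of query miRNAs targeting it. Query miRNAs absent
    from the table contribute nothing (logged).
    """
    by_mirna = target_table.groupby("mature_id")["gene"].apply(set)
    genes: dict[str, set[str]] = {}
    for mid in mirna_ids:
        if mid not in by_mirna.index:
            logger.info("miRNA %s has no validated targets in the table", mid)
            continue
        for g in by_mirna[mid]:
            genes.setdefault(g, set()).add(mid)
    return genes


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise EnrichmentError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query_genes: set[str],
    pathways: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Over-representation of the query in each pathway gene set.

    Pathways are intersected with the background; those with no overlap are
    skipped (logged). Results carry raw and BH-adjusted p-values and are
    sorted ascending by p. Requires ``background >= query_genes``.
    """
    if not query_genes <= background:
        raise EnrichmentError("background must contain every query gene")
    N = len(background)
    n = len(query_genes)
    rows = []
    for pid, genes in sorted(pathways.items()):
        in_bg = genes & background
        if not in_bg:
            logger.info("pathway %s has no overlap with the background; skipped", pid)
            continue
        hit = query_genes & in_bg
        rows.append(
            {
                "pathway_id": pid,
                "k": len(hit),
                "K": len(in_bg),
                "n": n,
                "N": N,
                "p_value": hypergeom_pvalue(len(hit), len(in_bg), n, N),
                "hit_genes": ";".join(sorted(hit)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["pathway_id", "k", "K", "n", "N", "p_value", "hit_genes"]
    )
    if not df.empty:
        df["p_adjusted"] = false_discovery_control(df["p_value"], method="bh")
        df = df.sort_values(["p_value", "pathway_id"], kind="stable").reset_index(
            drop=True
        )
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df[["pathway_id", "k", "K", "n", "N", "p_value", "p_adjusted", "hit_genes"]]


def enrich_from_tables(
    mirna_ids: list[str],
    target_table: pd.DataFrame,
    pathways: dict[str, set[str]],
    background: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Map miRNAs to targets and run the enrichment in one step.

    Background defaults to all genes in the target table, augmented with
    the query genes (a supplied background is used as-is after the same
    augmentation check).
    """
    provenance = map_targets(mirna_ids, target_table)
    query = set(provenance)
    if background is None:
        background = set(target_table["gene"])
    return hypergeom_enrich(query, pathways, background), provenance
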