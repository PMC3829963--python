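"""Summary plots and report over a finished pipeline results directory."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def _read(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(results_dir, top_n: int = 10) -> Path:
    """Render plots and a text summary from the tables in ``results_dir``.

    Produces length-distribution bars per library, ranked top up/down fold
    changes under both estimators, per-group member fold-change panels, and
    ``summary.txt``. Returns the summary path. An empty differential set is
    reported, not an error.
    """
    results_dir = Path(results_dir)
    diff = _read(results_dir / "differential.tsv")
    lines = []

    hist_paths = sorted(results_dir.glob("length_histogram.*.tsv"))
    if hist_paths:
        fig, axes = plt.subplots(1, len(hist_paths), figsize=(5 * len(hist_paths), 3.5))
        if len(hist_paths) == 1:
            axes = [axes]
        for ax, hp in zip(axes, hist_paths):
            hist = _read(hp)
            lib = hp.stem.split(".", 1)[1]
            ax.bar(hist["length"], hist["reads"], color="steelblue")
            ax.set_xlabel("tag length (nt)")
            ax.set_ylabel("mapped reads")
            ax.set_title(lib)
            if len(hist):
                mode = int(hist.loc[hist["reads"].idxmax(), "length"])
                lines.append(f"{lib}: modal mapped read length {mode} nt")
        fig.tight_layout()
        fig.savefig(results_dir / "length_distribution.png", dpi=120)
        plt.close(fig)

    called = diff[diff["status"].isin(["up", "down"])]
    lines.append(
        f"{len(called)} miRNAs classified differentially expressed "
        f"({(diff['status'] == 'up').sum()} up, {(diff['status'] == 'down').sum()} down)"
    )
    if called.empty:
        lines.append("no differentially expressed miRNAs at this threshold")
    else:
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        for ax, (status, asc) in zip(axes, [("up", False), ("down", True)]):
            sub = called[called["status"] == status].sort_values(
                "log2fc_sum", ascending=asc
            ).head(top_n)
            y = range(len(sub))
            ax.barh(y, sub["log2fc_sum"], height=0.35, label="sum of isomiRs")
            ax.barh(
                [v + 0.4 for v in y],
                sub["log2fc_dominant"],
                height=0.35,
                label="dominant isomiR",
            )
            ax.set_yticks([v + 0.2 for v in y], sub["mature_id"])
            ax.invert_yaxis()
            ax.set_xlabel("log2 fold change")
            ax.set_title(f"top {status}-regulated")
            ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(results_dir / "top_differential.png", dpi=120)
        plt.close(fig)
        for _, row in called.iterrows():
            lines.append(
                f"  {row['status']:>4}  {row['mature_id']}  "
                f"log2FC(sum)={row['log2fc_sum']:+.2f}  "
                f"log2FC(dominant)={row['log2fc_dominant']:+.2f}"
            )

    groups_path = results_dir / "groups.tsv"
    if groups_path.exists():
        groups = _read(groups_path)
        scored = groups.dropna(subset=["concordance"])
        if not scored.empty:
            fig, ax = plt.subplots(figsize=(6, 0.5 * len(scored) + 1.5))
            for i, (_, row) in enumerate(scored.iterrows()):
                fcs = [
                    float(v)
                    for v in str(row["member_log2fc"]).split(";")
                    if v != "NA"
                ]
                ax.scatter(fcs, [i] * len(fcs), s=18)
            ax.set_yticks(range(len(scored)), scored["group_id"])
            ax.axvline(0, color="grey", lw=0.8)
            ax.set_xlabel("member log2 fold change (sum estimator)")
            ax.set_title("cluster / family dysregulation")
            fig.tight_layout()
            fig.savefig(results_dir / "group_concordance.png", dpi=120)
            plt.close(fig)
            lines.append(
                f"mean group concordance {scored['concordance'].mean():.3f} "
                f"over {len(scored)} scored groups"
            )

    summary = results_dir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    return summary
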