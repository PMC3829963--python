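"""Synthetic small RNA-seq data with known ground truth.

Emulates a two-condition (case vs. control, e.g. ob/ob vs. wild-type liver)
miRNA sequencing experiment: hairpin precursors with one or two mature arms,
genomically clustered and seed-sharing paralogous loci, per-condition
expression profiles with known log2 effect sizes, and 36-cycle reads whose
short inserts read through into the 3' sequencing adapter. IsomiR diversity
arises from independent 5' and 3' cleavage offsets, mimicking imprecise and
alternative Drosha/Dicer processing.

Everything is deterministic for a fixed seed; per-read and per-miRNA ground
truth are emitted alongside the FASTQ so every downstream stage is testable
without external data.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matcher import MatureAnnotation, Precursor, assign_arm

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: bases sequenced after the 3' adapter when insert + adapter < read length
#: (downstream PCR-primer region; arbitrary fixed sequence)
POST_ADAPTER = "ATCTCGTATGCCGTCTTCTG"

#: classic Illumina GAIIx-era small RNA 3' adapter
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"


class SimConfigError(ValueError):
    pass


def _default_offsets() -> dict[int, float]:
    return {0: 0.6, 1: 0.15, -1: 0.15, 2: 0.05, -2: 0.05}


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults reproduce the package's reference conditions: 50 hairpins, 20%
    of matures differentially expressed at |log2 fold change| = 3, 100,000
    reads per library, 0.5% per-base substitution error, cleavage offsets
    concentrated on the canonical ends.
    """

    n_precursors: int = 50
    n_clusters: int = 3
    cluster_span: int = 10_000  # max intra-cluster gap, bp
    n_families: int = 2
    family_size: int = 3
    mature_len_range: tuple[int, int] = (20, 24)
    read_len: int = 36
    adapter3: str = DEFAULT_ADAPTER3
    error_rate: float = 0.005  # substitution probability per base
    cleavage_offset_probs: dict[int, float] = field(default_factory=_default_offsets)
    lib_depth: int = 100_000
    frac_de: float = 0.2
    effect_log2: float = 3.0  # magnitude of true log2 fold change of DE miRNAs
    seed: int = 0
    # ---- secondary knobs -------------------------------------------------
    p_two_mature: float = 0.3  # fraction of hairpins with both arms annotated
    low_quality_frac: float = 0.01  # reads emitted with uniformly low qualities
    flank_len: int = 8  # nt of hairpin flank beyond each mature
    loop_len: int = 12  # nt between the two arms
    abundance_sigma: float = 1.0  # lognormal spread of baseline expression
    conditions: tuple[str, str] = ("case", "control")
    #: assign differential expression to whole clusters/families so that
    #: group members share the same true effect (co-transcription /
    #: homology-driven co-regulation); off by default, where DE matures are
    #: drawn individually
    de_respect_groups: bool = False

    def validate(self) -> None:
        if self.n_precursors <= 0:
            raise SimConfigError("n_precursors must be positive")
        if self.n_precursors < self.n_clusters:
            raise SimConfigError("n_precursors < n_clusters")
        if not 0 <= self.error_rate < 1:
            raise SimConfigError("error_rate must be in [0, 1)")
        if self.read_len < 15:
            raise SimConfigError("read_len must be >= 15")
        if self.effect_log2 <= 0:
            raise SimConfigError("effect_log2 must be > 0")
        if not 0 <= self.frac_de <= 1:
            raise SimConfigError("frac_de must be in [0, 1]")
        total = sum(self.cleavage_offset_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"cleavage_offset_probs sum to {total}, not 1")
        if any(not -6 <= k <= 6 for k in self.cleavage_offset_probs):
            raise SimConfigError("cleavage offsets must lie in [-6, +6]")
        lo, hi = self.mature_len_range
        if not 16 <= lo <= hi <= 28:
            raise SimConfigError("mature_len_range must lie within [16, 28]")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def make_precursors(cfg: SimConfig) -> list[Precursor]:
    """Generate a deterministic precursor set with clusters and families.

    Each hairpin is flank + 5p arm + loop + 3p arm + flank, with one or both
    arms annotated as matures. The first ``n_clusters`` groups of hairpins
    share a chromosome with pairwise gaps <= ``cluster_span``; the next
    ``n_families`` groups of singleton hairpins share an identical seed
    (mature positions 2-8). Clusters alternate between 2 and 3 members.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    cluster_sizes = [2 + (i % 2) for i in range(cfg.n_clusters)]
    n_clustered = sum(cluster_sizes)
    n_family_members = cfg.n_families * cfg.family_size
    if n_clustered + n_family_members > cfg.n_precursors:
        raise SimConfigError(
            "n_precursors too small for requested clusters and families"
        )

    # family seeds: mature positions 2-8 (1-based), i.e. sequence[1:8]
    family_seeds = [_random_seq(rng, 7) for _ in range(cfg.n_families)]

    precursors: list[Precursor] = []
    cluster_of: list[str | None] = []
    family_of: list[str | None] = []
    for i in range(cfg.n_precursors):
        cluster_id = None
        family_id = None
        j = i
        for c, size in enumerate(cluster_sizes):
            if j < size:
                cluster_id = f"cluster{c + 1}"
                break
            j -= size
        else:
            j = i - n_clustered
            if 0 <= j < n_family_members:
                family_id = f"fam{j // cfg.family_size + 1}"
        cluster_of.append(cluster_id)
        family_of.append(family_id)

    lo, hi = cfg.mature_len_range
    chrom_counter = 0
    prev_cluster: str | None = None
    pos = 0
    chrom = "chr0"
    strand = "+"
    for i in range(cfg.n_precursors):
        len5 = int(rng.integers(lo, hi + 1))
        len3 = int(rng.integers(lo, hi + 1))
        arm5 = _random_seq(rng, len5)
        arm3 = _random_seq(rng, len3)
        if family_of[i] is not None:
            seed = family_seeds[int(family_of[i].removeprefix("fam")) - 1]
            arm5 = arm5[0] + seed + arm5[8:]
        seq = (
            _random_seq(rng, cfg.flank_len)
            + arm5
            + _random_seq(rng, cfg.loop_len)
            + arm3
            + _random_seq(rng, cfg.flank_len)
        )
        p5 = (cfg.flank_len, cfg.flank_len + len5)
        p3 = (len(seq) - cfg.flank_len - len3, len(seq) - cfg.flank_len)

        both = rng.random() < cfg.p_two_mature
        name = f"sim-mir-{i + 1}"
        matures = []
        # family seed sits on the 5p arm, so family members always annotate it
        use5 = both or family_of[i] is not None or rng.random() < 0.5
        if use5:
            matures.append(
                MatureAnnotation(
                    id=f"sim-miR-{i + 1}-5p",
                    arm=assign_arm(*p5, len(seq)),
                    p_start=p5[0],
                    p_end=p5[1],
                    family_id=family_of[i],
                )
            )
        if both or not use5:
            matures.append(
                MatureAnnotation(
                    id=f"sim-miR-{i + 1}-3p",
                    arm=assign_arm(*p3, len(seq)),
                    p_start=p3[0],
                    p_end=p3[1],
                )
            )

        if cluster_of[i] is not None:
            if cluster_of[i] != prev_cluster:
                chrom_counter += 1
                chrom = f"chr{chrom_counter}"
                strand = "+" if rng.random() < 0.5 else "-"
                pos = int(rng.integers(10_000, 1_000_000))
            else:
                pos += len(seq) + int(rng.integers(200, cfg.cluster_span + 1))
            prev_cluster = cluster_of[i]
        else:
            chrom_counter += 1
            chrom = f"chr{chrom_counter}"
            strand = "+" if rng.random() < 0.5 else "-"
            pos = int(rng.integers(10_000, 1_000_000))
            prev_cluster = None

        precursors.append(
            Precursor(
                id=name,
                sequence=seq,
                chrom=chrom,
                start=pos,
                end=pos + len(seq),
                strand=strand,
                matures=tuple(matures),
            )
        )
    return precursors


def make_profile(precursors: list[Precursor], cfg: SimConfig) -> pd.DataFrame:
    """Two-condition expression profile with known effects (the truth table).

    Baseline abundances are lognormal. Differentially expressed matures are
    split equally between up- and down-regulation; the up set's baselines
    are rescaled so that the total abundance mass is identical in both
    conditions, hence after normalisation non-DE miRNAs have a true log2
    fold change of exactly 0 and DE miRNAs of exactly +/- effect_log2.
    With ``cfg.de_respect_groups`` the DE units are whole clusters/families
    (members share the effect); otherwise individual matures.

    Columns: mature_id, condition, true_abundance, true_log2fc, is_de,
    cluster_id, family_id. Abundances sum to 1 within each condition.
    """
    cfg.validate()
    if not precursors:
        raise SimConfigError("empty precursor set")
    rng = np.random.default_rng(cfg.seed + 1)

    matures = []
    for prec in precursors:
        for m in prec.matures:
            matures.append((m.id, prec, m))
    n = len(matures)
    base = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n)

    n_de_target = int(round(cfg.frac_de * n))
    n_de_target -= n_de_target % 2  # equal up/down split
    cluster_by_prec = _cluster_labels(precursors, cfg)
    if cfg.de_respect_groups:
        units: dict[str, list[int]] = {}
        for k, (mid, prec, m) in enumerate(matures):
            label = m.family_id or cluster_by_prec.get(prec.id) or f"singleton:{mid}"
            units.setdefault(label, []).append(k)
        unit_list = [units[u] for u in sorted(units)]
    else:
        unit_list = [[k] for k in range(n)]
    order = rng.permutation(len(unit_list))
    up_idx: list[int] = []
    down_idx: list[int] = []
    for pos, u in enumerate(order):
        if len(up_idx) + len(down_idx) >= n_de_target:
            break
        (up_idx if pos % 2 == 0 else down_idx).extend(unit_list[u])
    if not up_idx or not down_idx:
        up_idx, down_idx = [], []
    up_idx = np.asarray(up_idx, dtype=np.int64)
    down_idx = np.asarray(down_idx, dtype=np.int64)
    if len(up_idx):
        # mass balance: scaled up-baselines cancel the down set's loss
        base[up_idx] *= (
            2.0**-cfg.effect_log2
            * base[down_idx].sum()
            / base[up_idx].sum()
        )
    de_idx = np.concatenate([up_idx, down_idx])

    scale = np.ones(n)
    scale[up_idx] = 2.0**cfg.effect_log2
    scale[down_idx] = 2.0**-cfg.effect_log2
    case = base * scale
    control = base.copy()
    assert math.isclose(case.sum(), control.sum(), rel_tol=1e-9)
    case /= case.sum()
    control /= control.sum()

    log2fc = np.zeros(n)
    log2fc[up_idx] = cfg.effect_log2
    log2fc[down_idx] = -cfg.effect_log2
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True

    rows = []
    case_label, control_label = cfg.conditions
    for k, (mid, prec, m) in enumerate(matures):
        for cond, ab in ((case_label, case[k]), (control_label, control[k])):
            rows.append(
                {
                    "mature_id": mid,
                    "condition": cond,
                    "true_abundance": ab,
                    "true_log2fc": log2fc[k],
                    "is_de": bool(is_de[k]),
                    "cluster_id": cluster_by_prec.get(prec.id),
                    "family_id": m.family_id,
                }
            )
    return pd.DataFrame(rows)


def _cluster_labels(precursors: list[Precursor], cfg: SimConfig) -> dict[str, str]:
    """Recover the generator's cluster assignment from genomic layout."""
    from .grouping import build_clusters

    labels: dict[str, str] = {}
    for c, members in enumerate(build_clusters(precursors, max_gap=cfg.cluster_span)):
        for prec in members:
            labels[prec.id] = f"cluster{c + 1}"
    return labels


def simulate_library(
    precursors: list[Precursor],
    truth: pd.DataFrame,
    condition: str,
    cfg: SimConfig,
    seed_offset: int = 0,
) -> tuple[list[SeqRecord], pd.DataFrame, int]:
    """Simulate one FASTQ library for one condition.

    Per read: a mature is sampled by abundance; independent 5' and 3'
    cleavage offsets are drawn and the corresponding hairpin substring
    excised (out-of-bounds excisions are resampled and counted); per-base
    substitution errors are applied; the 3' adapter (and, if needed, fixed
    post-adapter bases) is appended and the read truncated to ``read_len``.
    Base qualities are Q40 except for a ``low_quality_frac`` fraction of
    reads emitted at Q2 to exercise the quality filter.

    Returns (records, per-read truth table, number of resampled excisions).
    """
    cfg.validate()
    sub = truth[truth["condition"] == condition]
    mature_lookup: dict[str, tuple[Precursor, MatureAnnotation]] = {
        m.id: (prec, m) for prec in precursors for m in prec.matures
    }
    missing = set(sub["mature_id"]) - set(mature_lookup)
    if missing:
        raise SimConfigError(f"truth covers unknown matures: {sorted(missing)[:3]}")
    if set(mature_lookup) - set(sub["mature_id"]):
        raise SimConfigError("truth does not cover all matures")

    mature_ids = sub["mature_id"].to_numpy()
    probs = sub["true_abundance"].to_numpy()
    probs = probs / probs.sum()
    matures = [mature_lookup[mid] for mid in mature_ids]
    p_starts = np.array([m.p_start for _, m in matures])
    p_ends = np.array([m.p_end for _, m in matures])
    p_lens = np.array([len(prec.sequence) for prec, _ in matures])

    cond_tag = zlib.crc32(condition.encode())  # stable across processes
    rng = np.random.default_rng((cfg.seed, cond_tag, seed_offset))
    offsets = np.array(sorted(cfg.cleavage_offset_probs), dtype=np.int64)
    offset_p = np.array([cfg.cleavage_offset_probs[o] for o in offsets])
    offset_p = offset_p / offset_p.sum()

    depth = cfg.lib_depth
    k = rng.choice(len(mature_ids), size=depth, p=probs)
    o5 = offsets[rng.choice(len(offsets), size=depth, p=offset_p)]
    o3 = offsets[rng.choice(len(offsets), size=depth, p=offset_p)]
    n_resampled = 0
    while True:
        start, end = p_starts[k] + o5, p_ends[k] + o3
        bad = ~((start >= 0) & (start < end) & (end <= p_lens[k]))
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        n_resampled += n_bad
        k[bad] = rng.choice(len(mature_ids), size=n_bad, p=probs)
        o5[bad] = offsets[rng.choice(len(offsets), size=n_bad, p=offset_p)]
        o3[bad] = offsets[rng.choice(len(offsets), size=n_bad, p=offset_p)]

    low_q = rng.random(depth) < cfg.low_quality_frac

    records: list[SeqRecord] = []
    truth_rows: list[dict] = []
    hi_qual = [40] * cfg.read_len
    lo_qual = [2] * cfg.read_len
    tail = cfg.adapter3 + POST_ADAPTER
    for i in range(depth):
        prec, _ = matures[k[i]]
        insert = prec.sequence[start[i] : end[i]]
        n_err = 0
        if cfg.error_rate > 0:
            err = rng.random(len(insert)) < cfg.error_rate
            n_err = int(err.sum())
            if n_err:
                seq_arr = np.frombuffer(insert.encode(), dtype=np.uint8).copy()
                for pos in np.nonzero(err)[0]:
                    choices = _BASES[_BASES != seq_arr[pos]]
                    seq_arr[pos] = rng.choice(choices)
                insert = seq_arr.tobytes().decode("ascii")
        read = (insert + tail)[: cfg.read_len]
        rec = SeqRecord(Seq(read), id=f"{condition}.read{i + 1}", description="")
        rec.letter_annotations["phred_quality"] = (
            lo_qual if low_q[i] else hi_qual
        )[: len(read)]
        records.append(rec)
        truth_rows.append(
            {
                "read_id": rec.id,
                "mature_id": mature_ids[k[i]],
                "offset5": int(o5[i]),
                "offset3": int(o3[i]),
                "n_errors": n_err,
                "low_quality": bool(low_q[i]),
            }
        )
    return records, pd.DataFrame(truth_rows), n_resampled


def true_read_counts(read_truth: pd.DataFrame) -> pd.Series:
    """Per-miRNA read counts actually drawn into one library."""
    return read_truth.groupby("mature_id").size().rename("true_count")


def write_fastq(records: list[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fastq")


def simulate_experiment(cfg: SimConfig, outdir=None):
    """Generate precursors, truth, and one FASTQ library per condition.

    With ``outdir`` set, writes hairpin FASTA + mature GFF3 + FASTQ + truth
    TSVs and returns file paths in a manifest dict; otherwise returns the
    in-memory objects.
    """
    from . import io as iio

    precursors = make_precursors(cfg)
    truth = make_profile(precursors, cfg)
    libs = {}
    read_truths = {}
    for idx, condition in enumerate(cfg.conditions):
        records, read_truth, _ = simulate_library(
            precursors, truth, condition, cfg, seed_offset=idx
        )
        libs[condition] = records
        read_truths[condition] = read_truth
    if outdir is None:
        return precursors, truth, libs, read_truths

    import hashlib
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iio.write_precursor_fasta(precursors, outdir / "hairpins.fa")
    iio.write_mature_gff3(precursors, outdir / "matures.gff3")
    truth.to_csv(outdir / "truth_profile.tsv", sep="\t", index=False)
    paths = {
        "hairpin_fasta": str(outdir / "hairpins.fa"),
        "mature_gff3": str(outdir / "matures.gff3"),
        "truth_profile": str(outdir / "truth_profile.tsv"),
        "fastq": {},
        "read_truth": {},
    }
    for condition in cfg.conditions:
        fq = outdir / f"{condition}.fastq"
        write_fastq(libs[condition], fq)
        rt = outdir / f"{condition}.read_truth.tsv"
        read_truths[condition].to_csv(rt, sep="\t", index=False)
        paths["fastq"][condition] = str(fq)
        paths["read_truth"][condition] = str(rt)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["mature_len_range"] = list(cfg.mature_len_range)
    cfg_dict["conditions"] = list(cfg.conditions)
    cfg_dict["cleavage_offset_probs"] = {
        str(k): v for k, v in cfg.cleavage_offset_probs.items()
    }
    blob = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "paths": paths,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
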