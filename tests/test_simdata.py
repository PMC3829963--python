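"""Generator behaviour: determinism, construction invariants, read model."""

import numpy as np
import pandas as pd
import pytest

from isomirseq.preprocess import trim_adapter
from isomirseq.simdata import (
    SimConfig,
    SimConfigError,
    make_precursors,
    make_profile,
    simulate_experiment,
    simulate_library,
    true_read_counts,
)


def test_precursors_deterministic_under_fixed_seed():
    cfg = SimConfig(n_precursors=20, seed=1)
    a, b = make_precursors(cfg), make_precursors(cfg)
    assert a == b
    c = make_precursors(SimConfig(n_precursors=20, seed=2))
    assert a != c


def test_cluster_members_within_span(small_precursors, small_cfg):
    by_chrom = {}
    for p in small_precursors:
        by_chrom.setdefault(p.chrom, []).append(p)
    multi = [sorted(v, key=lambda p: p.start) for v in by_chrom.values() if len(v) > 1]
    assert multi, "generator placed no clusters"
    for chain in multi:
        for a, b in zip(chain, chain[1:]):
            assert b.start - a.end <= small_cfg.cluster_span


def test_family_members_share_seed():
    cfg = SimConfig(n_precursors=10, n_clusters=0, n_families=1, family_size=3, seed=4)
    precursors = make_precursors(cfg)
    seeds = set()
    n = 0
    for p in precursors:
        for m in p.matures:
            if m.family_id == "fam1":
                seeds.add(p.mature_sequence(m)[1:8])
                n += 1
    assert n == 3 and len(seeds) == 1


def test_mature_annotations_well_formed(small_precursors):
    for p in small_precursors:
        assert 1 <= len(p.matures) <= 2
        for m in p.matures:
            lo, hi = m.p_start, m.p_end
            assert 0 <= lo < hi <= len(p.sequence)
            expected_arm = "5p" if (lo + hi) / 2 < len(p.sequence) / 2 else "3p"
            assert m.arm == expected_arm


def test_invalid_configs_rejected():
    with pytest.raises(SimConfigError):
        make_precursors(SimConfig(n_precursors=2, n_clusters=3))
    with pytest.raises(SimConfigError):
        SimConfig(frac_de=1.5).validate()
    with pytest.raises(SimConfigError):
        SimConfig(error_rate=1.0).validate()
    with pytest.raises(SimConfigError):
        SimConfig(cleavage_offset_probs={0: 0.5, 1: 0.4}).validate()
    with pytest.raises(SimConfigError):
        SimConfig(read_len=10).validate()


def test_profile_no_de_when_frac_zero(small_precursors):
    cfg = SimConfig(n_precursors=12, n_clusters=2, n_families=1, frac_de=0.0, seed=7)
    truth = make_profile(small_precursors, cfg)
    assert (truth["true_log2fc"] == 0).all()
    assert not truth["is_de"].any()


def test_profile_de_split_and_normalisation():
    cfg = SimConfig(n_precursors=50, n_clusters=0, n_families=0, p_two_mature=0.0,
                    frac_de=0.2, seed=5)
    precursors = make_precursors(cfg)
    truth = make_profile(precursors, cfg)
    case = truth[truth["condition"] == "case"]
    assert len(case) == 50
    assert case["is_de"].sum() == 10
    assert (case["true_log2fc"] > 0).sum() == 5
    assert (case["true_log2fc"] < 0).sum() == 5
    for _, grp in truth.groupby("condition"):
        assert grp["true_abundance"].sum() == pytest.approx(1.0, abs=1e-9)
    nonde = truth[~truth["is_de"]]
    assert (nonde["true_log2fc"] == 0).all()


def test_noiseless_reads_are_canonical_matures(small_precursors, small_cfg):
    cfg = SimConfig(n_precursors=12, n_clusters=2, n_families=1, lib_depth=400,
                    seed=7, error_rate=0.0, cleavage_offset_probs={0: 1.0},
                    low_quality_frac=0.0)
    truth = make_profile(small_precursors, cfg)
    records, read_truth, n_resampled = simulate_library(
        small_precursors, truth, "case", cfg
    )
    assert len(records) == cfg.lib_depth
    assert n_resampled == 0
    canonical = {
        p.mature_sequence(m) for p in small_precursors for m in p.matures
    }
    for rec in records:
        insert, found = trim_adapter(str(rec.seq), cfg.adapter3)
        assert found and insert in canonical


def test_observed_offsets_match_model_within_3_binomial_sd():
    probs = {0: 0.6, 1: 0.2, -1: 0.2}
    cfg = SimConfig(n_precursors=20, n_clusters=0, n_families=0, lib_depth=30_000,
                    seed=9, cleavage_offset_probs=probs)
    precursors = make_precursors(cfg)
    truth = make_profile(precursors, cfg)
    _, read_truth, _ = simulate_library(precursors, truth, "control", cfg)
    n = len(read_truth)
    for col in ("offset5", "offset3"):
        freq = read_truth[col].value_counts()
        assert set(freq.index) <= set(probs)
        for off, p in probs.items():
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(freq.get(off, 0) / n - p) <= 3 * sd


def test_read_fractions_converge_to_true_abundance(small_precursors):
    cfg = SimConfig(n_precursors=12, n_clusters=2, n_families=1, lib_depth=30_000,
                    seed=13)
    truth = make_profile(small_precursors, cfg)
    _, read_truth, _ = simulate_library(small_precursors, truth, "case", cfg)
    counts = true_read_counts(read_truth)
    n = counts.sum()
    expected = truth[truth["condition"] == "case"].set_index("mature_id")[
        "true_abundance"
    ]
    for mid, p in expected.items():
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(counts.get(mid, 0) / n - p) <= 3 * sd + 1e-12


def test_simulated_experiment_files_byte_identical(tmp_path):
    cfg = SimConfig(n_precursors=8, n_clusters=1, n_families=1, lib_depth=300, seed=21)
    m1 = simulate_experiment(cfg, outdir=tmp_path / "a")
    m2 = simulate_experiment(cfg, outdir=tmp_path / "b")
    assert m1["config_sha256"] == m2["config_sha256"]
    for cond in cfg.conditions:
        a = open(m1["paths"]["fastq"][cond], "rb").read()
        b = open(m2["paths"]["fastq"][cond], "rb").read()
        assert a == b
    ta = open(m1["paths"]["truth_profile"], "rb").read()
    tb = open(m2["paths"]["truth_profile"], "rb").read()
    assert ta == tb


def test_group_coherent_profile_shares_effects(small_precursors):
    cfg = SimConfig(n_precursors=12, n_clusters=2, n_families=1, seed=7,
                    frac_de=0.5, de_respect_groups=True)
    truth = make_profile(small_precursors, cfg)
    case = truth[truth["condition"] == "case"]
    for key in ("cluster_id", "family_id"):
        for _, grp in case.dropna(subset=[key]).groupby(key):
            assert grp["true_log2fc"].nunique() == 1
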