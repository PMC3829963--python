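import numpy as np
import pytest

from isomirseq.matcher import MatureAnnotation, Precursor, assign_arm
from isomirseq.simdata import SimConfig, make_precursors, make_profile


def make_hairpin(
    mature_seq: str,
    flank5: str = "GGGGG",
    flank3: str = "TTTTT",
    pid: str = "hp-1",
    mid: str = "hp-1-5p",
    chrom: str = "chr1",
    start: int = 1000,
    strand: str = "+",
    arm: str | None = None,
) -> Precursor:
    """One-mature hairpin with the mature flanked by known sequence."""
    seq = flank5 + mature_seq + flank3
    p_start, p_end = len(flank5), len(flank5) + len(mature_seq)
    return Precursor(
        id=pid,
        sequence=seq,
        chrom=chrom,
        start=start,
        end=start + len(seq),
        strand=strand,
        matures=(
            MatureAnnotation(
                id=mid,
                arm=arm or assign_arm(p_start, p_end, len(seq)),
                p_start=p_start,
                p_end=p_end,
            ),
        ),
    )


MATURE22 = "ACGTACGTTGCAGGCATTCGAC"  # 22 nt


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_precursors=12, n_clusters=2, n_families=1, lib_depth=3000, seed=7)


@pytest.fixture(scope="session")
def small_precursors(small_cfg):
    return make_precursors(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_precursors):
    return make_profile(small_precursors, small_cfg)


def brute_force_scan(tag: str, sequence: str, max_mismatches: int):
    """Independent O(n*m) Hamming-scan oracle."""
    hits = []
    for start in range(len(sequence) - len(tag) + 1):
        mm = sum(a != b for a, b in zip(tag, sequence[start : start + len(tag)]))
        if mm <= max_mismatches:
            hits.append((start, mm))
    return hits
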