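import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aneuscore import (
    ArmCountVector,
    ArmDefinition,
    SimulationConfig,
    build_reference,
    load_arm_definitions,
    simulate_cohort,
)

SAM_HEADER = (
    "@HD\tVN:1.6\n"
    "@SQ\tSN:chr1\tLN:249250621\n"
    "@SQ\tSN:chr13\tLN:115169878\n"
    "@SQ\tSN:chrY\tLN:59373566\n"
    "@SQ\tSN:chrM\tLN:16571\n"
)


def sam_line(name, chrom, pos1, mapq, flag=0):
    """One aligned (or unmapped, flag=4) SAM record; pos1 is 1-based."""
    if flag & 4:
        return f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
    return f"{name}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t4M\t*\t0\t0\tACGT\tIIII\n"


@pytest.fixture
def write_sam(tmp_path):
    def _write(lines, name="toy.sam"):
        path = tmp_path / name
        path.write_text(SAM_HEADER + "".join(lines))
        return path

    return _write


@pytest.fixture(scope="session")
def hg19_arms():
    return load_arm_definitions()


@pytest.fixture
def toy_arms():
    """Two chromosomes' worth of toy arms, all included, plus an excluded one."""
    return [
        ArmDefinition("1", "p", 0, 100, True),
        ArmDefinition("1", "q", 100, 300, True),
        ArmDefinition("2", "p", 0, 50, True),
        ArmDefinition("2", "q", 50, 200, False),
    ]


def vec(sample_id, **counts):
    return ArmCountVector(sample_id=sample_id, counts=counts)


@pytest.fixture
def toy_panel():
    """Three-arm panel with hand-checkable statistics."""
    return [
        vec("n1", A=40, B=41, C=19),
        vec("n2", A=45, B=35, C=20),
        vec("n3", A=35, B=44, C=21),
    ]


@pytest.fixture(scope="session")
def small_cohort(hg19_arms):
    """One seeded default-condition cohort shared across tests."""
    cfg = SimulationConfig(n_patients=120, seed=2024)
    return simulate_cohort(cfg, hg19_arms)


@pytest.fixture(scope="session")
def scored_cohort(small_cohort):
    from aneuscore import score_cohort
    from aneuscore.cli_io import join_scores_clinical
    from aneuscore.scoring import scores_frame

    panel = build_reference(small_cohort.reference)
    results = score_cohort(small_cohort.arm_counts, panel)
    df = join_scores_clinical(small_cohort.clinical, scores_frame(results))
    return df
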