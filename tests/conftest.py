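import numpy as np
import pytest

from sclc_taxonomy import synthetic as syn
from sclc_taxonomy.preprocess import counts_to_log_tpm


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at generator defaults (the study conditions)."""
    cfg = syn.CohortConfig()
    counts, lengths, truth, clinical = syn.generate_cohort(cfg)
    return {
        "config": cfg,
        "counts": counts,
        "lengths": lengths,
        "truth": truth,
        "clinical": clinical,
        "logtpm": counts_to_log_tpm(counts, lengths),
    }


@pytest.fixture(scope="session")
def balanced_cohort():
    """Smaller cohort with equal subtype prevalences (for per-subtype tests)."""
    cfg = syn.CohortConfig(
        n_samples=72,
        n_genes=500,
        subtype_proportions=(1 / 6,) * 6,
        seed=11,
    )
    counts, lengths, truth, clinical = syn.generate_cohort(cfg)
    return {
        "config": cfg,
        "counts": counts,
        "lengths": lengths,
        "truth": truth,
        "clinical": clinical,
        "logtpm": counts_to_log_tpm(counts, lengths),
    }


@pytest.fixture(scope="session")
def mouse_timecourse(default_cohort):
    truth = default_cohort["truth"]
    shared = sorted(
        truth.programs["NE"] | truth.programs["NONNE"] | truth.programs["EMT"]
    ) + [f"HK_{i:03d}" for i in range(60)]
    cfg = syn.TimeCourseConfig(n_cells=360, seed=5)
    tc = syn.generate_mouse_timecourse(cfg, shared, truth.programs)
    return {"config": cfg, "tc": tc, "truth": truth, "shared": shared}
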