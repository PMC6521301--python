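import numpy as np
import pytest

from grspipe import SimulationConfig, classify_responders, compute_grs, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (191 participants, 103 SNPs, seed 11)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def classified(default_cohort):
    return classify_responders(default_cohort.phenotypes)


@pytest.fixture(scope="session")
def responder_flags(default_cohort, classified):
    aligned = classified.table.set_index("participant_id").reindex(
        default_cohort.genotypes.participant_ids
    )
    return aligned["responder"].to_numpy(dtype=bool)


def truth_grs(cohort, panel_name="truth"):
    """GRS over the planted causal panel with the true risk directions."""
    dirs = {t["rsid"]: t["risk_direction"] for t in cohort.truth["causal_snps"]}
    return compute_grs(cohort.genotypes, dirs, panel_name=panel_name)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
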