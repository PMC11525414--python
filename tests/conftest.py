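import numpy as np
import pytest

from analogue_report import DesignSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240708)


@pytest.fixture(scope="session")
def small_cohort():
    """Two synthetic observers on a reduced design (no delay, one chroma)."""
    design = DesignSpec(delays_ms=(0,), chroma_radii=(25,))
    analogue, afc, psi_log = simulate_cohort(2, design=design, seed=11)
    return {"design": design, "analogue": analogue, "afc": afc,
            "psi_log": psi_log}


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    small_cohort["analogue"].to_csv(out / "analogue_trials.csv", index=False)
    small_cohort["afc"].to_csv(out / "afc_trials.csv", index=False)
    return out
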