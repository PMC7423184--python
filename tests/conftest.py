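import numpy as np
import pytest

from exomod.datatypes import N_PREDICTORS, PredictionProfile
from exomod.simulate import SimConfig, simulate_cohort


def make_profile(
    n_damaging: int,
    n_unknown: int = 0,
    func_class: str = "nonsynonymous",
    siphy29: float | None = 10.0,
    afr_freq: float | None = 0.0,
    eur_freq: float | None = None,
) -> PredictionProfile:
    """Profile with an exact damaging / unknown verdict composition."""
    verdicts = (
        ["damaging"] * n_damaging
        + ["unknown"] * n_unknown
        + ["tolerated"] * (N_PREDICTORS - n_damaging - n_unknown)
    )
    return PredictionProfile(
        verdicts=tuple(verdicts),
        siphy29=siphy29,
        func_class=func_class,
        afr_freq=afr_freq,
        eur_freq=eur_freq,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated cohort shared by read-only tests."""
    cfg = SimConfig(
        n_per_group={"long_survivor": 8, "stroke": 8, "random": 10, "control": 10},
        n_genes=6,
        theta=30,
        variants_per_gene=(5, 80),
        missing_rate=0.05,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
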