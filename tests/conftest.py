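import numpy as np
import pandas as pd
import pytest

from hipce.registry import CohortSpec, HazardSpec


def make_weibull_data(
    n=5000, shape=1.4, scale=12.0, censor_at=8.0, seed=0
) -> pd.DataFrame:
    """Weibull event times with administrative censoring (~30% at defaults)."""
    rng = np.random.default_rng(seed)
    t_event = scale * rng.weibull(shape, size=n)
    censor = rng.uniform(0.0, 2.0 * censor_at, size=n)
    revised = (t_event <= censor).astype(int)
    time = np.minimum(t_event, censor)
    return pd.DataFrame({"followup_time": np.maximum(time, 1e-9), "revised": revised})


@pytest.fixture(scope="session")
def weibull_data() -> pd.DataFrame:
    return make_weibull_data()


@pytest.fixture(scope="session")
def small_registry() -> pd.DataFrame:
    from hipce.registry import generate_registry

    spec = CohortSpec(n_patients=4000, seed=42)
    return generate_registry(spec)


def single_stratum_spec(n, family, params, head_sizes=None, window=15.0, seed=None):
    """Male-only, one-manufacturer cohort with a single true hazard."""
    hs = head_sizes or {50: 1.0}
    return CohortSpec(
        n_patients=n,
        registry_window=window,
        seed=seed,
        sex_probs={"male": 1.0, "female": 0.0},
        asa_probs={1: 0.5, 2: 0.5},
        device_class_probs={"RS": 1.0, "THR": 0.0},
        manufacturer_probs={"BirminghamHip": 1.0},
        head_size_probs={"male": hs, "female": {44: 1.0}},
        hazards={"RS": HazardSpec(family=family, params=dict(params))},
    )
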