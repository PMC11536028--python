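import numpy as np
import pytest

from ptaupet.cohort import ParticipantRecord, default_config, generate_cohort
from ptaupet.composites import all_required_regions
from ptaupet.thresholds import build_threshold_set

REGIONS = sorted(all_required_regions())


def make_record(
    id: str = "X001",
    group: str = "CU",
    centiloid: float = 0.0,
    ptau217: float = 0.1,
    suvr_value: float = 1.0,
    suvr_overrides: dict | None = None,
    **kwargs,
) -> ParticipantRecord:
    """A minimal valid participant with a flat SUVR profile."""
    suvr = {region: suvr_value for region in REGIONS}
    if suvr_overrides:
        suvr.update(suvr_overrides)
    defaults = dict(age=72.0, sex="female", apoe4=False)
    defaults.update(kwargs)
    return ParticipantRecord(
        id=id,
        group=group,
        centiloid=centiloid,
        ptau217=ptau217,
        regional_suvr=suvr,
        **defaults,
    )


def reference_stratum(n: int = 20, rng_seed: int = 0) -> list[ParticipantRecord]:
    """Amyloid-negative CU records with mildly noisy baseline SUVR."""
    rng = np.random.default_rng(rng_seed)
    records = []
    for i in range(n):
        noise = {r: float(1.0 + rng.normal(0, 0.05)) for r in REGIONS}
        records.append(
            make_record(
                id=f"R{i:03d}", group="CU", centiloid=-2.0, suvr_overrides=noise
            )
        )
    return records


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def default_thresholds(default_cohort):
    return build_threshold_set(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = default_config(seed=5)
    cfg.n_per_group = {"CU": 70, "MCI": 40, "dementia": 50}
    return generate_cohort(cfg)
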