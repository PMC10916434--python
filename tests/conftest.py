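import numpy as np
import pandas as pd
import pytest

from covnet.synthetic import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_table(data: np.ndarray, regions, group: str = "G", start: int = 1) -> pd.DataFrame:
    """Wrap an (n_subjects, K) array as an uptake table for one group."""
    frame = pd.DataFrame(np.asarray(data, dtype=float), columns=list(regions))
    frame.insert(0, "group", group)
    frame.insert(0, "subject_id", [f"{group}{start + i:02d}" for i in range(len(frame))])
    return frame


@pytest.fixture
def small_spec():
    """Two groups, 4 regions + reference, one strong planted edge in group A."""
    regions = ("r1", "r2", "r3", "r4", "cerebellum")
    corr_a = np.eye(5)
    corr_a[0, 1] = corr_a[1, 0] = 0.9
    return CohortSpec(
        group_names=("A", "B"),
        n_per_group=8,
        region_names=regions,
        mean_uptake=np.full(5, 2.0),
        correlation={"A": corr_a, "B": np.eye(5)},
        noise_sd=0.2,
        seed=11,
    )
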