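import numpy as np
import pytest

import fcbands as fc
from fcbands.network import SampleDataset


@pytest.fixture(scope="session")
def aal90():
    return fc.load_aal90()


@pytest.fixture
def linear_spec():
    return fc.ClassifierSpec()


def make_feature_dataset(X: np.ndarray, y: np.ndarray,
                         band: str = "test", normalized: bool = True
                         ) -> SampleDataset:
    """Wrap a raw K x P matrix as a SampleDataset with a dummy feature map."""
    P = X.shape[1]
    # dummy map over a star graph: (1,2), (1,3), ... enough distinct pairs
    fmap = tuple((1, j + 2) for j in range(P))
    return SampleDataset(X=X, y=y, feature_map=fmap, band=band,
                         normalized=normalized)


@pytest.fixture
def small_planted_cohort():
    """19/20 cohort, 8 regions, one strong slow-5 edge between regions 1-2."""
    design = fc.CohortDesign(
        n_patients=19, n_controls=20, n_regions=8, n_timepoints=170,
        planted_edges=(fc.PlantedEdge(1, 2, fc.SLOW5, 0.8, -0.8),),
        seed=11,
    )
    return fc.generate_cohort(design)
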