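import numpy as np
import pytest

from landgen.genetics import DistanceMatrix, GenotypeTable
from landgen.raster import FeatureLayer, RasterGrid, ResistanceSurface


@pytest.fixture
def grid5() -> RasterGrid:
    return RasterGrid(np.ones((5, 5)), 30.0)


@pytest.fixture
def toy_genotypes() -> GenotypeTable:
    """4 individuals x 2 loci, hand-checkable allele sharing."""
    calls = np.array(
        [
            [[1, 1], [2, 3]],
            [[1, 2], [2, 2]],
            [[2, 2], [3, 3]],
            [[1, 2], [2, 3]],
        ]
    )
    coords = np.array([[0.0, 0.0], [3.0, 4.0], [10.0, 0.0], [0.0, 10.0]])
    return GenotypeTable(list("abcd"), ["L1", "L2"], calls, coords)


def random_distance_matrix(n: int, rng, kind: str = "geographic") -> DistanceMatrix:
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix([f"i{k}" for k in range(n)], m, kind)


def random_surface(shape, rng, low=1.0, high=20.0) -> ResistanceSurface:
    vals = rng.uniform(low, high, size=shape)
    return ResistanceSurface(RasterGrid(vals, 30.0))


def feature_from_mask(mask, name="feat", role="barrier") -> FeatureLayer:
    mask = np.asarray(mask, dtype=float)
    return FeatureLayer(name, RasterGrid(mask, 30.0), role)
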