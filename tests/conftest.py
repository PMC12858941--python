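import numpy as np
import pandas as pd
import pytest

from traitscape.grids import GridSpec
from traitscape.synthetic import CommunityField, SpeciesPool


def make_pool(traits: dict[str, list[float]], optima: dict[str, list[float]] | None = None,
              breadths: dict[str, list[float]] | None = None) -> SpeciesPool:
    """Hand-built species pool for exact-value tests."""
    n = len(next(iter(traits.values())))
    binomials = [f"genus{i:02d} species{i:02d}" for i in range(n)]
    optima = optima or {"env_0": list(np.zeros(n))}
    breadths = breadths or {a: [1.0] * n for a in optima}
    return SpeciesPool(
        binomials=binomials,
        traits=pd.DataFrame(traits, index=binomials),
        niche_optima=pd.DataFrame(optima, index=binomials),
        niche_breadths=pd.DataFrame(breadths, index=binomials),
    )


def make_community(grid: GridSpec, covers: np.ndarray, binomials=None) -> CommunityField:
    """CommunityField from an explicit (n_species, n_rows, n_cols) cover array."""
    covers = np.asarray(covers, dtype=float)
    if binomials is None:
        binomials = [f"genus{i:02d} species{i:02d}" for i in range(covers.shape[0])]
    return CommunityField(grid=grid, binomials=list(binomials), cover=covers)


@pytest.fixture
def grid4() -> GridSpec:
    return GridSpec(0.0, 0.0, 1.0, 4, 4)


@pytest.fixture
def two_species_world(grid4):
    """Two species with constant covers (0.6, 0.4) everywhere, traits (5, 20)."""
    pool = make_pool({"t": [5.0, 20.0]})
    cover = np.empty((2, 4, 4))
    cover[0], cover[1] = 0.6, 0.4
    comm = make_community(grid4, cover, pool.binomials)
    return pool, comm
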