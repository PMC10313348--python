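import numpy as np
import pytest
from hypothesis import settings

from specidx import fixtures as fx
from specidx import index as idx
from specidx import search as srch

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_fixture():
    """The standard benchmark fixture: 2000 target spectra (incl. an
    entrapment share) + 2000 decoys, 500 moderately noisy queries."""
    return fx.make_fixture(fx.FixtureConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def small_fixture():
    """A light fixture for unit tests (150 library spectra, 40 queries)."""
    return fx.make_fixture(
        fx.FixtureConfig(
            seed=11,
            n_proteins=16,
            n_entrap_proteins=6,
            n_library=150,
            n_queries=40,
        )
    )


@pytest.fixture(scope="session")
def default_indexes(default_fixture, tmp_path_factory):
    root = tmp_path_factory.mktemp("idx_default")
    cfg = idx.IndexConfig(n_partitions=4)
    idx.build_index(default_fixture.target_spectra, cfg, root / "target")
    idx.build_index(default_fixture.decoy_spectra, cfg, root / "decoy")
    return root / "target", root / "decoy"


@pytest.fixture(scope="session")
def default_search(default_fixture, default_indexes):
    params = srch.SearchParams()
    rt = srch.search_spectra(
        default_fixture.queries, default_indexes[0], params
    )
    rd = srch.search_spectra(
        default_fixture.queries, default_indexes[1], params
    )
    return rt, rd


@pytest.fixture(scope="session")
def small_index(small_fixture, tmp_path_factory):
    root = tmp_path_factory.mktemp("idx_small")
    idx.build_index(
        small_fixture.target_spectra,
        idx.IndexConfig(n_partitions=4),
        root / "target",
    )
    return root / "target"


def random_unit_spectrum(rng, n_peaks=None, mz_range=(100.0, 1300.0)):
    """A preprocessed random spectrum for scoring tests."""
    from specidx.spectra_io import Spectrum, preprocess

    n = int(n_peaks if n_peaks is not None else rng.integers(3, 60))
    mz = np.sort(rng.uniform(*mz_range, size=n))
    inten = rng.uniform(0.05, 1.0, size=n)
    return preprocess(
        Spectrum.from_peaks("rnd", 500.0, 2, mz, inten)
    )
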