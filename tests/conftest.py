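import numpy as np
import pytest

from qtlci.cim import ScanSettings, build_scan_plan
from qtlci.genmap import benchmark_map, place_qtls
from qtlci.io import make_fixture
from qtlci.popsim import dataset_rng, make_dataset


@pytest.fixture(scope="session")
def bmap():
    return benchmark_map()


@pytest.fixture(scope="session")
def bplan(bmap):
    return build_scan_plan(bmap, walk=1.0)


@pytest.fixture(scope="session")
def settings():
    return ScanSettings()


@pytest.fixture(scope="session")
def tiny_one_qtl():
    """2 chromosomes x 5 markers, n=60, one strong QTL at a marker."""
    return make_fixture("tiny-one-qtl")


@pytest.fixture(scope="session")
def tiny_null():
    return make_fixture("tiny-null")


@pytest.fixture(scope="session")
def benchmark_dataset(bmap):
    """One benchmark dataset with QTL at the left flanking markers (D=0)."""
    return make_dataset(bmap, place_qtls(bmap, 0.0, 1.0), 200, 0.6, dataset_rng(11, 0))


def brute_force_lod(y, x, covariates=None):
    """Independent OLS oracle for the LOD score, via lstsq residuals."""
    y = np.asarray(y, float)
    n = len(y)
    C0 = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        C0 = np.hstack([C0, cov])
    C1 = np.hstack([C0, np.asarray(x, float)[:, None]])
    r0 = y - C0 @ np.linalg.lstsq(C0, y, rcond=None)[0]
    r1 = y - C1 @ np.linalg.lstsq(C1, y, rcond=None)[0]
    rss0, rss1 = float(r0 @ r0), float(r1 @ r1)
    return (n / 2.0) * np.log10(rss0 / rss1)
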