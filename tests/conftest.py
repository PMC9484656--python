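import numpy as np
import pytest

from domaindyn.domains import DomainMap, Segment
from domaindyn.ensembles import Ensemble


def toy_ensemble(coords, resids=None, names=None, elements=None,
                 masses=None, times=None, resnames=None, charges=None, **labels):
    """Hand-built ensemble from a coordinate array (frames, atoms, 3) in nm."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    return Ensemble(
        names=np.array(names if names is not None else ["CA"] * n),
        elements=np.array(elements if elements is not None else ["C"] * n),
        resids=np.array(resids if resids is not None else np.arange(1, n + 1)),
        resnames=np.array(resnames if resnames is not None else ["ALA"] * n),
        masses=np.array(masses if masses is not None else np.ones(n)),
        coords=coords,
        charges=None if charges is None else np.asarray(charges, float),
        times=None if times is None else np.asarray(times, float),
        **labels,
    )


def flat_map(n_residues, segment_size=1, first=1):
    """Map where every residue (or block) is its own segment: nothing excluded
    as same-segment except residue self-pairs."""
    segs = []
    r = first
    i = 0
    while r <= first + n_residues - 1:
        end = min(r + segment_size - 1, first + n_residues - 1)
        segs.append(Segment(f"seg{i}", ((r, end),), "domain"))
        r = end + 1
        i += 1
    return DomainMap(segs)


@pytest.fixture(scope="session")
def fixture_spec():
    from domaindyn.synthetic import atp7b_fixture
    return atp7b_fixture(n_frames=40, n_replicas=2, seed=11)


@pytest.fixture(scope="session")
def fixture_sets(fixture_spec):
    from domaindyn.synthetic import generate_ensembles
    return generate_ensembles(fixture_spec)
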