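import numpy as np
import pytest

from edgemetrics import EdgeMap


def random_map(rng, shape, n_points, nonempty=False):
    """A map with up to n_points uniformly placed marked pixels."""
    pts = {tuple(p) for p in rng.integers(0, shape, size=(n_points, 2))}
    if nonempty and not pts:
        pts = {(int(rng.integers(0, shape[0])), int(rng.integers(0, shape[1])))}
    return EdgeMap.from_points(shape, pts)


def random_pair(rng, max_side=32, max_points=20, overlap=0.5):
    """A validated (gt, dc) pair; dc shares roughly `overlap` of gt's pixels."""
    shape = tuple(int(s) for s in rng.integers(4, max_side + 1, size=2))
    gt = random_map(rng, shape, int(rng.integers(1, max_points)), nonempty=True)
    coords = gt.coords()
    keep = coords[rng.random(len(coords)) < overlap]
    extra = rng.integers(0, shape, size=(int(rng.integers(0, max_points)), 2))
    dc_pts = {tuple(p) for p in keep} | {tuple(p) for p in extra}
    dc = EdgeMap.from_points(shape, dc_pts)
    return gt, dc


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
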