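import numpy as np
import pytest

from fibretrack.model import LineageNode, LineageTree, Track


def make_track(points, cell_id="a", dt=3.0, **kw):
    """Track from a list of (x, y[, z]) tuples at consecutive frames."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] == 2:
        pts = np.hstack([pts, np.zeros((len(pts), 1))])
    return Track(
        cell_id=cell_id, dt=dt, frames=np.arange(len(pts)), xyz=pts, **kw
    )


@pytest.fixture
def simple_division_lineage():
    """One mother dividing at t=30 min into two daughters."""
    lin = LineageTree()
    lin.add(LineageNode("m", None, 0.0, 30.0, "division", "negative"))
    lin.add(LineageNode("d1", "m", 30.0, 90.0, "censored", "negative"))
    lin.add(LineageNode("d2", "m", 30.0, 90.0, "censored", "positive"))
    lin.validate()
    return lin
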