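import numpy as np
import pytest
from shapely.geometry import box

import popweave as pw


@pytest.fixture(scope="session")
def bundle():
    """Default noiseless synthetic scenario, built once per session."""
    return pw.build_bundle(pw.SyntheticScenario(seed=7))


def make_grid(n_rows, n_cols, cell=1.0, nodata=255):
    """Unit-cell grid with origin at the top-left corner, y down from n_rows."""
    return pw.GridSpec(n_rows, n_cols, 0.0, n_rows * cell, cell, nodata_code=nodata)


def cat(grid, values, legend=None):
    return pw.CategoricalRaster(grid, np.asarray(values, dtype=np.int32), legend or {})


def cell_box(grid, r0, r1, c0, c1):
    """Rectangle covering cell rows [r0, r1) and columns [c0, c1)."""
    s = grid.cell_size
    return box(
        grid.origin_x + c0 * s,
        grid.origin_y - r1 * s,
        grid.origin_x + c1 * s,
        grid.origin_y - r0 * s,
    )
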