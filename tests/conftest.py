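import numpy as np
import pytest

import stereogold as sg


@pytest.fixture(scope="session")
def validation_spec() -> sg.BundleSpec:
    """The standard validation bundle: 5 columns, all four rows, one bead per
    stereocilium in the row-specific pattern."""
    return sg.BundleSpec()


@pytest.fixture(scope="session")
def validation_cell(tmp_path_factory, validation_spec):
    """A complete synthetic cell folder on disk, with ground truth."""
    cell_dir = tmp_path_factory.mktemp("cells") / "CellV"
    gt = sg.write_cell_folder(validation_spec, cell_dir)
    return cell_dir, gt


@pytest.fixture(scope="session")
def analyzed_cell(validation_cell):
    """The validation cell after a full per-cell analysis.

    The fixture volume is generated at the working resolution the real data
    reach after the default 4x downsampling, so the analysis itself runs
    with resize_factor=1.
    """
    cell_dir, gt = validation_cell
    config = sg.AnalysisConfig(resize_factor=1.0)
    results = sg.analyze_cell(cell_dir, config, make_figures=True)
    return cell_dir, gt, results


@pytest.fixture(scope="session")
def small_borders():
    """Border samples of a small unrotated bundle (coplanar bases), for
    orientation tests: dict tower id -> (n, 3) um points."""
    spec = sg.BundleSpec(n_columns=4, rows=(2, 3, 4), rng_seed=3)
    towers, _, _, _, gt = sg.generate_bundle(spec)
    borders = sg.sample_tower_borders(towers, factor=0.02, seed=0)
    assert all(len(p) >= 10 for p in borders.values())
    return borders, gt


def rigid_rotate_borders(borders, axis, angle):
    """Rotate every tower's border points by the same rotation (about the
    pooled centroid, so the scene stays near the origin)."""
    allpts = np.vstack(list(borders.values()))
    c = allpts.mean(axis=0)
    return {
        tid: sg.rodrigues_rotate(p - c, axis, angle) + c for tid, p in borders.items()
    }
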