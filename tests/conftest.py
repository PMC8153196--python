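import numpy as np
import pytest

from maxenm.maxent import FeatureConfig, build_feature_matrix, default_regularization, fit_maxent
from maxenm.occurrences import build_M, filter_by_uncertainty, spatial_thin, split_calibration_evaluation
from maxenm.selection import background_values, occurrence_values
from maxenm.synthetic import default_virtual_species


@pytest.fixture(scope="session")
def small_species():
    """Default virtual species at a small grid; shared read-only."""
    stack, vs, suit, occ = default_virtual_species(seed=11, grid_rows=40, grid_cols=40, n_presences=150)
    return stack, vs, suit, occ


@pytest.fixture(scope="session")
def calibration_data(small_species):
    """Cleaned/thinned/split occurrences with M and marshalled tables."""
    stack, vs, suit, occ = small_species
    occ2 = spatial_thin(filter_by_uncertainty(occ), 20.0, seed=5)
    cal, ev = split_calibration_evaluation(occ2, seed=6)
    area = build_M(occ2, stack, 3.0)
    names = stack.layer_names
    pres = occurrence_values(cal, stack, names)
    bg = background_values(stack, area, names, max_cells=1500, seed=7)
    return dict(stack=stack, occ=occ2, cal=cal, ev=ev, area=area, names=names, pres=pres, bg=bg)


@pytest.fixture(scope="session")
def fitted_lqp(calibration_data):
    """One converged mid-regularization fit reused across checks."""
    d = calibration_data
    fm = build_feature_matrix(d["pres"], d["bg"], d["names"], FeatureConfig(classes=("L", "Q", "P")))
    lam = default_regularization(fm.meta, fm.presence, fm.presence.shape[0], 1.0)
    return fit_maxent(fm, lam, rm=1.0), fm, lam
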