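import numpy as np
import pytest

import drugscreen as ds


@pytest.fixture
def unit_hill_curve():
    """Exact LL4 curve: top 100, bottom 0, IC50 10 nM, unit slope."""
    return ds.DoseResponseCurve(model="LL4", top=100.0, bottom=0.0,
                                slope=1.0, midpoint=10.0,
                                conc_range=(0.1, 10000.0))


@pytest.fixture
def drug_panel():
    """A small panel spanning potent to weak drugs."""
    return [ds.GroundTruthProfile("bortezomib", ic50=10.0),
            ds.GroundTruthProfile("dexamethasone", ic50=50.0),
            ds.GroundTruthProfile("panobinostat", ic50=100.0),
            ds.GroundTruthProfile("carfilzomib", ic50=3.0),
            ds.GroundTruthProfile("melflufen", ic50=300.0),
            ds.GroundTruthProfile("venetoclax", ic50=1.0)]


@pytest.fixture
def quiet():
    return ds.NoiseModel(cv=0.0, seed=0)


def dss_trapezoid_oracle(curve, conc_range, t=10.0, n=100_000):
    """Independent brute-force quadrature of the DSS definition."""
    x_min, x_max = np.log10(conc_range[0]), np.log10(conc_range[1])
    x = np.linspace(x_min, x_max, n)
    ih = np.clip(curve.inhibition(10.0 ** x), 0.0, 100.0)
    integrand = np.where(ih >= t, ih - t, 0.0)
    # zero out everything before the first threshold crossing
    above = ih >= t
    if not above.any():
        return 0.0
    first = np.argmax(above)
    integrand[:first] = 0.0
    area = np.trapezoid(integrand, x)
    return 100.0 * area / ((100.0 - t) * (x_max - x_min))
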