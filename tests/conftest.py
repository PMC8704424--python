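import numpy as np
import pytest

import stimlimit as sl


@pytest.fixture(scope="session")
def geom10():
    return sl.ElectrodeGeometry(diameter_um=10.0)


@pytest.fixture(scope="session")
def geom20():
    return sl.ElectrodeGeometry(diameter_um=20.0)


@pytest.fixture(scope="session")
def geom30():
    return sl.ElectrodeGeometry(diameter_um=30.0)


@pytest.fixture(scope="session")
def rc_circuit(geom10):
    """Linear electrode: 100 kΩ access, 25 nF total polarization capacitance."""
    return sl.ElectrodeCircuitParams(
        access_resistance_ohm=1e5,
        c_specific_F_cm2=25e-9 / sl.disk_area(geom10),
        cv_anodic=sl.CVProfile(baseline_F_cm2=1e-3),
        cv_cathodic=sl.CVProfile(baseline_F_cm2=1e-3),
    )


@pytest.fixture(scope="session")
def sirof_circuit():
    return sl.circuit_from_preset("fig2_electrode")


def make_curve(levels, probs, counts, cic=100.0, **kw):
    """Assemble a ResponseCurve directly from per-level statistics."""
    import pandas as pd

    table = pd.DataFrame(
        {
            "charge_nC": levels,
            "response_probability": probs,
            "mean_evoked_spikes": counts,
            "sd_evoked_spikes": 0.0,
            "n_trials": 5,
            "in_cic": [q <= cic for q in levels],
        }
    )
    return sl.ResponseCurve(table=table, cic_limit_nC=cic, **kw)


@pytest.fixture(scope="session")
def curve_factory():
    return make_curve
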