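import numpy as np
import pytest

from pkquant import calibration, synthetic
from pkquant.nca import ConcentrationTimeProfile


@pytest.fixture
def noise_free_curve():
    """Exact calibration line fitted on 6 noise-free standards."""
    plate = synthetic.simulate_calibration_plate(noise_cv=0.0, is_cv=0.0)
    standards = [
        calibration.CalibrationStandard(
            nominal=r.nominal_ng_per_ml,
            analyte_response=r.analyte_response,
            is_response=r.is_response,
        )
        for r in plate.itertuples()
    ]
    return calibration.fit_calibration(standards)


def make_profile(times, concs, route="iv_bolus", blq=None, subject_id="s1",
                 dose_per_kg=2.0, body_weight=0.02):
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if blq is None:
        blq = np.zeros(times.size, dtype=bool)
    return ConcentrationTimeProfile(
        subject_id=subject_id,
        route=route,
        dose_per_kg=dose_per_kg,
        body_weight=body_weight,
        times=times,
        concs=concs,
        blq=np.asarray(blq, dtype=bool),
    )


@pytest.fixture
def dense_iv_profile():
    """Noise-free one-compartment IV curve, 1-min sampling over 5 half-lives."""
    k = 0.01
    c0 = 4000.0
    t_end = 5 * np.log(2) / k
    t = np.arange(0.0, t_end + 1.0, 1.0)
    return make_profile(t, c0 * np.exp(-k * t)), k, c0
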