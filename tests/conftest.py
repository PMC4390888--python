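import numpy as np
import pytest

import superfill as sf


@pytest.fixture(scope="session")
def rv_by_renzyme():
    """r_V of the carbonic anhydrase / CFDA simulation for the three
    enzyme-partitioning regimes (computed once per session)."""
    out = {}
    for r in (0.33, 1.0, 3.0):
        trace = sf.simulate_two_compartment(sf.TwoCompartmentConfig(r_enzyme=r))
        out[r] = sf.extract_rate_ratio(trace)
    return out


@pytest.fixture(scope="session")
def pipeline_recovery():
    """End-to-end synthetic pipeline: generate a 10^4-vesicle population
    across frames, render, detect, measure; aggregate truth vs recovery."""
    rng = np.random.default_rng(20250929)
    cal = sf.CalibrationCurve.for_background(1e-6)
    truth_rf, measured_rf = [], []
    n_total = n_detected = n_false = 0
    for _ in range(50):
        pop = sf.PopulationConfig(
            n_vesicles=200,
            solute=sf.SoluteSpec("bsa-fitc", 1e-6),
            seed=int(rng.integers(2**31)),
        )
        records = sf.sample_population(pop)
        frame = sf.render_frame(records, 1e-6, cal, seed=int(rng.integers(2**31)))
        meas = sf.measure_frame(frame, 0.2)
        match = sf.detectable_fraction(records, meas)
        truth_rf += [r.r_f_true for r in records if r.is_superfilled]
        measured_rf += [m.r_f for m in meas]
        n_total += len(records)
        n_detected += len(meas)
        n_false += match["false_positives"]
    return {
        "n_total": n_total,
        "n_detected": n_detected,
        "n_false_positives": n_false,
        "detected_fraction": n_detected / n_total,
        "true_mean_rf_superfilled": float(np.mean(truth_rf)),
        "recovered_mean_rf": float(np.mean(measured_rf)),
        "n_superfilled_true": len(truth_rf),
    }
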