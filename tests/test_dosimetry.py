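import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdadose.calibration import DoseCalibrator
from pdadose.dosimetry import (
    ControlStats,
    ExposureDetector,
    detect_exposure,
    estimate_dose,
    evaluate_accuracy,
    fit_control_stats,
    ppm_to_mg_per_m3,
    project,
)
from pdadose.schedule import ExposureSchedule
from pdadose.sensor_model import (
    GeneratorConfig,
    fingerprints_and_doses,
    generate_training_set,
    simulate_control_fingerprints,
    simulate_fingerprint,
)


@pytest.fixture(scope="module")
def fitted():
    cfg = GeneratorConfig(seed=11)
    concs, n_rep, n_days, hours = cfg.calibration_design
    X, y = fingerprints_and_doses(
        generate_training_set(concs, n_days, n_rep, cfg, hours_per_day=hours)
    )
    return cfg, DoseCalibrator().fit(X, y)


@pytest.fixture(scope="module")
def noise_free_model(config):
    concs, _, n_days, hours = config.calibration_design
    obs = []
    for c in concs:
        sched = ExposureSchedule.constant(c, n_days, hours)
        for d in range(1, n_days + 1):
            obs.append((simulate_fingerprint(sched, config, upto_day=d), c * hours * d))
    X = np.array([o[0] for o in obs])
    y = np.array([o[1] for o in obs])
    return DoseCalibrator().fit(X, y)


# -- projection -------------------------------------------------------------


def test_project_mean_is_origin(fitted):
    _, model = fitted
    assert project(model.mean_, model) == pytest.approx((0.0, 0.0), abs=1e-9)


def test_project_unit_loading_displacement(fitted):
    _, model = fitted
    fp = model.mean_ + 5.0 * model.components_[0]
    pc1, pc2 = project(fp, model)
    assert pc1 == pytest.approx(5.0, abs=1e-9)
    assert pc2 == pytest.approx(0.0, abs=1e-9)


def test_pc1_displacement_matches_drift_scale(config, noise_free_model):
    """A noise-free 20 ppm day-1 patch sits 2.14/h x 8 h along PC1 from the
    unexposed baseline."""
    fp = simulate_fingerprint(ExposureSchedule.constant(20, 1), config)
    disp = noise_free_model.pc1_displacement(fp.reshape(1, -1))[0]
    assert disp == pytest.approx(17.12, abs=0.02)


# -- dose estimation --------------------------------------------------------


def test_exact_inversion_single_concentration():
    """Noise-free single-mode, single-concentration calibration inverts
    exactly (the response is a perfect line along u)."""
    cfg = GeneratorConfig(secondary_variance_ratio=0.0)
    sched = ExposureSchedule.constant(20, 14)
    X = np.array(
        [simulate_fingerprint(sched, cfg, upto_day=d) for d in range(1, 15)]
    )
    y = np.array([20.0 * 8 * d for d in range(1, 15)])
    model = DoseCalibrator().fit(X, y)
    fp = simulate_fingerprint(ExposureSchedule.constant(20, 1), cfg)  # 160 ppm·h
    est = estimate_dose(fp, model)
    assert est.dose == pytest.approx(160.0, abs=1e-6)
    assert est.twa == pytest.approx(est.dose / 8.0, abs=1e-12)


def test_zero_fingerprint_reads_zero_dose(fitted):
    cfg, model = fitted
    ctrl = fit_control_stats(
        simulate_control_fingerprints(24, cfg, np.random.default_rng(0)), model
    )
    est = estimate_dose(np.zeros(12), model, control_stats=ctrl)
    assert est.dose == pytest.approx(0.0, abs=1.5)
    assert not est.exposed


def test_noise_free_end_to_end_error_below_eight_percent(config, noise_free_model):
    """Held-out noise-free patches invert within 8% at every concentration
    and day; the residual is the non-proportionality of the rate table."""
    for c in (10, 20, 40):
        sched = ExposureSchedule.constant(c, 14)
        for d in range(1, 15):
            fp = simulate_fingerprint(sched, config, upto_day=d)
            est = estimate_dose(fp, noise_free_model)
            truth = c * 8 * d
            assert abs(est.dose - truth) / truth <= 0.08


def test_dose_monotone_in_pc1_and_clamped(fitted, rng):
    _, model = fitted
    u = model.components_[0]
    doses = [
        estimate_dose(model.mean_ + t * u, model).dose for t in np.linspace(-300, 300, 41)
    ]
    assert all(b >= a for a, b in zip(doses, doses[1:]))
    assert min(doses) >= 0.0
    # strongly negative projections clamp to zero but keep the raw value
    est = estimate_dose(model.mean_ - 300 * u, model)
    assert est.dose == 0.0 and est.raw_dose < 0


# -- detection --------------------------------------------------------------


def test_margin_at_threshold_reads_unexposed(fitted):
    """Exactly at the threshold the patch reads unexposed (strict >)."""
    _, model = fitted
    # score of mean_ is exactly 0.0; fallback threshold -1 + 1 = 0 exactly
    ctrl = ControlStats(mean=-1.0, sd=0.0, n=5)
    with pytest.warns(UserWarning, match="absolute threshold"):
        exposed, margin = detect_exposure(model.mean_, model, ctrl)
    assert margin == 0.0
    assert not exposed


def test_control_sd_zero_falls_back_with_warning(fitted):
    _, model = fitted
    ctrl = ControlStats(mean=0.0, sd=0.0, n=5)
    with pytest.warns(UserWarning, match="fall"):
        exposed, _ = detect_exposure(
            model.mean_ + 2.0 * model.components_[0], model, ctrl
        )
    assert exposed


def test_day_one_lowest_concentration_detected(fitted):
    cfg, model = fitted
    ctrl = fit_control_stats(
        simulate_control_fingerprints(24, cfg, np.random.default_rng(5)), model
    )
    fp = simulate_fingerprint(
        ExposureSchedule.constant(10, 1), cfg, rng=np.random.default_rng(6)
    )
    exposed, margin = detect_exposure(fp, model, ctrl)
    assert exposed and margin > 0


def test_controls_rarely_flagged(fitted):
    cfg, model = fitted
    ctrl = fit_control_stats(
        simulate_control_fingerprints(24, cfg, np.random.default_rng(7)), model
    )
    rng = np.random.default_rng(8)
    flags = [
        detect_exposure(fp, model, ctrl)[0]
        for fp in simulate_control_fingerprints(200, cfg, rng)
    ]
    assert np.mean(flags) <= 0.01


def test_exposure_detector_estimator(fitted):
    cfg, model = fitted
    det = ExposureDetector(calibrator=model).fit(
        simulate_control_fingerprints(24, cfg, np.random.default_rng(9))
    )
    exposed_fp = simulate_fingerprint(
        ExposureSchedule.constant(40, 1), cfg, rng=np.random.default_rng(10)
    )
    X = np.vstack([np.zeros(12), exposed_fp])
    assert list(det.predict(X)) == [False, True]
    assert det.decision_function(X)[1] > 0
    assert det.control_stats_.n == 24


# -- accuracy scoring -------------------------------------------------------


def test_accuracy_perfect_estimates():
    rep = evaluate_accuracy([80, 160], [80, 160])
    assert rep.fraction_within[0.10] == 1.0
    assert rep.fraction_within[0.25] == 1.0


def test_accuracy_boundary_inclusive():
    """Relative errors 5%, 10%, 25%, 1.25%: within-10% counts the 10%
    boundary, within-25% counts everything."""
    rep = evaluate_accuracy([76, 88, 100, 81], [80, 80, 80, 80])
    assert rep.fraction_within[0.10] == pytest.approx(0.75)
    assert rep.fraction_within[0.25] == pytest.approx(1.0)


def test_accuracy_zero_truth_excluded():
    with pytest.warns(UserWarning, match="zero true dose"):
        rep = evaluate_accuracy([10, 80], [0, 80])
    assert rep.n_trials == 1


def test_accuracy_permutation_invariant(rng):
    est = rng.uniform(50, 150, 30)
    tru = rng.uniform(50, 150, 30)
    a = evaluate_accuracy(est, tru)
    perm = rng.permutation(30)
    b = evaluate_accuracy(est[perm], tru[perm])
    assert a.fraction_within == b.fraction_within


@settings(derandomize=True, max_examples=30)
@given(
    st.lists(
        st.tuples(st.floats(0, 5000), st.floats(1, 5000)), min_size=1, max_size=30
    )
)
def test_accuracy_fractions_nested(pairs):
    est = [p[0] for p in pairs]
    tru = [p[1] for p in pairs]
    rep = evaluate_accuracy(est, tru)
    assert rep.fraction_within[0.10] <= rep.fraction_within[0.25]


# -- unit conversion --------------------------------------------------------


def test_ppm_conversion_chlorobenzene():
    mg = ppm_to_mg_per_m3(10, 112.56)
    # two significant figures
    assert float(f"{mg:.2g}") == 46.0
    assert ppm_to_mg_per_m3(0, 112.56) == 0.0
    assert ppm_to_mg_per_m3(40, 112.56) == pytest.approx(4502.4 / 24.45, rel=1e-12)


def test_ppm_conversion_rejects_bad_inputs():
    with pytest.raises(ValueError):
        ppm_to_mg_per_m3(10, 112.56, molar_volume=0)
    with pytest.raises(ValueError):
        ppm_to_mg_per_m3(-1, 112.56)
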