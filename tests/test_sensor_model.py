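import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdadose.schedule import ExposureSchedule
from pdadose.sensor_model import (
    ArrayLayout,
    GeneratorConfig,
    SaturationError,
    SensorImage,
    child_rng,
    dot_colors,
    generate_training_set,
    render_array_image,
    simulate_fingerprint,
)

MAX_DESIGN_DRIFT = 4.31 * 8 * 14  # heaviest trajectory of the trial design


def test_empty_schedule_gives_zero_fingerprint(config):
    fp = simulate_fingerprint(ExposureSchedule(()), config)
    assert np.array_equal(fp, np.zeros(12))


@pytest.mark.parametrize(
    "conc, n_days, expected",
    [
        (10, 1, 1.16 * 8),          # single day at the lowest concentration
        (20, 14, 2.14 * 8 * 14),    # full two-week trajectory
        (40, 14, 4.31 * 8 * 14),
    ],
)
def test_drift_projection_matches_rate_table(config, conc, n_days, expected):
    """Noise-free projection on the drift direction equals summed rate x hours."""
    sched = ExposureSchedule.constant(conc, n_days)
    fp = simulate_fingerprint(sched, config)
    assert fp @ config.drift_direction == pytest.approx(expected, abs=1e-9)


def test_rate_interpolation(config):
    assert config.rate_for(30) == pytest.approx((2.14 + 4.31) / 2)
    assert config.rate_for(15) == pytest.approx((1.16 + 2.14) / 2)
    assert config.rate_for(0) == 0.0


def test_unknown_concentration_rejected():
    cfg = GeneratorConfig(interpolate_rates=False)
    with pytest.raises(ValueError, match="30"):
        simulate_fingerprint(ExposureSchedule.constant(30, 1), cfg)
    with pytest.raises(ValueError, match="outside the"):
        GeneratorConfig().rate_for(50)


def test_upto_day_beyond_schedule_rejected(config):
    with pytest.raises(ValueError, match="upto_day"):
        simulate_fingerprint(ExposureSchedule.constant(10, 3), config, upto_day=5)


def test_secondary_direction_orthogonal(config):
    assert abs(config.drift_direction @ config.secondary_direction) < 1e-12
    assert np.linalg.norm(config.drift_direction) == pytest.approx(1.0, abs=1e-12)
    assert np.linalg.norm(config.secondary_direction) == pytest.approx(1.0, abs=1e-12)


def test_secondary_vanishes_at_zero_and_matches_variance_ratio(config):
    assert config.secondary_amplitude(0.0) == pytest.approx(0.0)
    s = config._design_drifts()
    amp = config.secondary_amplitude(s)
    ratio = np.var(amp, ddof=1) / np.var(s, ddof=1)
    assert ratio == pytest.approx(6.6 / 93.3, rel=1e-9)
    # uncorrelated with the drift over the design
    assert np.cov(amp, s, ddof=1)[0, 1] == pytest.approx(0.0, abs=1e-6)


@settings(derandomize=True, max_examples=30)
@given(
    st.lists(
        st.tuples(st.sampled_from([10.0, 20.0, 40.0]), st.floats(0, 12)),
        min_size=1,
        max_size=10,
    ),
    st.integers(1, 8),
)
def test_drift_additive_over_concatenated_schedules(records, split):
    """Noise-free projection on u is additive when schedules are concatenated."""
    config = GeneratorConfig()
    u = config.drift_direction
    full = ExposureSchedule.from_records(
        (i + 1, c, h) for i, (c, h) in enumerate(records)
    )
    k = min(split, len(records))
    head = ExposureSchedule.from_records(
        (i + 1, c, h) for i, (c, h) in enumerate(records[:k])
    )
    tail = ExposureSchedule.from_records(
        (i + 1, c, h) for i, (c, h) in enumerate(records[k:])
    )
    total = simulate_fingerprint(full, config) @ u
    parts = (simulate_fingerprint(head, config) @ u) + (
        simulate_fingerprint(tail, config) @ u
    )
    assert total == pytest.approx(parts, abs=1e-9)


def test_gamut_safe_over_full_design(config):
    """Every dose reachable in the trial design renders in [0, 255]."""
    for s in np.linspace(0, MAX_DESIGN_DRIFT, 200):
        fp = (
            s * config.drift_direction
            + config.secondary_amplitude(s) * config.secondary_direction
        )
        colors = dot_colors(fp, config)  # raises on gamut violation
        assert colors.min() >= 0 and colors.max() <= 255


def test_saturation_error_names_dot_and_channel(config, layout):
    fp = np.zeros(12)
    fp[2] = 300.0  # dot 1, blue channel driven far out of gamut
    with pytest.raises(SaturationError, match=r"dot 1 channel B"):
        render_array_image(fp, layout, config)


def test_render_identity_case(config, layout):
    """Zero fingerprint, identity gains, no noise: dots exactly at pre_rgb."""
    img = render_array_image(np.zeros(12), layout, config)
    for (r, c), pre in zip(layout.centers, config.pre_rgb):
        assert tuple(img.pixels[r, c]) == tuple(int(v) for v in pre)
    # background is pure white
    assert tuple(img.pixels[0, 0]) == (255, 255, 255)


def test_render_post_color_is_pre_minus_delta(config, layout):
    fp = np.zeros(12)
    fp[0:3] = [-100.0, 0.0, 100.0]
    img = render_array_image(fp, layout, config)
    r, c = layout.centers[0]
    assert tuple(img.pixels[r, c]) == (145, 50, 135)


def test_render_background_scaled_by_gains(config, layout):
    img = render_array_image(
        np.zeros(12), layout, config, gains=(0.98, 0.93, 1.0)
    )
    r0, c0, h, w = layout.background_region
    bg = img.pixels[r0 : r0 + h, c0 : c0 + w].reshape(-1, 3)
    med = np.median(bg, axis=0)
    assert np.allclose(med, (255 * 0.98, 255 * 0.93, 255))


def test_render_deterministic_given_seed(config, layout):
    fp = simulate_fingerprint(ExposureSchedule.constant(20, 3), config)
    a = render_array_image(fp, layout, config, rng=np.random.default_rng(7))
    b = render_array_image(fp, layout, config, rng=np.random.default_rng(7))
    assert a.pixels.tobytes() == b.pixels.tobytes()


def test_training_set_size_and_truth(config):
    obs = generate_training_set([10, 20, 40], 14, 3, config)
    assert len(obs) == 126
    single = generate_training_set([10], 1, 1, config)
    assert len(single) == 1
    assert single[0].dose_ppmh == pytest.approx(80)


def test_training_set_empty_concentrations_rejected(config):
    with pytest.raises(ValueError, match="concentration"):
        generate_training_set([], 14, 3, config)


def test_training_set_byte_reproducible(config, layout):
    kw = dict(layout=layout, images=True)
    a = generate_training_set([10], 2, 1, config, **kw)
    b = generate_training_set([10], 2, 1, config, **kw)
    for oa, ob in zip(a, b):
        assert np.array_equal(oa.fingerprint, ob.fingerprint)
        assert oa.post_image.pixels.tobytes() == ob.post_image.pixels.tobytes()
        assert oa.pre_image.pixels.tobytes() == ob.pre_image.pixels.tobytes()


def test_child_seed_streams_distinct_and_stable():
    a = child_rng(0, 10, 0, 1).integers(0, 2**31, 4)
    b = child_rng(0, 10, 0, 1).integers(0, 2**31, 4)
    c = child_rng(0, 10, 0, 2).integers(0, 2**31, 4)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_layout_validation():
    with pytest.raises(ValueError, match="overlap"):
        ArrayLayout(centers=((55, 60), (55, 80), (105, 60), (105, 160)))
    with pytest.raises(ValueError, match="outside"):
        ArrayLayout(centers=((5, 60), (55, 160), (105, 60), (105, 160)))
    with pytest.raises(ValueError, match="background"):
        dataclasses.replace(ArrayLayout(), background_region=(40, 40, 60, 60))


def test_png_round_trip(tmp_path, config, layout):
    img = render_array_image(
        np.zeros(12), layout, config, rng=np.random.default_rng(3)
    )
    p = tmp_path / "img.png"
    img.to_png(p)
    back = SensorImage.from_png(p)
    assert np.array_equal(back.pixels, img.pixels)


def test_image_value_range_enforced():
    with pytest.raises(ValueError, match=r"\[0, 255\]"):
        SensorImage(np.full((4, 4, 3), 300.0))
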