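"""Held-out evaluation of the full pipeline.

Mirrors the exposure-trial protocol: calibrate on three replicate arrays
per concentration (every daily photograph enters with equal weight), then
score dose estimation and exposure detection on a fourth, held-out
replicate never seen in training.  All stages can run through rendered
images (the faithful path: render -> white balance -> locate -> extract ->
fingerprint) or directly on simulated fingerprints (fast path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import DoseCalibrator, fit_pca, fit_reference_curve
from .dosimetry import DEFAULT_K, ExposureDetector
from .imaging import fingerprint_from_images
from .schedule import ExposureSchedule
from .sensor_model import (
    ArrayLayout,
    GeneratorConfig,
    Observation,
    child_rng,
    fingerprints_and_doses,
    generate_training_set,
    simulate_control_fingerprints,
    simulate_fingerprint,
)

#: replicate index of the held-out array (training uses 0..2)
HELDOUT_REPLICATE = 3
#: number of unexposed fingerprints used to estimate control statistics
N_CONTROL_STATS = 24
#: number of held-out unexposed patches classified per seed
N_CONTROL_TRIALS = 2


def measured_fingerprints(
    observations: list[Observation], layout: ArrayLayout
) -> np.ndarray:
    """Extract each observation's fingerprint from its image pair via the
    imaging pipeline (or take the simulated fingerprint when no images
    were rendered)."""
    out = []
    for o in observations:
        if o.post_image is not None and o.pre_image is not None:
            out.append(
                fingerprint_from_images(o.pre_image, o.post_image, layout)
            )
        else:
            out.append(o.fingerprint)
    return np.array(out)


@dataclass
class HoldoutResult:
    """Per-trial table plus the fitted model for one seed."""

    trials: pd.DataFrame  # exposed held-out trials
    controls: pd.DataFrame  # held-out control classifications
    model: DoseCalibrator


def run_holdout_trial(
    seed: int,
    config: GeneratorConfig | None = None,
    *,
    concentrations=(10.0, 20.0, 40.0),
    n_days: int = 14,
    n_replicates: int = 3,
    hours_per_day: float = 8.0,
    use_images: bool = True,
    layout: ArrayLayout | None = None,
    k: float = DEFAULT_K,
    n_control_trials: int = N_CONTROL_TRIALS,
) -> HoldoutResult:
    """One full calibrate-then-test cycle under a single seed.

    Training: ``n_replicates`` replicates per concentration, all days.
    Testing: one additional replicate per concentration (days 1..n_days)
    plus ``n_control_trials`` unexposed patches.  Returns per-trial dose
    estimates, relative errors and detection outcomes.
    """
    config = (config or GeneratorConfig()).with_seed(seed)
    layout = layout or ArrayLayout()

    train = generate_training_set(
        concentrations,
        n_days,
        n_replicates,
        config,
        hours_per_day=hours_per_day,
        layout=layout,
        images=use_images,
    )
    X_train = measured_fingerprints(train, layout)
    y_train = np.array([o.dose_ppmh for o in train])
    model = DoseCalibrator().fit(X_train, y_train)

    ctrl_rng = child_rng(config.seed, -1.0, 0, 0)
    detector = ExposureDetector(calibrator=model, k=k).fit(
        simulate_control_fingerprints(N_CONTROL_STATS, config, ctrl_rng)
    )

    held = generate_training_set(
        concentrations,
        n_days,
        1,
        config,
        hours_per_day=hours_per_day,
        layout=layout,
        images=use_images,
        replicate_offset=HELDOUT_REPLICATE,
    )
    X_held = measured_fingerprints(held, layout)
    doses = model.predict(X_held)
    exposed = detector.predict(X_held)
    rows = [
        {
            "seed": seed,
            "concentration_ppm": o.concentration_ppm,
            "day": o.day,
            "true_dose": o.dose_ppmh,
            "estimated_dose": float(d),
            "rel_error": abs(float(d) - o.dose_ppmh) / o.dose_ppmh,
            "detected": bool(e),
        }
        for o, d, e in zip(held, doses, exposed)
    ]

    ctrl_rows = []
    trial_rng = child_rng(config.seed, -2.0, 0, 0)
    for i in range(n_control_trials):
        fp = simulate_fingerprint(
            ExposureSchedule(()), config, rng=trial_rng
        )
        flag = bool(detector.predict(fp.reshape(1, -1))[0])
        ctrl_rows.append({"seed": seed, "control_index": i, "detected": flag})

    return HoldoutResult(
        trials=pd.DataFrame(rows),
        controls=pd.DataFrame(ctrl_rows),
        model=model,
    )


def run_holdout_study(
    seeds, config: GeneratorConfig | None = None, **kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate :func:`run_holdout_trial` over many seeds."""
    trials, controls = [], []
    for s in seeds:
        res = run_holdout_trial(int(s), config, **kwargs)
        trials.append(res.trials)
        controls.append(res.controls)
    return pd.concat(trials, ignore_index=True), pd.concat(controls, ignore_index=True)


def accuracy_at(trials: pd.DataFrame, day: int, tolerance: float) -> float:
    """Pooled fraction of day-``day`` trials within ``tolerance`` relative
    error (boundary inclusive)."""
    sub = trials[trials["day"] == day]
    return float((sub["rel_error"] <= tolerance).mean())


def detection_rate(trials: pd.DataFrame, controls: pd.DataFrame) -> float:
    """Fraction of held-out patches classified correctly: exposed trials
    flagged, control trials not."""
    n_ok = int(trials["detected"].sum()) + int((~controls["detected"]).sum())
    return n_ok / (len(trials) + len(controls))


def variance_structure_study(
    seeds, config: GeneratorConfig | None = None
) -> pd.DataFrame:
    """PCA variance fractions and reference-curve R² of the training design
    (direct fingerprints with default noise), one row per seed."""
    base = config or GeneratorConfig()
    concs, n_rep, n_days, hours = base.calibration_design
    rows = []
    for s in seeds:
        cfg = base.with_seed(int(s))
        obs = generate_training_set(
            concs, n_days, n_rep, cfg, hours_per_day=hours, images=False
        )
        X, y = fingerprints_and_doses(obs)
        model = DoseCalibrator().fit(X, y)
        rows.append(
            {
                "seed": int(s),
                "pc1_fraction": model.explained_variance_ratio_[0],
                "pc2_fraction": model.explained_variance_ratio_[1],
                "r_squared": model.r_squared_,
            }
        )
    return pd.DataFrame(rows)


def rate_recovery(config: GeneratorConfig | None = None) -> dict[float, float]:
    """Recovered PC1 drift rate (units/h) per concentration from noise-free
    trajectories.

    A calibration is fit on the full noise-free design; each
    concentration's daily PC1 scores are regressed on cumulative exposure
    hours and the slope returned.
    """
    config = config or GeneratorConfig()
    concs, n_rep, n_days, hours = config.calibration_design
    # noise-free design: no rng
    obs = []
    for c in concs:
        sched = ExposureSchedule.constant(c, n_days, hours)
        for day in range(1, n_days + 1):
            fp = simulate_fingerprint(sched, config, upto_day=day)
            obs.append((c, day, fp, c * hours * day))
    X = np.array([o[2] for o in obs])
    y = np.array([o[3] for o in obs])
    mean, loadings, scores, _ = fit_pca(X, doses=y)
    out = {}
    for c in concs:
        idx = [i for i, o in enumerate(obs) if o[0] == c]
        hrs = np.array([obs[i][1] * hours for i in idx])
        pc1 = scores[idx, 0]
        _, slope, _ = fit_reference_curve(hrs, pc1)
        out[float(c)] = float(slope)
    return out
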