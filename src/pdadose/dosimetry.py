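"""Dose inversion, exposure detection, accuracy scoring and unit conversion.

A fitted :class:`~pdadose.calibration.DoseCalibrator` turns a new ΔRGB
fingerprint into a cumulative dose (ppm·h) by evaluating the reference
curve at its PC1 score; the 8-h time-weighted average (TWA, ppm) is the
dose divided by the averaging window.  Exposure is detected by comparing
the PC1 displacement with a threshold estimated from unexposed control
patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .calibration import DoseCalibrator

#: default occupational averaging window (the daily exposure period), hours
DEFAULT_AVERAGING_HOURS = 8.0
#: default detection threshold, in control-score standard deviations.  The
#: exposed/control separation is tens of noise sd even after a single day at
#: the lowest calibrated concentration, so a conservative threshold costs
#: nothing in sensitivity while driving the false-positive rate to ~0.
DEFAULT_K = 5.0
#: absolute PC1-displacement threshold used when the control sd is zero
DEFAULT_FALLBACK_THRESHOLD = 1.0

#: chlorobenzene molecular weight, g/mol
CHLOROBENZENE_MW = 112.56
#: molar volume of an ideal gas at 25 degC, 1 atm, L/mol
MOLAR_VOLUME_25C = 24.45


@dataclass(frozen=True)
class ControlStats:
    """Mean and sd of control (unexposed) PC1 scores."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class DoseEstimate:
    """Inverted exposure for one fingerprint."""

    dose: float  # ppm·h, clamped at 0
    pc1_score: float
    pc2_score: float
    exposed: bool
    twa: float  # ppm over the averaging window
    detection_margin: float  # signed distance of pc1 beyond the threshold
    averaging_hours: float = DEFAULT_AVERAGING_HOURS
    raw_dose: float = 0.0  # before clamping; negative values were clamped

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class AccuracyReport:
    """Pooled accuracy of dose estimates against ground truth."""

    n_trials: int
    fraction_within: dict[float, float]
    relative_errors: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        tols = sorted(self.fraction_within)
        for a, b in zip(tols, tols[1:]):
            if self.fraction_within[a] > self.fraction_within[b] + 1e-12:
                raise ValueError("fractions must be non-decreasing in tolerance")


def project(fingerprint: np.ndarray, model: DoseCalibrator) -> tuple[float, float]:
    """Centered PC scores ``loadings @ (fingerprint - mean)`` of one
    fingerprint: (pc1, pc2)."""
    scores = model.transform(np.asarray(fingerprint, dtype=float).reshape(1, -1))[0]
    return float(scores[0]), float(scores[1] if scores.size > 1 else 0.0)


def fit_control_stats(
    control_fingerprints: np.ndarray, model: DoseCalibrator
) -> ControlStats:
    """Control PC1-score statistics from >= 3 unexposed fingerprints."""
    X = check_array(control_fingerprints, ensure_min_samples=3)
    scores = model.transform(X)[:, 0]
    return ControlStats(
        mean=float(scores.mean()), sd=float(scores.std(ddof=1)), n=X.shape[0]
    )


def detect_exposure(
    fingerprint: np.ndarray,
    model: DoseCalibrator,
    control_stats: ControlStats,
    *,
    k: float = DEFAULT_K,
    fallback_threshold: float = DEFAULT_FALLBACK_THRESHOLD,
) -> tuple[bool, float]:
    """Threshold detector: exposed iff pc1 > control_mean + k * control_sd.

    The inequality is strict, so a score exactly at the threshold reads
    unexposed.  If the control sd is zero the absolute
    ``fallback_threshold`` (PC1 units above the control mean) is used with
    a warning.  Returns ``(exposed, margin)`` with ``margin = pc1 -
    threshold``.
    """
    pc1, _ = project(fingerprint, model)
    if control_stats.sd == 0:
        warnings.warn(
            "control sd is zero; falling back to an absolute threshold",
            stacklevel=2,
        )
        threshold = control_stats.mean + fallback_threshold
    else:
        threshold = control_stats.mean + k * control_stats.sd
    margin = pc1 - threshold
    return margin > 0, float(margin)


def estimate_dose(
    fingerprint: np.ndarray,
    model: DoseCalibrator,
    *,
    averaging_hours: float = DEFAULT_AVERAGING_HOURS,
    control_stats: ControlStats | None = None,
    k: float = DEFAULT_K,
) -> DoseEstimate:
    """Invert one fingerprint into a cumulative dose and TWA.

    ``dose = max(0, beta0 + beta1 * pc1)``; negative raw predictions are
    clamped (the raw value is kept in ``raw_dose``).  Exposure is
    classified against ``control_stats`` when given, else against the
    absolute fallback threshold on the PC1 displacement from the baseline.
    """
    fp = np.asarray(fingerprint, dtype=float).reshape(1, -1)
    pc1, pc2 = project(fingerprint, model)
    raw = float(model.intercept_ + model.slope_ * pc1)
    dose = max(0.0, raw)
    if control_stats is not None:
        exposed, margin = detect_exposure(fingerprint, model, control_stats, k=k)
    else:
        disp = float(model.pc1_displacement(fp)[0])
        margin = disp - DEFAULT_FALLBACK_THRESHOLD
        exposed = margin > 0
    return DoseEstimate(
        dose=dose,
        pc1_score=pc1,
        pc2_score=pc2,
        exposed=exposed,
        twa=dose / averaging_hours,
        detection_margin=margin,
        averaging_hours=averaging_hours,
        raw_dose=raw,
    )


def evaluate_accuracy(
    estimates,
    truths,
    tolerances: tuple[float, ...] = (0.10, 0.25),
) -> AccuracyReport:
    """Fraction of trials whose relative error is within each tolerance.

    ``fraction_within[t] = #{i: |est_i - truth_i| / truth_i <= t} / n``,
    boundary inclusive.  Trials with zero truth are excluded with a warning
    (relative error undefined).  The result is invariant to trial order.
    """
    est = np.asarray(estimates, dtype=float).ravel()
    tru = np.asarray(truths, dtype=float).ravel()
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have equal lengths")
    keep = tru != 0
    if not keep.all():
        warnings.warn(
            f"excluded {int((~keep).sum())} trial(s) with zero true dose",
            stacklevel=2,
        )
    est, tru = est[keep], tru[keep]
    if est.size == 0:
        raise ValueError("no trials with nonzero truth")
    rel = np.abs(est - tru) / np.abs(tru)
    return AccuracyReport(
        n_trials=int(rel.size),
        fraction_within={float(t): float(np.mean(rel <= t)) for t in tolerances},
        relative_errors=tuple(rel.tolist()),
    )


def ppm_to_mg_per_m3(
    ppm: float, molecular_weight: float, molar_volume: float = MOLAR_VOLUME_25C
) -> float:
    """Convert a gas-phase concentration from ppm to mg/m³.

    ``mg/m³ = ppm x MW / Vm`` with the molar volume in L/mol (default
    24.45, ideal gas at 25 degC and 1 atm).  For chlorobenzene
    (MW 112.56 g/mol), 10 ppm is 46 mg/m³ to two significant figures.
    """
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    if molecular_weight <= 0 or molar_volume <= 0:
        raise ValueError("molecular weight and molar volume must be positive")
    return ppm * molecular_weight / molar_volume


class ExposureDetector(BaseEstimator):
    """Scikit-learn style wrapper of the control-threshold detector.

    Parameters
    ----------
    calibrator : fitted DoseCalibrator
        Supplies the PC1 projection.
    k : float, default 5.0
        Threshold in control-score standard deviations.
    fallback_threshold : float, default 1.0
        Absolute threshold used when the control sd is zero.
    """

    def __init__(
        self,
        calibrator: DoseCalibrator = None,
        k: float = DEFAULT_K,
        fallback_threshold: float = DEFAULT_FALLBACK_THRESHOLD,
    ):
        self.calibrator = calibrator
        self.k = k
        self.fallback_threshold = fallback_threshold

    def fit(self, X, y=None):
        """Fit control statistics from unexposed fingerprints ``X``."""
        if self.calibrator is None:
            raise ValueError("a fitted calibrator is required")
        stats = fit_control_stats(X, self.calibrator)
        self.control_mean_ = stats.mean
        self.control_sd_ = stats.sd
        self.n_controls_ = stats.n
        if stats.sd == 0:
            warnings.warn(
                "control sd is zero; using the absolute fallback threshold",
                stacklevel=2,
            )
            self.threshold_ = stats.mean + self.fallback_threshold
        else:
            self.threshold_ = stats.mean + self.k * stats.sd
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed margins: PC1 score minus the threshold."""
        check_is_fitted(self, "threshold_")
        return self.calibrator.transform(check_array(X))[:, 0] - self.threshold_

    def predict(self, X) -> np.ndarray:
        """Boolean exposed/control labels (strictly above the threshold)."""
        return self.decision_function(X) > 0

    @property
    def control_stats_(self) -> ControlStats:
        check_is_fitted(self, "threshold_")
        return ControlStats(self.control_mean_, self.control_sd_, self.n_controls_)
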