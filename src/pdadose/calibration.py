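"""PCA + reference-curve calibration of the patch.

Dose calibration proceeds in two steps, mirroring how colorimetric sensor
arrays are read out in practice:

1. **PCA.**  The 12-d ΔRGB fingerprints of the labeled training design are
   centered (no per-variable scaling — all coordinates share the 8-bit ΔRGB
   unit) and reduced to two principal components.  PC1 carries the dose
   response; its sign is fixed so that scores correlate positively with the
   training doses.
2. **Reference curve.**  Cumulative dose (ppm·h) is regressed on the PC1
   score.  By default the line is anchored at the zero-exposure baseline —
   an unexposed patch must read zero dose — which amounts to a slope-only
   least-squares fit on the PC1 *displacement* from the baseline projection.
   A free-intercept ordinary least squares fit is also available.

The fitted model inverts new fingerprints into dose by direct evaluation of
the curve (no curve inversion is needed because dose is the response).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .sensor_model import FINGERPRINT_DIM

SCHEMA_VERSION = 1
_ORTHO_TOL = 1e-10


def fit_pca(
    fingerprints: np.ndarray,
    doses: np.ndarray | None = None,
    n_components: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Top principal components of a fingerprint set.

    Returns ``(mean, loadings, scores, explained_variance_fractions)`` where
    ``loadings`` has orthonormal columns (p, k), ``scores = (X - mean) @
    loadings`` and the fractions are eigenvalues over the covariance trace,
    sorted descending.  When ``doses`` is given, each component's sign is
    fixed so its scores correlate positively with dose; otherwise the
    largest-magnitude loading of each component is made positive.
    """
    X = check_array(fingerprints, ensure_min_samples=3)
    n = X.shape[0]
    if np.allclose(X, X[0]):
        raise ValueError("fingerprints are all identical: zero total variance")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # (p, k)
    fractions = pca.explained_variance_ratio_.copy()
    for j in range(loadings.shape[1]):
        if doses is not None:
            y = np.asarray(doses, dtype=float)
            if y.shape[0] != n:
                raise ValueError("doses length must match fingerprints")
            orient = float(scores[:, j] @ (y - y.mean()))
        else:
            orient = 0.0
        if orient == 0.0:
            orient = loadings[np.argmax(np.abs(loadings[:, j])), j]
        if orient < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return pca.mean_.copy(), loadings, scores, fractions


def fit_reference_curve(
    pc1_scores: np.ndarray,
    doses: np.ndarray,
    *,
    anchor: float | None = None,
) -> tuple[float, float, float]:
    """Least-squares reference curve ``dose = beta0 + beta1 * pc1``.

    With ``anchor=None`` this is ordinary least squares with a free
    intercept.  With ``anchor=x0`` the line is constrained through
    ``(x0, 0)`` — the score of a zero-dose (unexposed) patch — so only the
    slope is estimated and ``beta0 = -beta1 * x0``.  Returns ``(beta0,
    beta1, r_squared)`` with ``r_squared = 1 - SSE/SST`` about the mean dose.
    """
    x = np.asarray(pc1_scores, dtype=float).ravel()
    y = np.asarray(doses, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need matching pc1 scores and doses, n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("PC1 scores are all equal: degenerate regressor")
    if anchor is None:
        beta1, beta0 = np.polyfit(x, y, 1)
    else:
        xa = x - anchor
        denom = float(xa @ xa)
        if denom == 0:
            raise ValueError("PC1 displacements are all zero: degenerate regressor")
        beta1 = float(xa @ y) / denom
        beta0 = -beta1 * anchor
    resid = y - (beta0 + beta1 * x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
    return float(beta0), float(beta1), float(r2)


class DoseCalibrator(BaseEstimator, RegressorMixin):
    """PCA + reference-curve dose model with a scikit-learn interface.

    Parameters
    ----------
    n_components : int, default 2
        Number of principal components retained (PC1 drives the curve; PC2
        is kept for diagnostics).
    anchor_baseline : bool, default True
        Anchor the reference curve at the zero-exposure baseline score, so
        an unexposed patch reads zero dose.  With ``False`` a free-intercept
        OLS is fit.

    Attributes
    ----------
    mean_ : ndarray (12,)
        Training mean fingerprint.
    components_ : ndarray (n_components, 12)
        Orthonormal loadings (rows), PC1 first, signs fixed dose-positive.
    explained_variance_ratio_ : ndarray (n_components,)
        Fraction of total variance per component, descending.
    baseline_score_ : float
        PC1 score of the zero fingerprint (the unexposed patch).
    slope_, intercept_ : float
        Reference curve ``dose = intercept_ + slope_ * pc1_score``.
    r_squared_ : float
        Coefficient of determination of the curve on the training set.
    """

    def __init__(self, n_components: int = 2, anchor_baseline: bool = True):
        self.n_components = n_components
        self.anchor_baseline = anchor_baseline

    def fit(self, X, y):
        X = check_array(X, ensure_min_samples=3)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        mean, loadings, scores, fractions = fit_pca(
            X, doses=y, n_components=self.n_components
        )
        self.mean_ = mean
        self.components_ = loadings.T
        self.explained_variance_ratio_ = fractions
        self.baseline_score_ = float(-mean @ loadings[:, 0])
        anchor = self.baseline_score_ if self.anchor_baseline else None
        self.intercept_, self.slope_, self.r_squared_ = fit_reference_curve(
            scores[:, 0], y, anchor=anchor
        )
        self.n_features_in_ = X.shape[1]
        self.n_samples_ = X.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        """Scores ``(X - mean_) @ components_.T`` of shape (n, n_components)."""
        check_is_fitted(self, "components_")
        X = check_array(X, ensure_2d=True)
        return (X - self.mean_) @ self.components_.T

    def pc1_displacement(self, X) -> np.ndarray:
        """PC1 score measured from the unexposed baseline (zero fingerprint).

        This is the paper-scale quantity: it grows at the per-hour drift
        rates and is zero for an unexposed patch.
        """
        return self.transform(X)[:, 0] - self.baseline_score_

    def predict(self, X) -> np.ndarray:
        """Cumulative dose estimates in ppm·h, clamped at zero."""
        check_is_fitted(self, "slope_")
        pc1 = self.transform(X)[:, 0]
        return np.maximum(0.0, self.intercept_ + self.slope_ * pc1)


# ---------------------------------------------------------------------------
# persistence


def _validate_model_dict(d: dict) -> None:
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema_version {d.get('schema_version')!r}, "
            f"expected {SCHEMA_VERSION}"
        )
    L = np.asarray(d["loadings"], dtype=float)
    if L.shape[0] != FINGERPRINT_DIM:
        raise ValueError(f"loadings must have {FINGERPRINT_DIM} rows, got {L.shape}")
    gram = L.T @ L
    if not np.allclose(gram, np.eye(L.shape[1]), atol=1e-8):
        raise ValueError("loadings columns are not orthonormal")
    fr = np.asarray(d["explained_variance_fractions"], dtype=float)
    if np.any(np.diff(fr) > 1e-12) or fr.sum() > 1 + 1e-9 or np.any(fr < 0):
        raise ValueError(
            "explained_variance_fractions must be descending, non-negative "
            "and sum to at most 1"
        )
    r2 = float(d["r_squared"])
    if not -1e-9 <= r2 <= 1 + 1e-9:
        raise ValueError("r_squared must lie in [0, 1]")


def save_model(model: DoseCalibrator, path: str | Path, *, metadata: dict | None = None) -> None:
    """Serialize a fitted calibrator to schema-versioned JSON."""
    check_is_fitted(model, "slope_")
    d = {
        "schema_version": SCHEMA_VERSION,
        "mean_vector": model.mean_.tolist(),
        "loadings": model.components_.T.tolist(),  # (12, k) column-major components
        "explained_variance_fractions": model.explained_variance_ratio_.tolist(),
        "baseline_score": model.baseline_score_,
        "curve_slope": model.slope_,
        "curve_intercept": model.intercept_,
        "r_squared": model.r_squared_,
        "anchor_baseline": model.anchor_baseline,
        "metadata": dict(metadata or {}, n_training_samples=model.n_samples_),
    }
    _validate_model_dict(d)
    Path(path).write_text(json.dumps(d, indent=1))


def load_model(path: str | Path) -> DoseCalibrator:
    """Load and validate a serialized calibrator.

    Raises ``ValueError`` naming the offending field when an invariant
    fails; a truncated or malformed file raises without returning a partial
    model.
    """
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"model file is not valid JSON: {e}") from e
    for key in (
        "schema_version",
        "mean_vector",
        "loadings",
        "explained_variance_fractions",
        "curve_slope",
        "curve_intercept",
        "r_squared",
    ):
        if key not in d:
            raise ValueError(f"model file missing field {key!r}")
    _validate_model_dict(d)
    L = np.asarray(d["loadings"], dtype=float)
    m = DoseCalibrator(
        n_components=L.shape[1], anchor_baseline=bool(d.get("anchor_baseline", True))
    )
    m.mean_ = np.asarray(d["mean_vector"], dtype=float)
    m.components_ = L.T
    m.explained_variance_ratio_ = np.asarray(
        d["explained_variance_fractions"], dtype=float
    )
    m.baseline_score_ = float(d.get("baseline_score", -m.mean_ @ L[:, 0]))
    m.slope_ = float(d["curve_slope"])
    m.intercept_ = float(d["curve_intercept"])
    m.r_squared_ = float(d["r_squared"])
    m.n_features_in_ = FINGERPRINT_DIM
    m.n_samples_ = int(d.get("metadata", {}).get("n_training_samples", 0))
    return m
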