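"""Soft-margin SVM with radial-basis kernel on the two collapsed burden
covariates, and the R^2 goodness-of-fit statistic that drives selection.

The dual quadratic program

    min_a 0.5 a'Qa - e'a,   Q_kj = t_k t_j K(x_k, x_j),
    s.t.  0 <= a_k <= C,    sum_k a_k t_k = 0,

is solved by a maximal-violating-pair SMO (see ``_core``).  Identical
covariate rows with the same label are merged into one point whose box
constraint is scaled by the multiplicity — an exactly equivalent program —
and the merged dual coefficient is split evenly over the duplicates on the
way out, so every reported alpha lies in [0, C].
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._core import _fit_point_set
from .weighting import CollapsedPair

logger = logging.getLogger(__name__)


@dataclass
class SvmConfig:
    """SVM hyper-parameters.

    C is the soft-margin penalty (default 10).  gamma is the RBF width;
    the default ``None`` resolves to 1/d where d is the number of
    covariates (2 for the collapsed pair).  Covariates are standardised to
    zero mean and unit variance over the sample before the kernel unless
    ``standardize`` is off.

    ``r2_mode`` selects how the estimated status t_hat enters R^2:
    "decision" (default) affinely calibrates the continuous decision
    values onto the labels first, making R^2 the squared correlation
    between t and f(x) — zero for an uninformative model and monotone in
    fit quality, which is what must drive backward selection; "raw" uses
    the uncalibrated decision values in 1 - SS_res/SS_tot (an SVM decision
    value is a margin, not a least-squares prediction, so raw R^2 is
    systematically negative and is reported for diagnostics only);
    "label" thresholds f at zero first.
    """

    C: float = 10.0
    gamma: float | None = None
    standardize: bool = True
    r2_mode: str = "decision"
    tol: float = 1e-3
    max_iter: int = 200_000

    _R2_CODES = {"decision": 0, "label": 1, "raw": 2}

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.r2_mode not in self._R2_CODES:
            raise ValueError("r2_mode must be 'decision', 'label' or 'raw'")

    def resolved_gamma(self, d: int = 2) -> float:
        return self.gamma if self.gamma is not None else 1.0 / d

    @property
    def r2_mode_code(self) -> int:
        return self._R2_CODES[self.r2_mode]


@dataclass
class SvmFit:
    """Fitted dual solution and goodness of fit."""

    alphas: np.ndarray
    bias: float
    decision_values: np.ndarray
    r2: float
    config: SvmConfig = field(default_factory=SvmConfig)

    @property
    def predicted_labels(self) -> np.ndarray:
        return np.where(self.decision_values > 0, 1, -1)

    def to_json(self) -> str:
        return json.dumps({
            "bias": self.bias, "r2": self.r2,
            "C": self.config.C, "gamma": self.config.resolved_gamma(),
            "alphas": self.alphas.tolist(),
            "decision_values": self.decision_values.tolist()})


def rbf_kernel(x, y, gamma: float) -> float:
    """exp(-gamma * ||x - y||^2); equals 1 at zero distance and tends to 1
    for any pair as gamma -> 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal dimension")
    d = x - y
    return float(np.exp(-gamma * np.dot(d, d)))


def r_squared(labels, decision_values, mode: str = "decision") -> float:
    """Coefficient of determination of the estimated status against the
    true +/-1 labels, 1 - SS_res/SS_tot.

    ``mode="decision"`` (default) first calibrates the decision values
    with the least-squares affine map onto the labels, so the result
    equals the squared Pearson correlation between t and f: 0 for an
    uninformative model, 1 for a perfect one.  ``mode="raw"`` plugs the
    uncalibrated decision values straight into the residual form (useful
    for diagnostics; typically negative because a margin is not a
    least-squares prediction).  ``mode="label"`` thresholds f at zero
    first.
    """
    t = np.asarray(labels, dtype=float)
    f = np.asarray(decision_values, dtype=float)
    if t.shape != f.shape or t.size < 2:
        raise ValueError("labels and decision values must have equal "
                         "length >= 2")
    if mode not in ("decision", "raw", "label"):
        raise ValueError("mode must be 'decision', 'raw' or 'label'")
    ss_tot = float(((t - t.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("labels are all identical: zero total sum of "
                         "squares")
    if mode == "decision":
        fc = f - f.mean()
        sxx = float((fc ** 2).sum())
        if sxx == 0:
            return 0.0
        sxy = float((fc * (t - t.mean())).sum())
        return (sxy * sxy) / (sxx * ss_tot)
    if mode == "label":
        f = np.where(f > 0, 1.0, -1.0)
    ss_res = float(((t - f) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def fit_svm(pair, labels, config: SvmConfig | None = None) -> SvmFit:
    """Fit the RBF SVM on the collapsed covariate pair.

    ``pair`` may be a :class:`CollapsedPair` or an (n, d) covariate array.
    Labels must contain both classes.  If every covariate row is identical
    the fit degenerates to the constant majority-class decision (the label
    mean) with a warning.
    """
    if config is None:
        config = SvmConfig()
    if isinstance(pair, CollapsedPair):
        X = pair.as_matrix()
    else:
        X = np.atleast_2d(np.asarray(pair, dtype=float))
    t = np.asarray(labels, dtype=float)
    n = t.size
    if X.shape[0] != n:
        raise ValueError("covariates and labels disagree on n")
    if X.shape[1] != 2:
        raise ValueError("expected exactly the two collapsed covariates")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    classes = set(np.unique(t))
    if classes != {-1.0, 1.0}:
        raise ValueError("both classes (+1, -1) must be present")
    if n < 4:
        raise ValueError("need at least 4 individuals")

    # merge duplicate (x, t) rows into weighted points
    rows = np.column_stack([X, t])
    uniq, inv, mult = np.unique(rows, axis=0, return_inverse=True,
                                return_counts=True)
    x1 = np.ascontiguousarray(uniq[:, 0])
    x2 = np.ascontiguousarray(uniq[:, 1])
    yu = np.ascontiguousarray(uniq[:, 2])
    multf = mult.astype(np.float64)
    tbar = t.mean()
    alpha = np.zeros(uniq.shape[0])
    gamma = config.resolved_gamma(2)
    r2 = _fit_point_set(x1, x2, yu, multf, float(n), tbar, config.C, gamma,
                        config.standardize, config.tol, config.max_iter,
                        alpha, config.r2_mode_code)
    if (X == X[0]).all():
        warnings.warn("all covariate rows identical: constant "
                      "majority-class decision returned")
        return SvmFit(np.zeros(n), tbar, np.full(n, tbar), r2, config)

    # recover per-point decision values: standardise as in the core fit
    mu = (multf @ np.column_stack([x1, x2])) / n
    var = (multf @ (np.column_stack([x1, x2]) - mu) ** 2) / n
    sd = np.sqrt(var)
    Z = np.column_stack([x1, x2]) - mu
    with np.errstate(invalid="ignore"):
        Z = np.where(sd > 1e-12, Z / sd, 0.0)
    if not config.standardize:
        Z = np.column_stack([x1, x2])
    D2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-gamma * D2)
    fu = K @ (alpha * yu)
    # bias from the decision identity on free support vectors; recompute as
    # in the solver: b = f_k - sum alpha y K on the violating-bound midpoint
    G = (K * (yu[None, :] * yu[:, None])) @ alpha - 1.0
    up = ((yu > 0) & (alpha < config.C * multf - 1e-12)) | \
         ((yu < 0) & (alpha > 1e-12))
    low = ((yu > 0) & (alpha > 1e-12)) | \
          ((yu < 0) & (alpha < config.C * multf - 1e-12))
    v = -yu * G
    if up.any() and low.any():
        bias = 0.5 * (v[up].max() + v[low].min())
    elif up.any():
        bias = v[up].max()
    elif low.any():
        bias = v[low].min()
    else:
        bias = 0.0
    fu = fu + bias
    decision = fu[inv]
    alphas = (alpha / multf)[inv]  # even split over duplicates, in [0, C]
    return SvmFit(alphas, float(bias), decision, float(r2), config)
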