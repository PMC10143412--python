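"""Gaussian-copula mutual information and backward feature elimination.

The mutual information between a feature block X and a blood-pressure
target Y is estimated in two steps:

1. *Copula normalization*: each column is rank-transformed and mapped
   through the standard normal quantile function at rank/(n+1).  The
   transform is distribution-free — any strictly monotone transform of
   a column yields the identical normalized column — so the estimator
   captures the dependence structure (the copula) regardless of the
   marginals.
2. *Gaussian MI*: with copula-normal margins,
   ``I = 0.5 * log2(|Sigma_X| |Sigma_Y| / |Sigma_XY|)`` bits, with
   covariances estimated from the normalized data (1/(n-1) convention)
   and the result clipped below at zero.

Feature selection proceeds by backward elimination: after dropping
features with (near-)zero univariate MI against the target, the group
MI ``I_1`` of the current set is compared with the group MI ``I_2`` of
every leave-one-out subset; the feature whose removal costs least is
eliminated, until the minimum loss ``I_1 - min(I_2)`` exceeds the
stopping threshold (default 0.002 bits), at which point the set before
that removal is kept.  Redundant features therefore leave first at ~no
cost (the MI trajectory shows a plateau) and the decay that follows
marks the informative core.

:class:`GCMIFeatureSelector` wraps the procedure as a scikit-learn
transformer so it composes with pipelines and model selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "copula_normalize",
    "gcmi",
    "null_mi_threshold",
    "SelectionResult",
    "backward_select",
    "GCMIFeatureSelector",
]

logger = logging.getLogger(__name__)

#: Algorithm stop rule: elimination halts once the minimum group-MI loss
#: of a removal exceeds this many bits.
DEFAULT_THRESHOLD_BITS = 0.002
#: univariate prefilter: features with MI at or below this are "zero"
DEFAULT_ZERO_TOL_BITS = 1e-3


def null_mi_threshold(n: int, d: int = 1, e: int = 1, alpha: float = 0.95) -> float:
    """Null quantile of the plug-in Gaussian MI estimate, in bits.

    Under independence, ``2 n ln2 * I`` is asymptotically chi-square
    with ``d*e`` degrees of freedom, so this returns the ``alpha``
    quantile of the estimate when the true MI is zero — a principled
    "indistinguishable from zero" cutoff for the univariate prefilter
    at any sample size.
    """
    from scipy.stats import chi2

    return float(chi2.ppf(alpha, d * e) / (2.0 * n * np.log(2.0)))


def copula_normalize(column: np.ndarray) -> np.ndarray:
    """Map a sample to standard-normal scores by rank.

    Average ranks are used for ties; rank r maps to ``ndtri(r/(n+1))``.
    The output is invariant to any strictly monotone transform of the
    input.  Constant columns are rejected.
    """
    column = np.asarray(column, dtype=float)
    if column.ndim != 1:
        raise ValueError("copula_normalize expects a 1-D column")
    if np.ptp(column) == 0:
        raise ValueError("zero-variance feature cannot be copula-normalized")
    ranks = rankdata(column, method="average")
    return ndtri(ranks / (len(column) + 1))


def _logdet(cov: np.ndarray, ridge: float = 1e-10) -> float:
    sign, logdet = np.linalg.slogdet(np.atleast_2d(cov))
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular covariance; adding diagonal ridge", RuntimeWarning)
        sign, logdet = np.linalg.slogdet(np.atleast_2d(cov) + ridge * np.eye(cov.shape[0]))
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError("covariance singular even after ridge")
    return logdet


def gcmi(X: np.ndarray, Y: np.ndarray) -> float:
    """Gaussian-copula mutual information between X and Y in bits.

    Columns must already be copula-normalized.  Requires
    ``n > d + e + 2`` samples for a non-degenerate covariance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    n, d = X.shape
    e = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of samples")
    if not n > d + e + 2:
        raise ValueError(f"need n > d+e+2 samples (n={n}, d={d}, e={e})")
    joint = np.hstack([X, Y])
    cov = np.cov(joint, rowvar=False, ddof=1)
    ld_x = _logdet(cov[:d, :d])
    ld_y = _logdet(cov[d:, d:])
    ld_xy = _logdet(cov)
    bits = 0.5 * (ld_x + ld_y - ld_xy) / np.log(2.0)
    return max(0.0, float(bits))


@dataclass
class SelectionResult:
    """Outcome of one backward-elimination run for one target."""

    target_name: str
    threshold: float
    selected: list[str]
    elimination_order: list[str]
    mi_trajectory: list[float]  # group MI after each removal (starts at the full set)
    prefiltered: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _group_mi(Z: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
    return gcmi(Z[:, cols], y)


def backward_select(
    X,
    y,
    feature_names: list[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD_BITS,
    zero_tol: float = DEFAULT_ZERO_TOL_BITS,
    target_name: str = "SBP",
    keep_k: int | None = None,
    normalize_target: bool = True,
    already_normalized: bool = False,
) -> SelectionResult:
    """Greedy backward elimination under the group-MI stop rule.

    Features with univariate MI <= ``zero_tol`` against the target are
    dropped first; then the feature whose removal loses the least group
    MI is eliminated repeatedly until the minimum loss exceeds
    ``threshold`` bits (the set *before* that removal is kept), or until
    exactly ``keep_k`` features remain when ``keep_k`` is given.
    """
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("backward selection needs at least 2 features")
    y = np.asarray(y, dtype=float).reshape(-1)
    if already_normalized:
        Z = X.copy()
        yz = y.copy()
    else:
        Z = np.column_stack([copula_normalize(X[:, j]) for j in range(X.shape[1])])
        yz = copula_normalize(y) if normalize_target else y.copy()
    yz = yz.reshape(-1, 1)

    # (i) univariate prefilter
    current: list[int] = []
    prefiltered: list[str] = []
    for j in range(Z.shape[1]):
        if gcmi(Z[:, [j]], yz) <= zero_tol:
            prefiltered.append(feature_names[j])
        else:
            current.append(j)
    if not current:
        raise ValueError("no informative features: all were prefiltered at zero MI")

    elimination_order: list[str] = []
    # the joint covariance needs n > d + e + 2 samples; on very small
    # cohorts shed the weakest univariate features until the group
    # estimate is defined at all
    max_d = Z.shape[0] - yz.shape[1] - 3
    if len(current) > max_d:
        logger.warning(
            "feature set (%d) too large for n=%d samples; dropping weakest "
            "univariate features first", len(current), Z.shape[0],
        )
        by_uni = sorted(current, key=lambda j: gcmi(Z[:, [j]], yz))
        while len(current) > max(2, max_d):
            j = by_uni.pop(0)
            current.remove(j)
            elimination_order.append(feature_names[j])
    trajectory: list[float] = [_group_mi(Z, yz, current)]
    target_size = keep_k if keep_k is not None else 1
    while len(current) > max(1, target_size):
        i1 = _group_mi(Z, yz, current)
        losses = []
        for j in current:
            rest = [c for c in current if c != j]
            losses.append((i1 - _group_mi(Z, yz, rest), j))
        min_loss, drop = min(losses, key=lambda t: (t[0], current.index(t[1])))
        if keep_k is None and min_loss > threshold:
            break  # keep the set before this removal
        current = [c for c in current if c != drop]
        elimination_order.append(feature_names[drop])
        trajectory.append(_group_mi(Z, yz, current))
        if keep_k is not None and len(current) == keep_k:
            break
    return SelectionResult(
        target_name=target_name,
        threshold=threshold,
        selected=[feature_names[j] for j in current],
        elimination_order=elimination_order,
        mi_trajectory=trajectory,
        prefiltered=prefiltered,
    )


class GCMIFeatureSelector(SelectorMixin, BaseEstimator):
    """Backward-elimination feature selector driven by Gaussian-copula MI.

    Parameters
    ----------
    threshold : float, default 0.002
        Stop rule in bits: elimination halts when the cheapest removal
        would lose more group MI than this.
    zero_tol : float, default 1e-3
        Univariate prefilter tolerance in bits (the plug-in estimator
        never returns exactly zero).
    keep_k : int or None
        When set, ignore the threshold and retain exactly ``keep_k``
        features (replication mode for a fixed-size subset).
    normalize_target : bool, default True
        Copula-normalize the target as well as the features.
    target_name : str, default "SBP"
        Label recorded in the :class:`SelectionResult`.

    Attributes
    ----------
    selected_features_ : list of str
    elimination_order_ : list of str
    mi_trajectory_ : list of float
    result_ : SelectionResult
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD_BITS,
        zero_tol: float = DEFAULT_ZERO_TOL_BITS,
        keep_k: int | None = None,
        normalize_target: bool = True,
        target_name: str = "SBP",
    ):
        self.threshold = threshold
        self.zero_tol = zero_tol
        self.keep_k = keep_k
        self.normalize_target = normalize_target
        self.target_name = target_name

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"f{i}" for i in range(Xv.shape[1])]
        if Xv.ndim != 2:
            raise ValueError("X must be 2-D")
        self.n_features_in_ = Xv.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.result_ = backward_select(
            Xv, y, feature_names=names,
            threshold=self.threshold, zero_tol=self.zero_tol,
            keep_k=self.keep_k, normalize_target=self.normalize_target,
            target_name=self.target_name,
        )
        self.selected_features_ = list(self.result_.selected)
        self.elimination_order_ = list(self.result_.elimination_order)
        self.mi_trajectory_ = list(self.result_.mi_trajectory)
        keep = set(self.selected_features_)
        self.support_ = np.asarray([n in keep for n in names], dtype=bool)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _more_tags(self):
        return {"requires_y": True, "allow_nan": False}
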