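"""scikit-learn style estimators wrapping the segmentation solvers.

:class:`FusedSegmenter` fits a piecewise-constant signal to an ordered
series at a fixed penalty; :class:`FusedSegmenterCV` first selects the
penalty by cross-validation.  Segmentation is transductive — like manifold
embeddings, the fit describes the training series itself — so ``predict``
and ``transform`` return the reconstruction of the series the estimator was
fitted on.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dp import as_series, segment
from .model_selection import CVConfig, select_lambda

__all__ = ["FusedSegmenter", "FusedSegmenterCV"]


class FusedSegmenter(BaseEstimator):
    """Exact L0- or L1-penalized piecewise-constant fit of an ordered series.

    Parameters
    ----------
    family : {"gaussian", "poisson", "binomial"}
        Loss family.  Gaussian and Poisson expect a 1-d series (or a single
        column); binomial expects an ``(n, 2)`` array of (methylated, total)
        counts.
    penalty : {"l0", "l1"}
        L0 charges ``lam`` per changepoint; L1 charges ``lam`` per unit of
        total variation of the natural parameter.
    lam : float
        Non-negative penalty strength.

    Attributes
    ----------
    breakpoints_ : ndarray of int
        Positions ``i`` where the fitted value changes between ``i`` and
        ``i+1`` (0-based).
    segment_values_ : ndarray
        Per-segment fitted values on the mean scale (mean, rate, fraction).
    segment_params_ : ndarray
        The same segments in the natural parameter.
    fitted_values_ : ndarray
        Mean-scale reconstruction, one value per input position.
    n_segments_ : int
    objective_ : float
        Achieved penalized objective (family constants dropped).
    segmentation_ : Segmentation
        The full result object.

    Examples
    --------
    >>> import numpy as np
    >>> from l0seg import FusedSegmenter
    >>> y = np.array([0., 0., 10., 10.])
    >>> FusedSegmenter(family="gaussian", penalty="l0", lam=1.0).fit(y).segment_values_
    array([ 0., 10.])
    """

    def __init__(self, family: str = "gaussian", penalty: str = "l0", lam: float = 1.0):
        self.family = family
        self.penalty = penalty
        self.lam = lam

    def fit(self, X, y=None, sample_weight=None):
        series = as_series(X, sample_weight, self.family)
        seg = segment(series, self.family, self.penalty, self.lam)
        self.segmentation_ = seg
        self.breakpoints_ = seg.breakpoints
        self.segment_values_ = seg.segment_values
        self.segment_params_ = seg.segment_params
        self.fitted_values_ = seg.reconstruct()
        self.n_segments_ = seg.n_segments
        self.objective_ = seg.objective
        self.mean_envelope_pieces_ = seg.mean_envelope_pieces
        self.n_features_in_ = 2 if self.family == "binomial" else 1
        return self

    def predict(self, X=None) -> np.ndarray:
        """Mean-scale fitted values of the series the estimator was fit on."""
        check_is_fitted(self, "fitted_values_")
        return self.fitted_values_.copy()

    def transform(self, X=None) -> np.ndarray:
        check_is_fitted(self, "fitted_values_")
        return self.fitted_values_.reshape(-1, 1)

    def fit_predict(self, X, y=None, sample_weight=None) -> np.ndarray:
        return self.fit(X, sample_weight=sample_weight).predict()

    def fit_transform(self, X, y=None, sample_weight=None) -> np.ndarray:
        return self.fit(X, sample_weight=sample_weight).transform()


class FusedSegmenterCV(FusedSegmenter):
    """Segmenter with the penalty chosen by cross-validation.

    ``mode="binned"`` holds out fragment-length windows (for autocorrelated
    ChIP-like tracks); ``mode="pointwise"`` holds out single positions (for
    methylation and other conditionally independent series).

    Attributes (in addition to :class:`FusedSegmenter`'s)
    ----------
    lambda_ : float
        Selected penalty.
    cv_result_ : CVResult
        Per-penalty mean held-out losses and the fold-level table.
    """

    def __init__(
        self,
        family: str = "poisson",
        penalty: str = "l0",
        lambdas=None,
        n_lambdas: int = 20,
        mode: str = "binned",
        window_bp: int = 300,
        bin_bp: int = 20,
        n_folds: int = 5,
    ):
        super().__init__(family=family, penalty=penalty, lam=None)
        self.lambdas = lambdas
        self.n_lambdas = n_lambdas
        self.mode = mode
        self.window_bp = window_bp
        self.bin_bp = bin_bp
        self.n_folds = n_folds

    def fit(self, X, y=None, sample_weight=None):
        series = as_series(X, sample_weight, self.family)
        config = CVConfig(
            window_bp=self.window_bp,
            bin_bp=self.bin_bp,
            n_folds=self.n_folds,
            lambda_grid=None if self.lambdas is None else np.asarray(self.lambdas, float),
            n_lambdas=self.n_lambdas,
            mode=self.mode,
        )
        self.cv_result_ = select_lambda(series, self.family, self.penalty, config)
        self.lambda_ = self.cv_result_.lambda_
        seg = segment(series, self.family, self.penalty, self.lambda_)
        self.segmentation_ = seg
        self.breakpoints_ = seg.breakpoints
        self.segment_values_ = seg.segment_values
        self.segment_params_ = seg.segment_params
        self.fitted_values_ = seg.reconstruct()
        self.n_segments_ = seg.n_segments
        self.objective_ = seg.objective
        self.mean_envelope_pieces_ = seg.mean_envelope_pieces
        self.n_features_in_ = 2 if self.family == "binomial" else 1
        return self
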