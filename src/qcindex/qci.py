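"""Quality-of-Care Index: oriented first principal component of the four
care ratios, min-max rescaled to the 0–100 range.

:class:`QCIScorer` is a scikit-learn style transformer. ``fit`` z-scores
each ratio over the fitting set, extracts the leading eigenvector of their
4×4 correlation matrix (via :class:`sklearn.decomposition.PCA` on the
standardised matrix), orients it so that a higher score means better care
(the mortality-to-incidence loading is forced negative, falling back to
the YLL/YLD loading when the MIR loading vanishes), and records the
fitting-set extrema of the oriented raw score. ``transform`` maps those
extrema to exactly 0 and 100; out-of-fit units may leave the band and are
clamped with a warning by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .errors import ContractError
from .indices import INDEX_COLUMNS


def _as_index_matrix(X) -> np.ndarray:
    """Accept a DataFrame carrying the four ratio columns or a plain
    (n, 4) array in pir/mir/dpr/ylr order."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in INDEX_COLUMNS if c not in X.columns]
        if missing:
            raise ContractError(f"index table lacks column(s) {missing}")
        return X.loc[:, list(INDEX_COLUMNS)].to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(INDEX_COLUMNS):
        raise ContractError(
            f"expected an (n, {len(INDEX_COLUMNS)}) index matrix, got "
            f"shape {arr.shape}")
    return arr


def _project(Z: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Fixed-order column accumulation of ``Z @ v``.

    BLAS matmul picks kernels by memory alignment, so bitwise results can
    differ between a masked copy and the original array; explicit ufunc
    arithmetic keeps scores reproducible across those paths.
    """
    out = Z[:, 0] * v[0]
    for j in range(1, Z.shape[1]):
        out = out + Z[:, j] * v[j]
    return out


class QCIScorer(BaseEstimator, TransformerMixin):
    """Principal-component care-quality scorer on a 0–100 scale.

    Parameters
    ----------
    orient : bool, default True
        Resolve the PC1 sign ambiguity during ``fit`` so that the MIR
        loading is negative (higher score = better care). With
        ``orient=False`` the raw sign returned by the eigendecomposition
        is kept; call :meth:`orient` later.
    anchor, fallback : str
        Index whose loading sign anchors the orientation, and the index
        used when the anchor loading is exactly zero.
    clip : bool, default True
        Clamp out-of-fit scores into [0, 100] in ``transform``.

    Attributes
    ----------
    means_, sds_ : ndarray of shape (4,)
        Standardisation constants (sample sd, n−1 denominator).
    loadings_ : ndarray of shape (4,)
        Unit-norm PC1 coefficients, oriented.
    explained_share_ : ndarray of shape (4,)
        Variance fraction per component, descending; sums to 1.
    orientation_ : int
        −1 if the eigendecomposition's sign was flipped, else +1.
    rescale_min_, rescale_max_ : float
        Fitting-set extrema of the oriented raw score.
    n_fit_units_, n_dropped_ : int
        Complete rows used for fitting / incomplete rows excluded.
    """

    def __init__(self, orient: bool = True, anchor: str = "mir",
                 fallback: str = "ylr", clip: bool = True):
        self.orient = orient
        self.anchor = anchor
        self.fallback = fallback
        self.clip = clip

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None) -> "QCIScorer":
        M = _as_index_matrix(X)
        complete = ~np.isnan(M).any(axis=1)
        self.n_dropped_ = int((~complete).sum())
        M = M[complete]
        self.n_fit_units_ = int(M.shape[0])
        if self.n_fit_units_ < 5:
            raise ContractError(
                f"need >= 5 complete index rows to fit, got "
                f"{self.n_fit_units_}")
        self.means_ = M.mean(axis=0)
        self.sds_ = M.std(axis=0, ddof=1)
        dead = [INDEX_COLUMNS[j] for j in range(M.shape[1])
                if self.sds_[j] == 0]
        if dead:
            raise ContractError(
                f"index column(s) {dead} have zero variance over the "
                "fitting set")
        Z = (M - self.means_) / self.sds_
        pca = PCA(n_components=M.shape[1], svd_solver="full").fit(Z)
        self.loadings_ = pca.components_[0].copy()
        self.explained_share_ = pca.explained_variance_ratio_.copy()
        self.orientation_ = 1
        raw = _project(Z, self.loadings_)
        self.rescale_min_ = float(raw.min())
        self.rescale_max_ = float(raw.max())
        if self.rescale_max_ <= self.rescale_min_:
            raise ContractError("degenerate fitting set: all raw scores "
                                "identical")
        if self.orient:
            self.orient_()
        return self

    def orient_(self) -> "QCIScorer":
        """Force the anchor (MIR) loading negative, flipping loadings,
        orientation and the stored raw-score bounds consistently."""
        check_is_fitted(self, "loadings_")
        a = INDEX_COLUMNS.index(self.anchor)
        f = INDEX_COLUMNS.index(self.fallback)
        pivot = self.loadings_[a] if self.loadings_[a] != 0 \
            else self.loadings_[f]
        if pivot == 0:
            raise ContractError(
                f"both anchor ({self.anchor}) and fallback "
                f"({self.fallback}) loadings are zero; orientation "
                "undefined")
        if pivot > 0:
            self.loadings_ = -self.loadings_
            self.orientation_ *= -1
            self.rescale_min_, self.rescale_max_ = (-self.rescale_max_,
                                                    -self.rescale_min_)
        return self

    # -- scoring ---------------------------------------------------------
    def raw_scores(self, X) -> np.ndarray:
        """Oriented PC1 scores before the 0–100 rescale (NaN for rows
        with missing indices)."""
        check_is_fitted(self, "loadings_")
        M = _as_index_matrix(X)
        Z = (M - self.means_) / self.sds_
        return _project(Z, self.loadings_)

    def transform(self, X, clip: bool | None = None) -> np.ndarray:
        """0–100 QCI per row; fitting-set extrema map to exactly 0/100."""
        raw = self.raw_scores(X)
        n_missing = int(np.isnan(raw).sum())
        if n_missing:
            warnings.warn(f"{n_missing} row(s) with missing indices "
                          "skipped (QCI = NaN)", stacklevel=2)
        qci = (raw - self.rescale_min_) \
            / (self.rescale_max_ - self.rescale_min_) * 100.0
        clip = self.clip if clip is None else clip
        with np.errstate(invalid="ignore"):
            outside = (qci < 0) | (qci > 100)
        if outside.any():
            if clip:
                warnings.warn(
                    f"{int(outside.sum())} out-of-fit score(s) outside "
                    "[0, 100] clamped", stacklevel=2)
                qci = np.clip(qci, 0.0, 100.0)
        return qci

    def score_frame(self, indices: pd.DataFrame,
                    clip: bool | None = None) -> pd.DataFrame:
        """Keyed score table: unit key columns + ``raw_score`` + ``qci``."""
        keys = [c for c in ("location", "year", "sex", "age_group")
                if c in indices.columns]
        out = indices.loc[:, keys].copy()
        out["raw_score"] = self.raw_scores(indices)
        out["qci"] = self.transform(indices, clip=clip)
        return out


# -- functional wrappers over the estimator -----------------------------

def fit_pca(indices) -> QCIScorer:
    """Fit the standardised PCA without resolving the sign ambiguity."""
    return QCIScorer(orient=False).fit(indices)


def orient_component(model: QCIScorer) -> QCIScorer:
    """Orient a fitted scorer so higher scores mean better care."""
    return model.orient_()


def score_qci(model: QCIScorer, indices: pd.DataFrame,
              clip: bool | None = None) -> pd.DataFrame:
    """Score an index table with a fitted, oriented model."""
    return model.score_frame(indices, clip=clip)
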