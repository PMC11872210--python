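"""Trait-scape ordination: regularized iterative PCA imputation and the
standardized PCA whose score space carries the plasticity distances.

Traits are measured on wildly different scales (um, g g^-1, mm^2, cm,
mm, counts), so the ordination standardizes each trait to zero mean and
unit variance before rotation (correlation-matrix PCA).  All ``k``
principal dimensions are retained: the full-rank rotation is an
isometry, so Euclidean distances among scores equal distances among
standardized trait values — the property that makes distance-based
plasticity indices well defined.

Missing entries are completed beforehand by regularized iterative PCA:
initialize missing cells with column means, then alternate a low-rank
reconstruction with noise-shrunk singular values and re-imputation of
the missing cells until the imputed values stabilize.  The shrinkage
(each eigenvalue reduced by the mean of the trailing, discarded
eigenvalues) guards against overfitting the missing cells when the data
are noisy, while leaving an exactly low-rank matrix untouched.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


class IterativePCAImputer(TransformerMixin, BaseEstimator):
    """Complete a replicate x trait matrix by regularized iterative PCA.

    Parameters
    ----------
    n_components : rank of the reconstruction (must be < number of traits).
    max_iter, tol : iteration stops when successive imputations change
        by less than ``tol`` in Frobenius norm (on the imputed cells).
    scale : standardize columns inside the iteration (recomputed each
        pass), appropriate when traits have incommensurate units.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 1000,
                 tol: float = 1e-8, scale: bool = True):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.scale = scale

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        M, names = _as_matrix(X)
        if M.ndim != 2:
            raise ValueError("expected a 2-D replicate x trait matrix")
        n, p = M.shape
        if not 1 <= self.n_components < p:
            raise ValueError(
                f"n_components must be in [1, {p - 1}], got {self.n_components}")
        mask = np.isnan(M)
        observed = (~mask).sum(axis=0)
        if (observed == 0).any():
            bad = np.where(observed == 0)[0][0]
            name = names[bad] if names else str(bad)
            raise ValueError(f"column {name!r} is entirely missing")
        if (observed < 2).any():
            bad = np.where(observed < 2)[0][0]
            name = names[bad] if names else str(bad)
            raise ValueError(f"column {name!r} has fewer than 2 observed values")

        self.n_features_in_ = p
        if names:
            self.feature_names_in_ = np.asarray(names, dtype=object)

        col_means = np.nanmean(M, axis=0)
        Xc = np.where(mask, col_means, M)
        if not mask.any():
            self._store(Xc)
            self.n_iter_ = 0
            return pd.DataFrame(Xc, index=X.index, columns=names) if names else Xc

        S = self.n_components
        converged = False
        for it in range(1, self.max_iter + 1):
            mu = Xc.mean(axis=0)
            if self.scale:
                sd = Xc.std(axis=0, ddof=1)
                sd = np.where(sd == 0, 1.0, sd)
            else:
                sd = np.ones(Xc.shape[1])
            Z = (Xc - mu) / sd
            U, d, Vt = np.linalg.svd(Z, full_matrices=False)
            lam = d**2 / max(n - 1, 1)
            sigma2 = lam[S:].mean() if len(lam) > S else 0.0
            shrink = np.clip((lam[:S] - sigma2) / np.where(lam[:S] > 0, lam[:S], 1.0),
                             0.0, 1.0)
            Zhat = (U[:, :S] * (shrink * d[:S])) @ Vt[:S]
            Xhat = Zhat * sd + mu
            new = np.where(mask, Xhat, M)
            delta = float(np.sqrt(((new[mask] - Xc[mask]) ** 2).sum()))
            Xc = new
            if delta < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"imputation did not converge in {self.max_iter} iterations "
                f"(last change {delta:.3g}); returning last iterate",
                ConvergenceWarning)
        self.n_iter_ = it
        self._store(Xc)
        return pd.DataFrame(Xc, index=X.index, columns=names) if names else Xc

    def _store(self, Xc: np.ndarray) -> None:
        n = Xc.shape[0]
        self.means_ = Xc.mean(axis=0)
        if self.scale:
            sd = Xc.std(axis=0, ddof=1)
            self.scales_ = np.where(sd == 0, 1.0, sd)
        else:
            self.scales_ = np.ones(Xc.shape[1])
        Z = (Xc - self.means_) / self.scales_
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        self.components_ = Vt[: self.n_components]

    def transform(self, X):
        """Complete new rows using the fitted axes (fixed-axis iteration)."""
        if not hasattr(self, "components_"):
            raise ValueError("imputer is not fitted")
        M, names = _as_matrix(X)
        if M.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fitted data")
        mask = np.isnan(M)
        if not mask.any():
            return X if isinstance(X, pd.DataFrame) else M
        V = self.components_
        Xc = np.where(mask, self.means_, M)
        for _ in range(self.max_iter):
            Z = (Xc - self.means_) / self.scales_
            Xhat = (Z @ V.T) @ V * self.scales_ + self.means_
            new = np.where(mask, Xhat, M)
            delta = float(np.sqrt(((new[mask] - Xc[mask]) ** 2).sum()))
            Xc = new
            if delta < self.tol:
                break
        if names:
            return pd.DataFrame(Xc, index=X.index, columns=names)
        return Xc


class TraitScapePCA(TransformerMixin, BaseEstimator):
    """Standardized full-rank PCA defining the trait-scape.

    Fitted attributes
    -----------------
    mean_, scale_ : per-trait centering/scaling constants.
    components_ : (k, p) rotation rows; each row's largest-magnitude
        loading is made positive so score signs are reproducible.
    loadings_ : trait x dimension loading matrix (``components_.T``).
    explained_variance_ratio_ : fraction of variance per dimension
        (sums to 1 since all dimensions are kept).
    scores_ : training scores, zero column means.
    """

    def __init__(self, scale: bool = True):
        self.scale = scale

    def fit(self, X, y=None):
        M, names = _as_matrix(X)
        if M.ndim != 2 or M.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 replicates")
        if np.isnan(M).any():
            raise ValueError("input contains missing values; impute first")
        self.n_features_in_ = M.shape[1]
        self.feature_names_in_ = (np.asarray(names, dtype=object) if names
                                  else np.asarray([f"trait_{i}" for i in
                                                   range(M.shape[1])], dtype=object))
        self.mean_ = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        if self.scale:
            if (sd == 0).any():
                bad = self.feature_names_in_[np.where(sd == 0)[0][0]]
                raise ValueError(
                    f"trait {bad!r} has zero variance and cannot be unit-scaled")
            self.scale_ = sd
        else:
            self.scale_ = np.ones(M.shape[1])
        Z = (M - self.mean_) / self.scale_
        pca = PCA(n_components=None, svd_solver="full").fit(Z)
        comps = pca.components_.copy()
        for row in comps:
            j = np.argmax(np.abs(row))
            if row[j] < 0:
                row *= -1.0
        self.components_ = comps
        self.n_components_ = comps.shape[0]
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        scores = Z @ comps.T
        cols = [f"CV{i + 1}" for i in range(self.n_components_)]
        if isinstance(X, pd.DataFrame):
            self.scores_ = pd.DataFrame(scores, index=X.index, columns=cols)
            self.loadings_ = pd.DataFrame(comps.T, index=names, columns=cols)
        else:
            self.scores_ = scores
            self.loadings_ = comps.T
        return self

    def transform(self, X):
        if not hasattr(self, "components_"):
            raise ValueError("trait-scape is not fitted")
        M, names = _as_matrix(X)
        single = M.ndim == 1
        M = np.atleast_2d(M)
        if M.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} traits, got {M.shape[1]}")
        if names and list(names) != list(self.feature_names_in_):
            raise ValueError("trait names do not match the fitted trait set")
        if np.isnan(M).any():
            raise ValueError("input contains missing values; impute first")
        Z = (M - self.mean_) / self.scale_
        scores = Z @ self.components_.T
        if isinstance(X, pd.DataFrame):
            cols = [f"CV{i + 1}" for i in range(self.n_components_)]
            return pd.DataFrame(scores, index=X.index, columns=cols)
        return scores[0] if single else scores


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def impute_missing(traits, n_components: int = 2, max_iter: int = 1000,
                   tol: float = 1e-8, scale: bool = True):
    """Complete a replicate x trait matrix (see :class:`IterativePCAImputer`)."""
    return IterativePCAImputer(n_components=n_components, max_iter=max_iter,
                               tol=tol, scale=scale).fit_transform(traits)


def fit_trait_scape(traits, scale: bool = True) -> TraitScapePCA:
    """Fit the trait-scape ordination on a completed trait matrix."""
    return TraitScapePCA(scale=scale).fit(traits)


def project(scape: TraitScapePCA, new_traits):
    """Project complete new trait rows into an existing trait-scape."""
    return scape.transform(new_traits)
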