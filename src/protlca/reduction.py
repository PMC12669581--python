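"""Protein-matrix standardization, PCA reduction, and PC categorization.

The protein matrix (samples x proteins, continuous) is z-scored per protein,
reduced to its leading principal components, and the component scores are
discretized at percentile cutpoints under competing schemes (quartiles,
deciles, 10th/90th, 20th/80th).  The winning scheme is the one whose latent
class fit has the highest relative entropy.  Training means/SDs and
cutpoints are frozen so the identical transformation can be applied to an
external cohort measured on a partially overlapping protein panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .lca import CategoricalDesign, LatentClassAnalysis, relative_entropy

__all__ = [
    "SCHEMES",
    "CategorizationScheme",
    "Standardizer",
    "PCAReducer",
    "standardize",
    "fit_pca",
    "project",
    "compute_cutpoints",
    "categorize",
    "select_scheme",
]

# percentile cut-offs per scheme; category count = len(cuts) + 1
SCHEMES: dict[str, tuple[float, ...]] = {
    "quartiles": (25.0, 50.0, 75.0),
    "deciles": tuple(float(q) for q in range(10, 100, 10)),
    "p10_90": (10.0, 90.0),
    "p20_80": (20.0, 80.0),
}


@dataclass
class CategorizationScheme:
    """A named percentile-based discretization of PC scores.

    ``cutpoints`` (n_cuts x n_components) are the training-score percentile
    values, frozen after fitting so external cohorts are binned identically.
    """

    name: str
    percentiles: tuple[float, ...]
    cutpoints: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        if p.size < 1 or np.any(p <= 0) or np.any(p >= 100) or np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be strictly increasing within (0, 100)")

    @property
    def n_categories(self) -> int:
        return len(self.percentiles) + 1

    @classmethod
    def by_name(cls, name: str) -> "CategorizationScheme":
        if name not in SCHEMES:
            raise ValueError(f"unknown scheme {name!r}; choose from {sorted(SCHEMES)}")
        return cls(name, SCHEMES[name])


class Standardizer(BaseEstimator, TransformerMixin):
    """Per-protein z-scoring with sample SD (ddof=1), frozen for reuse.

    Unlike sklearn's StandardScaler this uses the sample standard deviation,
    so a 3-point column (1, 2, 3) maps exactly to (-1, 0, 1), and it refuses
    zero-variance proteins by name.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "Standardizer":
        X = _as_frame(X)
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=1)
        bad = self.sds_.index[(self.sds_ <= 0) | ~np.isfinite(self.sds_)]
        if len(bad):
            raise ValueError(f"zero-variance proteins cannot be standardized: {list(bad)}")
        self.protein_ids_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = _as_frame(X)
        shared = [p for p in X.columns if p in set(self.protein_ids_)]
        if len(shared) != X.shape[1]:
            raise ValueError("matrix contains proteins unknown to the standardizer")
        return (X - self.means_[X.columns]) / self.sds_[X.columns]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        df = X
    else:
        df = pd.DataFrame(np.asarray(X, dtype=float))
        df.columns = [f"prot{j + 1}" for j in range(df.shape[1])]
    if df.isna().any().any():
        raise ValueError("protein matrix contains missing values")
    return df.astype(float)


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Z-score every protein; returns the transformed matrix and the frozen stats."""
    s = Standardizer().fit(X)
    return s.transform(X), s


class PCAReducer(BaseEstimator, TransformerMixin):
    """PCA on the standardized protein matrix with a fixed sign convention.

    The sign of each component is chosen so its largest-magnitude loading is
    positive, making the decomposition deterministic across runs and
    platforms.  ``transform`` projects through the intersection of protein
    identifiers, standardizing the incoming matrix with the TRAINING
    means/SDs of the shared proteins — the rule that keeps one frozen model
    applicable to an external panel.
    """

    def __init__(self, n_components: int = 20, min_shared_fraction: float = 0.8):
        self.n_components = n_components
        self.min_shared_fraction = min_shared_fraction

    def fit(self, X: pd.DataFrame, y=None) -> "PCAReducer":
        X = _as_frame(X)
        n, p = X.shape
        if self.n_components > min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n-1, p)={min(n - 1, p)}"
            )
        self.standardizer_ = Standardizer().fit(X)
        Z = self.standardizer_.transform(X).to_numpy()
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(Z)
        W = pca.components_.T  # p x C loadings
        # deterministic sign: largest-|loading| entry of each component positive
        flip = np.sign(W[np.abs(W).argmax(axis=0), np.arange(W.shape[1])])
        flip[flip == 0] = 1.0
        self.loadings_ = W * flip[None, :]
        self.explained_variance_ = pca.explained_variance_.copy()
        self.explained_variance_ratio_ = pca.explained_variance_ratio_.copy()
        self.protein_ids_ = list(X.columns)
        self.means_ = self.standardizer_.means_.to_numpy()
        self.sds_ = self.standardizer_.sds_.to_numpy()
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Project a (possibly external) matrix onto the training loadings."""
        X = _as_frame(X)
        index = {p: i for i, p in enumerate(self.protein_ids_)}
        shared = [p for p in X.columns if p in index]
        self.shared_fraction_ = len(shared) / len(self.protein_ids_)
        if not shared:
            raise ValueError("no overlap between matrix proteins and model proteins")
        if self.shared_fraction_ < self.min_shared_fraction:
            raise ValueError(
                f"shared-protein fraction {self.shared_fraction_:.3f} below the "
                f"floor {self.min_shared_fraction}"
            )
        rows = np.array([index[p] for p in shared])
        Z = (X[shared].to_numpy() - self.means_[rows][None, :]) / self.sds_[rows][None, :]
        return Z @ self.loadings_[rows, :]

    def to_dict(self) -> dict:
        return {
            "n_components": int(self.n_components),
            "min_shared_fraction": self.min_shared_fraction,
            "protein_ids": self.protein_ids_,
            "means": self.means_.tolist(),
            "sds": self.sds_.tolist(),
            "loadings": self.loadings_.tolist(),
            "explained_variance": self.explained_variance_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAReducer":
        m = cls(n_components=d["n_components"], min_shared_fraction=d["min_shared_fraction"])
        m.protein_ids_ = list(d["protein_ids"])
        m.means_ = np.asarray(d["means"], dtype=float)
        m.sds_ = np.asarray(d["sds"], dtype=float)
        m.loadings_ = np.asarray(d["loadings"], dtype=float)
        m.explained_variance_ = np.asarray(d["explained_variance"], dtype=float)
        m.explained_variance_ratio_ = np.asarray(d["explained_variance_ratio"], dtype=float)
        m.standardizer_ = Standardizer()
        m.standardizer_.means_ = pd.Series(m.means_, index=m.protein_ids_)
        m.standardizer_.sds_ = pd.Series(m.sds_, index=m.protein_ids_)
        m.standardizer_.protein_ids_ = list(m.protein_ids_)
        return m


def fit_pca(X: pd.DataFrame, n_components: int = 20, **kwargs) -> PCAReducer:
    return PCAReducer(n_components=n_components, **kwargs).fit(X)


def project(model: PCAReducer, X: pd.DataFrame) -> np.ndarray:
    return model.transform(X)


def compute_cutpoints(scores: np.ndarray, scheme: CategorizationScheme) -> np.ndarray:
    """Percentile cutpoints per component, linear interpolation between
    order statistics (numpy's default quantile definition)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return np.percentile(scores, list(scheme.percentiles), axis=0, method="linear")


def categorize(
    scores: np.ndarray,
    scheme: CategorizationScheme,
    cutpoints: np.ndarray | None = None,
) -> tuple[CategoricalDesign, np.ndarray]:
    """Discretize PC scores at the scheme's percentile cutpoints.

    Codes are 1-based; a value equal to a cutpoint falls in the upper bin.
    If ``cutpoints`` is None they are computed on ``scores`` (training);
    otherwise the frozen training cutpoints are applied (external cohort).
    Empty bins (possible under heavy ties) are retained with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if cutpoints is None:
        cutpoints = compute_cutpoints(scores, scheme)
    cutpoints = np.asarray(cutpoints, dtype=float)
    if cutpoints.shape != (len(scheme.percentiles), scores.shape[1]):
        raise ValueError("cutpoints shape does not match scheme/score dimensions")
    R = scheme.n_categories
    codes = np.empty(scores.shape, dtype=np.int64)
    for c in range(scores.shape[1]):
        codes[:, c] = np.digitize(scores[:, c], cutpoints[:, c]) + 1
        counts = np.bincount(codes[:, c], minlength=R + 1)[1:]
        if np.any(counts == 0):
            warnings.warn(
                f"component {c + 1}: empty category under scheme {scheme.name!r} "
                "(ties at a cutpoint); bins retained"
            )
    design = CategoricalDesign(
        codes,
        np.full(scores.shape[1], R, dtype=np.int64),
        [f"PC{c + 1}" for c in range(scores.shape[1])],
    )
    return design, cutpoints


def select_scheme(
    scores: np.ndarray,
    schemes: list[str] | None = None,
    n_classes: int = 3,
    n_starts: int = 10,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[CategorizationScheme, pd.DataFrame]:
    """Pick the categorization scheme whose LCA fit has the highest entropy.

    Each candidate scheme is applied to the training scores and a K-class
    latent class model is fitted to the resulting design; schemes are ranked
    by the relative entropy of the fit.  Ties break toward fewer categories,
    then lexicographic name.  Schemes whose fit fails are excluded with a
    warning; the winning scheme is returned with its training cutpoints
    frozen.  The continuous scores seed the structured EM starts.
    """
    names = list(schemes) if schemes is not None else sorted(SCHEMES)
    if not names:
        raise ValueError("at least one scheme is required")
    rows = []
    fitted: dict[str, CategorizationScheme] = {}
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(names)) % (2**31)
    for name, s in zip(names, seeds):
        scheme = CategorizationScheme.by_name(name)
        design, cuts = categorize(scores, scheme)
        try:
            model = LatentClassAnalysis(
                n_classes=n_classes,
                n_starts=n_starts,
                max_iter=max_iter,
                tol=tol,
                random_state=int(s),
            ).fit(design, init_scores=scores)
        except ValueError as err:
            warnings.warn(f"scheme {name!r} excluded: LCA failed ({err})")
            continue
        scheme.cutpoints = cuts
        fitted[name] = scheme
        rows.append(
            {
                "scheme": name,
                "n_categories": scheme.n_categories,
                "entropy": model.entropy_,
                "bic": model.bic_,
                "loglik": model.loglik_,
                "converged": model.converged_,
            }
        )
    if not rows:
        raise ValueError("every candidate scheme failed to fit")
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["entropy", "n_categories", "scheme"], ascending=[False, True, True]
    )
    best = str(ranked.iloc[0]["scheme"])
    return fitted[best], table.reset_index(drop=True)
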