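"""End-to-end derivation and external application of the stratification model.

``ProteomicStratifier`` chains the full derivation: per-protein z-scoring,
PCA to the leading components, percentile categorization of the scores under
competing schemes with entropy-based scheme selection, BIC + bootstrap-LRT
selection of the number of classes, a final latent class fit, and
maximum-posterior assignment.  The fitted object freezes every training
statistic (means/SDs, loadings, cutpoints, class parameters) so the single
derived model can be applied unchanged to an external cohort measured on a
partially overlapping protein panel.  Models serialize to a versioned JSON
document that round-trips to bit-identical assignments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .lca import (
    CategoricalDesign,
    LatentClassAnalysis,
    SelectKResult,
    assign,
    select_k,
)
from .reduction import CategorizationScheme, PCAReducer, categorize, select_scheme
from .survival import SurvivalResult, cox_fit, km_logrank, truncate_outcome_table

__all__ = ["ProteomicStratifier", "derive_model", "apply_model", "run_association",
           "save_model", "load_model"]

SCHEMA_VERSION = 1


class ProteomicStratifier(BaseEstimator, ClusterMixin):
    """Latent-class stratification model over a protein expression matrix.

    Parameters
    ----------
    n_components : int
        Principal components retained (20 by default; 30 is the customary
        sensitivity setting).
    schemes : list of str or None
        Candidate percentile categorization schemes (None = all four).
    scheme_k : int
        Class count at which scheme entropies are compared.
    k_max : int
        Largest class count considered by BIC/BLRT selection.
    n_bootstrap : int
        Bootstrap replicates for the likelihood-ratio test (999 by default).
    n_classes : int or None
        Fix the class count and skip selection (None = select).
    n_starts, max_iter, tol : EM settings for the latent class fits.
    min_shared_fraction : float
        Minimum protein-id overlap required to apply the model externally.
    random_state : int
        Root seed; all stages draw from streams spawned from it.

    Fitted attributes include ``reducer_``, ``scheme_``, ``lca_``,
    ``n_classes_``, ``labels_``, ``posterior_`` and ``report_``.
    """

    def __init__(
        self,
        n_components: int = 20,
        schemes: list[str] | None = None,
        scheme_k: int = 3,
        k_max: int = 6,
        n_bootstrap: int = 999,
        n_classes: int | None = None,
        n_starts: int = 20,
        max_iter: int = 500,
        tol: float = 1e-6,
        min_shared_fraction: float = 0.8,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.schemes = schemes
        self.scheme_k = scheme_k
        self.k_max = k_max
        self.n_bootstrap = n_bootstrap
        self.n_classes = n_classes
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.min_shared_fraction = min_shared_fraction
        self.random_state = random_state

    # -- derivation ---------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None, extra_design: CategoricalDesign | None = None):
        """Derive the stratification model on a training protein matrix.

        ``extra_design`` optionally concatenates pre-coded categorical items
        (e.g. clinical variables) with the PC design — the combined
        clinical+proteomic clustering — without a separate code path.
        """
        seeds = np.random.SeedSequence(self.random_state).generate_state(4) % (2**31)
        self.reducer_ = PCAReducer(
            n_components=self.n_components,
            min_shared_fraction=self.min_shared_fraction,
        ).fit(X)
        scores = self.reducer_.transform(X)

        self.scheme_, scheme_table = select_scheme(
            scores,
            schemes=self.schemes,
            n_classes=self.scheme_k,
            n_starts=max(self.n_starts // 2, 2),
            seed=int(seeds[0]),
            max_iter=self.max_iter,
            tol=self.tol,
        )
        design, _ = categorize(scores, self.scheme_, self.scheme_.cutpoints)
        if extra_design is not None:
            design = extra_design.concat(design)
        self.extra_items_ = (
            None
            if extra_design is None
            else {
                "labels": list(extra_design.item_labels),
                "n_categories": extra_design.n_categories.tolist(),
            }
        )

        if self.n_classes is not None:
            self.n_classes_ = int(self.n_classes)
            selection: SelectKResult | None = None
        else:
            selection = select_k(
                design,
                k_max=self.k_max,
                n_bootstrap=self.n_bootstrap,
                n_starts=self.n_starts,
                seed=int(seeds[1]),
                max_iter=self.max_iter,
                tol=self.tol,
                init_scores=scores if extra_design is None else None,
            )
            self.n_classes_ = selection.n_classes

        self.lca_ = LatentClassAnalysis(
            n_classes=self.n_classes_,
            n_starts=self.n_starts,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=int(seeds[2]),
        ).fit(design, init_scores=scores if extra_design is None else None)
        self.posterior_ = self.lca_.predict_proba(design)
        self.labels_, self.max_posterior_ = assign(self.posterior_)
        self.sample_ids_ = list(X.index) if isinstance(X, pd.DataFrame) else None

        sizes = pd.Series(self.labels_).value_counts().sort_index()
        self.report_ = {
            "scheme_table": scheme_table,
            "scheme": self.scheme_.name,
            "selection": selection,
            "n_classes": self.n_classes_,
            "entropy": self.lca_.entropy_,
            "bic": self.lca_.bic_,
            "cluster_sizes": sizes.to_dict(),
        }
        return self

    # -- external application -----------------------------------------------

    def _design(self, X: pd.DataFrame) -> CategoricalDesign:
        if self.extra_items_ is not None:
            raise ValueError(
                "model was derived with extra categorical items; use predict_design"
            )
        scores = self.reducer_.transform(X)
        design, _ = categorize(scores, self.scheme_, self.scheme_.cutpoints)
        return design

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.lca_.predict_proba(self._design(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Maximum-posterior cluster labels (1-based) for a protein matrix."""
        return assign(self.predict_proba(X))[0]

    def predict_design(self, design: CategoricalDesign) -> np.ndarray:
        """Assignments for a pre-built design (combined-clustering path)."""
        return assign(self.lca_.predict_proba(design))[0]

    def application_report(self, X: pd.DataFrame) -> dict:
        tau = self.predict_proba(X)
        labels, maxp = assign(tau)
        return {
            "shared_fraction": self.reducer_.shared_fraction_,
            "cluster_sizes": pd.Series(labels).value_counts().sort_index().to_dict(),
            "mean_max_posterior": float(maxp.mean()),
            "min_max_posterior": float(maxp.min()),
        }

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        params = self.get_params()
        payload = {
            "schema_version": SCHEMA_VERSION,
            "params": params,
            "reducer": self.reducer_.to_dict(),
            "scheme": {
                "name": self.scheme_.name,
                "percentiles": list(self.scheme_.percentiles),
                "cutpoints": np.asarray(self.scheme_.cutpoints).tolist(),
            },
            "lca": self.lca_.to_dict(),
            "n_classes": self.n_classes_,
            "extra_items": self.extra_items_,
        }
        blob = json.dumps(
            {k: v for k, v in payload.items() if k != "provenance"}, sort_keys=True
        )
        payload["provenance"] = {
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": params["random_state"],
        }
        return payload

    @classmethod
    def from_dict(cls, d: dict) -> "ProteomicStratifier":
        for key in ("schema_version", "reducer", "scheme", "lca", "n_classes"):
            if key not in d:
                raise ValueError(f"invalid model document: missing {key!r}")
        if d["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {d['schema_version']}")
        model = cls(**d["params"])
        model.reducer_ = PCAReducer.from_dict(d["reducer"])
        scheme = CategorizationScheme(
            d["scheme"]["name"], tuple(d["scheme"]["percentiles"])
        )
        scheme.cutpoints = np.asarray(d["scheme"]["cutpoints"], dtype=float)
        model.scheme_ = scheme
        model.lca_ = LatentClassAnalysis.from_dict(d["lca"])
        model.n_classes_ = int(d["n_classes"])
        model.extra_items_ = d.get("extra_items")
        return model


def save_model(model: ProteomicStratifier, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, sort_keys=True, indent=1)


def load_model(path: str | Path) -> ProteomicStratifier:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as err:
            raise ValueError(f"corrupted model file {path}: {err}") from err
    if not isinstance(d, dict):
        raise ValueError(f"corrupted model file {path}: not a JSON object")
    return ProteomicStratifier.from_dict(d)


def derive_model(
    proteins: pd.DataFrame, **params
) -> tuple[ProteomicStratifier, dict]:
    """Fit a stratification model; returns the model and its derivation report."""
    model = ProteomicStratifier(**params).fit(proteins)
    return model, model.report_


def apply_model(
    model: ProteomicStratifier, proteins: pd.DataFrame
) -> tuple[pd.Series, np.ndarray, dict]:
    """Assign an external cohort with the frozen model.

    Returns labels (indexed by sample id), the posterior matrix, and an
    application report (shared-protein fraction, assignment confidence).
    """
    tau = model.predict_proba(proteins)
    labels, _ = assign(tau)
    report = model.application_report(proteins)
    return pd.Series(labels, index=proteins.index, name="cluster"), tau, report


def run_association(
    labels,
    outcomes: pd.DataFrame,
    horizon: float = 3.0,
    reference=None,
    endpoints: list[str] | None = None,
) -> dict[str, SurvivalResult]:
    """Cluster-vs-outcome association for every endpoint in the table.

    Follow-up is truncated at ``horizon`` years; each endpoint gets KM
    curves, the multi-group log-rank test, Cox hazard ratios against the
    reference cluster (default: the cluster with the lowest crude event rate
    for that endpoint), and Harrell's C of the Cox linear predictor.
    """
    labels = np.asarray(labels)
    if len(pd.unique(labels)) < 2:
        raise ValueError("association requires at least two clusters")
    trunc = truncate_outcome_table(outcomes, horizon)
    if endpoints is None:
        endpoints = [c[len("time_"):] for c in trunc.columns if c.startswith("time_")]
    if not endpoints:
        raise ValueError("no time_/event_ endpoint columns found")
    results: dict[str, SurvivalResult] = {}
    for ep in endpoints:
        tcol, ecol = f"time_{ep}", f"event_{ep}"
        if tcol not in trunc.columns or ecol not in trunc.columns:
            raise ValueError(f"missing endpoint columns for {ep!r}")
        time = trunc[tcol].to_numpy(dtype=float)
        event = trunc[ecol].to_numpy(dtype=int)
        ref = reference
        if ref is None:
            rates = {
                g: event[labels == g].mean() for g in sorted(pd.unique(labels))
            }
            ref = min(rates, key=lambda g: (rates[g], g))
        km, chi2, dof, p = km_logrank(time, event, labels)
        res = cox_fit(time, event, labels=labels, reference=ref, endpoint=ep)
        res.logrank_chi2, res.logrank_df, res.logrank_p = chi2, dof, p
        res.km = km
        results[ep] = res
    return results
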