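"""Latent class analysis of categorical indicators.

A latent class model describes ``n`` samples observed on ``J`` categorical
items (item ``j`` has ``R_j`` categories) as a finite mixture of ``K``
classes.  Class ``k`` has mixing proportion ``pi_k`` and item-response
probabilities ``rho_{jrk} = P(y_j = r | class k)``; items are conditionally
independent given the class.  The model is fitted by EM from multiple random
starts, the number of classes is chosen by BIC followed by a parametric
bootstrap likelihood-ratio test (BLRT), and samples are assigned to their
maximum-posterior class.  A Gaussian latent-profile variant operating on
continuous scores is provided for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

__all__ = [
    "CategoricalDesign",
    "LatentClassAnalysis",
    "LatentProfileAnalysis",
    "BLRTResult",
    "SelectKResult",
    "fit_lca",
    "posterior",
    "relative_entropy",
    "simulate_from_model",
    "blrt",
    "select_k",
    "assign",
    "fit_lpa",
]


@dataclass
class CategoricalDesign:
    """A matrix of 1-based category codes, one column per categorical item.

    ``codes`` is an ``(n, J)`` integer array with entries in ``1..R_j``;
    ``n_categories`` holds ``R_j`` per item.  ``R_j`` may exceed the largest
    observed code (categories legal under a scheme but unobserved in a
    particular sample).
    """

    codes: np.ndarray
    n_categories: np.ndarray
    item_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if self.n_categories.shape != (self.codes.shape[1],):
            raise ValueError("n_categories must have one entry per item")
        if self.codes.shape[0] and (
            self.codes.min() < 1 or np.any(self.codes.max(axis=0) > self.n_categories)
        ):
            raise ValueError("category codes must lie in 1..R_j for every item")
        if self.item_labels is None:
            self.item_labels = [f"item{j + 1}" for j in range(self.codes.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_items(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_codes(cls, codes, n_categories=None, item_labels=None) -> "CategoricalDesign":
        codes = np.asarray(codes, dtype=np.int64)
        if n_categories is None:
            n_categories = codes.max(axis=0)
        return cls(codes, np.asarray(n_categories), item_labels)

    def concat(self, other: "CategoricalDesign") -> "CategoricalDesign":
        """Column-wise concatenation (used for combined clinical+PC designs)."""
        if other.n_samples != self.n_samples:
            raise ValueError("designs have different numbers of samples")
        return CategoricalDesign(
            np.hstack([self.codes, other.codes]),
            np.concatenate([self.n_categories, other.n_categories]),
            list(self.item_labels) + list(other.item_labels),
        )


def _as_design(X) -> CategoricalDesign:
    if isinstance(X, CategoricalDesign):
        return X
    if isinstance(X, pd.DataFrame):
        return CategoricalDesign.from_codes(X.to_numpy(), item_labels=list(X.columns))
    return CategoricalDesign.from_codes(X)


def relative_entropy(tau: np.ndarray, n_classes: int | None = None) -> float:
    """Relative entropy of a posterior matrix, in [0, 1].

    ``E = 1 - sum_i sum_k -tau_ik ln tau_ik / (n ln K)`` with ``0 ln 0 := 0``.
    1 means perfectly crisp assignment, 0 maximal uncertainty.  Defined as 1
    for a one-class model.
    """
    tau = np.asarray(tau, dtype=float)
    K = n_classes if n_classes is not None else tau.shape[1]
    if K <= 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(tau > 0, tau * np.log(tau), 0.0)
    n = tau.shape[0]
    return float(1.0 + plogp.sum() / (n * np.log(K)))


class LatentClassAnalysis(BaseEstimator):
    """Latent class model for categorical indicators, fitted by EM.

    Parameters
    ----------
    n_classes : int
        Number of latent classes K.
    n_starts : int
        Random EM initializations; the best-loglik solution is kept.
    max_iter, tol : int, float
        EM stops when the loglik gain falls below ``tol``.
    rho_floor : float
        Item-response probabilities are floored at this value and
        renormalized after each M-step, preventing degenerate -inf logliks.
    random_state : int or None
        Seed for the initializations.

    Fitted attributes: ``weights_`` (pi, decreasing), ``rho_`` (J x Rmax x K,
    padded with zeros beyond R_j), ``n_categories_``, ``loglik_``, ``bic_``,
    ``entropy_``, ``n_params_``, ``converged_``, ``n_iter_``,
    ``loglik_trace_`` (per-iteration loglik of the winning start).
    """

    def __init__(
        self,
        n_classes: int = 3,
        n_starts: int = 20,
        max_iter: int = 500,
        tol: float = 1e-6,
        rho_floor: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_classes = n_classes
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.rho_floor = rho_floor
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    #
    # The EM hot loop works in a "stacked" parameter space: the item-response
    # probabilities of all items are concatenated into one (sum_j R_j, K)
    # block matrix, and the design is one-hot encoded into an (n, sum_j R_j)
    # indicator matrix O.  Then the per-sample class log-likelihood is the
    # single matmul O @ log(rho_stack), and the M-step count matrix is
    # O.T @ tau — both BLAS calls, which keeps bootstrap-heavy model
    # selection tractable.

    @staticmethod
    def _offsets(n_categories: np.ndarray) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(n_categories)])

    def _stack_design(self, design: CategoricalDesign) -> np.ndarray:
        off = self._offsets(design.n_categories)
        cols = off[:-1][None, :] + (design.codes - 1)
        O = np.zeros((design.n_samples, off[-1]))
        O[np.arange(design.n_samples)[:, None], cols] = 1.0
        return O

    def _m_step(self, counts: np.ndarray, Nk: np.ndarray, offsets: np.ndarray):
        """Mixing proportions and floored/renormalized rho from soft counts."""
        pi = np.clip(Nk, 1e-12, None)
        pi = pi / pi.sum()
        rho = counts / np.clip(Nk, 1e-12, None)[None, :]
        rho = np.clip(rho, self.rho_floor, None)
        sums = np.add.reduceat(rho, offsets[:-1], axis=0)
        rho /= np.repeat(sums, np.diff(offsets), axis=0)
        return pi, rho

    def _init_params(
        self, O: np.ndarray, offsets: np.ndarray, rng, kind: str,
        init_scores: np.ndarray | None = None,
        w: np.ndarray | None = None,
    ):
        """Starting (pi, rho) for one EM run.

        ``kind='kmeans'``: a structure-seeking start — k-means on
        ``init_scores`` when the caller supplies the continuous scores the
        design was discretized from (the reliable route: class structure
        carried by a minority of items is nearly invisible in the one-hot
        geometry), otherwise k-means on the leading singular directions of
        the centered one-hot design.  Hard labels are softened to 0.95
        posterior mass.  ``kind='random'``: independent Dirichlet draws of
        each item's response profile per class — dispersed random restarts.
        """
        n, K = O.shape[0], self.n_classes
        if kind == "kmeans":
            from sklearn.cluster import KMeans

            if init_scores is not None:
                emb = np.asarray(init_scores, dtype=float)
            else:
                Oc = O - O.mean(axis=0, keepdims=True)
                ncomp = min(max(K, 2), min(Oc.shape) - 1) or 1
                try:
                    _, sv, vt = np.linalg.svd(Oc, full_matrices=False)
                    emb = Oc @ vt[:ncomp].T
                except np.linalg.LinAlgError:
                    emb = Oc
            km = KMeans(n_clusters=K, n_init=10, random_state=int(rng.integers(2**31)))
            labels = km.fit(emb, sample_weight=w).labels_
            tau = np.full((n, K), 0.05 / max(K - 1, 1))
            tau[np.arange(n), labels] = 0.95
            tw = tau if w is None else tau * w[:, None]
            return self._m_step(O.T @ tw, tw.sum(axis=0), offsets)
        pi = np.full(K, 1.0 / K)
        rho = np.empty((offsets[-1], K))
        for a, b in zip(offsets[:-1], offsets[1:]):
            rho[a:b] = rng.dirichlet(np.ones(b - a), size=K).T
        rho = np.clip(rho, self.rho_floor, None)
        for a, b in zip(offsets[:-1], offsets[1:]):
            rho[a:b] /= rho[a:b].sum(axis=0, keepdims=True)
        return pi, rho

    def _em(self, O, offsets, rng, kind="random", init_scores=None, w=None):
        """One EM run; ``w`` optionally weights rows (collapsed patterns)."""
        pi, rho = self._init_params(O, offsets, rng, kind, init_scores, w)
        trace = []
        converged = False
        for _ in range(self.max_iter):
            logp = O @ np.log(rho) + np.log(pi)[None, :]
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum() if w is None else (w * norm).sum())
            tau = np.exp(logp - norm[:, None])
            trace.append(ll)
            if len(trace) > 1 and trace[-1] - trace[-2] < self.tol:
                converged = True
                break
            tw = tau if w is None else tau * w[:, None]
            pi, rho = self._m_step(O.T @ tw, tw.sum(axis=0), offsets)
        return pi, rho, tau, trace, converged

    def _unstack_rho(self, rho_stack: np.ndarray, n_categories: np.ndarray) -> np.ndarray:
        Rmax = int(n_categories.max())
        K = rho_stack.shape[1]
        rho = np.zeros((len(n_categories), Rmax, K))
        off = self._offsets(n_categories)
        for j, (a, b) in enumerate(zip(off[:-1], off[1:])):
            rho[j, : b - a, :] = rho_stack[a:b]
        return rho

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None, init_scores=None) -> "LatentClassAnalysis":
        """Fit by EM from ``n_starts`` initializations.

        ``init_scores`` optionally supplies the continuous matrix the design
        was discretized from; the structured starts then run k-means on it.
        """
        design = _as_design(X)
        K = self.n_classes
        if K < 1:
            raise ValueError("n_classes must be >= 1")
        patterns, counts = np.unique(design.codes, axis=0, return_counts=True)
        n_patterns = patterns.shape[0]
        if K > n_patterns:
            raise ValueError(
                f"n_classes={K} exceeds the {n_patterns} distinct response patterns"
            )
        self.n_categories_ = design.n_categories.copy()
        offsets = self._offsets(design.n_categories)
        O = self._stack_design(design)
        n = design.n_samples

        if K == 1:
            # closed-form one-class ML: rho = marginal category frequencies
            counts = O.sum(axis=0)
            ll = 0.0
            rho_stack = np.empty((offsets[-1], 1))
            for a, b in zip(offsets[:-1], offsets[1:]):
                freq = counts[a:b] / n
                f = np.clip(freq, self.rho_floor, None)
                f /= f.sum()
                rho_stack[a:b, 0] = f
                nz = freq > 0
                ll += float((counts[a:b][nz] * np.log(f[nz])).sum())
            self.weights_ = np.array([1.0])
            self.rho_ = self._unstack_rho(rho_stack, design.n_categories)
            self.loglik_ = ll
            self.loglik_trace_ = [ll]
            self.converged_ = True
            self.n_iter_ = 0
        else:
            rng = np.random.default_rng(self.random_state)
            # duplicate response patterns collapse into weighted unique rows
            # (a big win for small designs in the bootstrap-heavy paths);
            # incompatible with score-seeded starts, which are per-sample
            if init_scores is None and n_patterns < 0.7 * n:
                O_fit = self._stack_design(
                    CategoricalDesign(patterns, design.n_categories)
                )
                w = counts.astype(float)
            else:
                O_fit, w = O, None
            best = None
            n_struct = max(1, min(3, self.n_starts // 4))
            for s in range(self.n_starts):
                kind = "kmeans" if s < n_struct else "random"
                pi, rho_stack, tau, trace, conv = self._em(
                    O_fit, offsets, rng, kind, init_scores, w
                )
                if best is None or trace[-1] > best[3][-1]:
                    best = (pi, rho_stack, tau, trace, conv)
            pi, rho_stack, tau, trace, conv = best
            rho = self._unstack_rho(rho_stack, design.n_categories)
            # canonical ordering: decreasing mixing proportion
            order = np.argsort(-pi, kind="stable")
            self.weights_ = pi[order]
            self.rho_ = rho[:, :, order]
            self.loglik_ = trace[-1]
            self.loglik_trace_ = trace
            self.converged_ = bool(conv)
            self.n_iter_ = len(trace)
            if not conv:
                warnings.warn(
                    "EM did not converge in any start; best iterate returned",
                    RuntimeWarning,
                )

        self.n_params_ = int((K - 1) + K * (design.n_categories - 1).sum())
        self.bic_ = -2.0 * self.loglik_ + self.n_params_ * np.log(n)
        self.entropy_ = relative_entropy(self.predict_proba(design), K)
        return self

    def _log_components(self, design: CategoricalDesign) -> np.ndarray:
        """(n, K) matrix of log pi_k + sum_j log rho_{j, y_ij, k}."""
        if design.n_items != self.rho_.shape[0]:
            raise ValueError("design has a different number of items than the model")
        if np.any(design.codes.max(axis=0) > self.n_categories_):
            raise ValueError("design contains category codes unseen by the model")
        J = design.n_items
        with np.errstate(divide="ignore"):
            logrho = np.where(self.rho_ > 0, np.log(np.clip(self.rho_, 1e-300, None)), -np.inf)
        ll = logrho[np.arange(J)[None, :], design.codes - 1, :].sum(axis=1)
        return ll + np.log(self.weights_)[None, :]

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class-membership probabilities tau_ik (rows sum to 1)."""
        logp = self._log_components(_as_design(X))
        return np.exp(logp - logsumexp(logp, axis=1)[:, None])

    def score(self, X) -> float:
        """Total log-likelihood of a design under the fitted model."""
        return float(logsumexp(self._log_components(_as_design(X)), axis=1).sum())

    def predict(self, X) -> np.ndarray:
        """Maximum-posterior class labels (1-based; ties -> lowest class)."""
        return np.argmax(self.predict_proba(X), axis=1) + 1

    def sample(self, n: int, random_state: int | None = None) -> CategoricalDesign:
        """Draw a design from the fitted model (parametric bootstrap draw)."""
        rng = np.random.default_rng(random_state)
        K = self.weights_.shape[0]
        labels = rng.choice(K, size=n, p=self.weights_)
        J = self.rho_.shape[0]
        codes = np.empty((n, J), dtype=np.int64)
        u = rng.random((n, J))
        for j in range(J):
            rj = self.n_categories_[j]
            cdf = np.cumsum(self.rho_[j, :rj, :], axis=0)  # (rj, K)
            idx = (u[:, j][:, None] > cdf[:, labels].T).sum(axis=1)
            codes[:, j] = np.minimum(idx, rj - 1) + 1
        return CategoricalDesign(codes, self.n_categories_.copy())

    def to_dict(self) -> dict:
        return {
            "n_classes": int(self.weights_.shape[0]),
            "weights": self.weights_.tolist(),
            "rho": self.rho_.tolist(),
            "n_categories": self.n_categories_.tolist(),
            "loglik": self.loglik_,
            "bic": self.bic_,
            "entropy": self.entropy_,
            "converged": self.converged_,
            "n_params": self.n_params_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentClassAnalysis":
        model = cls(n_classes=d["n_classes"])
        model.weights_ = np.asarray(d["weights"], dtype=float)
        model.rho_ = np.asarray(d["rho"], dtype=float)
        model.n_categories_ = np.asarray(d["n_categories"], dtype=np.int64)
        model.loglik_ = d["loglik"]
        model.bic_ = d["bic"]
        model.entropy_ = d["entropy"]
        model.converged_ = d["converged"]
        model.n_params_ = d["n_params"]
        return model


@dataclass
class BLRTResult:
    """Bootstrap likelihood-ratio test of k0 vs k0+1 classes."""

    k0: int
    k1: int
    lr_observed: float
    lr_bootstrap: np.ndarray
    n_bootstrap: int
    p_value: float
    n_failed: int = 0


@dataclass
class SelectKResult:
    n_classes: int
    table: pd.DataFrame
    blrt_trace: list[BLRTResult] = field(default_factory=list)


def blrt(
    design,
    k0: int,
    n_bootstrap: int = 999,
    n_starts: int = 20,
    seed: int | None = None,
    bootstrap_starts: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    init_scores=None,
) -> BLRTResult:
    """Parametric bootstrap likelihood-ratio test of k0 vs k0+1 classes.

    The observed LR is ``2 (loglik_{k0+1} - loglik_{k0})``.  The null
    distribution is built by simulating ``n_bootstrap`` datasets from the
    fitted k0-class model and refitting both models on each; refits use
    half the starts (speed; the bootstrap dominates the cost).  The p-value
    is the rank-based ``(1 + #{LR_b >= LR_obs}) / (B + 1)``.
    """
    if k0 < 1:
        raise ValueError("k0 must be >= 1")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    design = _as_design(design)
    if bootstrap_starts is None:
        bootstrap_starts = max(n_starts // 2, 1)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_bootstrap + 2) % (2**31)

    def _fit(d, k, starts, s, scores=None):
        return LatentClassAnalysis(
            n_classes=k, n_starts=starts, max_iter=max_iter, tol=tol, random_state=int(s)
        ).fit(d, init_scores=scores)

    m0 = _fit(design, k0, n_starts, seeds[0], init_scores)
    m1 = _fit(design, k0 + 1, n_starts, seeds[1], init_scores)
    lr_obs = max(2.0 * (m1.loglik_ - m0.loglik_), 0.0)

    lrs = []
    n_failed = 0
    n = design.n_samples
    for b in range(n_bootstrap):
        child = np.random.SeedSequence(entropy=int(seeds[2 + 2 * b]))
        sub = child.generate_state(8) % (2**31)
        done = False
        for attempt in range(4):  # original draw + up to 3 retries
            try:
                boot = m0.sample(n, random_state=int(sub[2 * attempt % 8]))
                b0 = _fit(boot, k0, bootstrap_starts, sub[(2 * attempt + 1) % 8])
                b1 = _fit(boot, k0 + 1, bootstrap_starts, seeds[3 + 2 * b] + attempt)
                lrs.append(max(2.0 * (b1.loglik_ - b0.loglik_), 0.0))
                done = True
                break
            except ValueError:
                continue
        if not done:
            n_failed += 1
            warnings.warn(f"bootstrap replicate {b} failed after retries; skipped")

    lrs = np.asarray(lrs)
    B = len(lrs)
    p = (1.0 + np.sum(lrs >= lr_obs)) / (B + 1.0)
    return BLRTResult(k0, k0 + 1, lr_obs, lrs, B, float(p), n_failed)


def select_k(
    design,
    k_max: int = 6,
    n_bootstrap: int = 999,
    n_starts: int = 20,
    seed: int | None = None,
    alpha: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-6,
    init_scores=None,
) -> SelectKResult:
    """Choose the number of classes: BIC minimum, then BLRT step-up.

    Fits K = 1..k_max, locates the BIC-minimizing k*, then tests k* vs k*+1
    by BLRT and keeps stepping up while p <= alpha and k < k_max.  The full
    per-K table and the BLRT trace are returned so the decision is auditable.
    """
    design = _as_design(design)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * k_max + 2) % (2**31)
    rows = []
    for k in range(1, k_max + 1):
        try:
            m = LatentClassAnalysis(
                n_classes=k,
                n_starts=n_starts,
                max_iter=max_iter,
                tol=tol,
                random_state=int(seeds[k]),
            ).fit(design, init_scores=init_scores)
        except ValueError:
            break
        rows.append(
            {
                "n_classes": k,
                "loglik": m.loglik_,
                "n_params": m.n_params_,
                "bic": m.bic_,
                "entropy": m.entropy_,
                "converged": m.converged_,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no class count could be fitted")
    k = int(table.loc[table["bic"].idxmin(), "n_classes"])
    trace: list[BLRTResult] = []
    if k_max > 1:
        while k < k_max:
            res = blrt(
                design,
                k,
                n_bootstrap=n_bootstrap,
                n_starts=n_starts,
                seed=int(seeds[k_max + k]),
                max_iter=max_iter,
                tol=tol,
                init_scores=init_scores,
            )
            trace.append(res)
            if res.p_value <= alpha:
                k += 1
            else:
                break
    return SelectKResult(k, table, trace)


def assign(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-posterior labels (1-based) and the winning probability.

    Ties are broken toward the lowest class index.
    """
    tau = np.asarray(tau, dtype=float)
    labels = np.argmax(tau, axis=1) + 1
    return labels, tau[np.arange(tau.shape[0]), labels - 1]


class LatentProfileAnalysis(BaseEstimator):
    """Gaussian-mixture latent profile model on continuous scores.

    Sensitivity-analysis counterpart of :class:`LatentClassAnalysis` that
    does not require categorizing the component scores.  EM is run through
    single warm-started steps so the per-iteration loglik trace is exposed
    (``loglik_trace_``).  ``covariance`` is ``"diag"`` (default) or
    ``"tied"`` (shared full covariance).
    """

    def __init__(
        self,
        n_classes: int = 3,
        covariance: str = "diag",
        n_starts: int = 5,
        max_iter: int = 300,
        tol: float = 1e-6,
        reg_covar: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_classes = n_classes
        self.covariance = covariance
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.reg_covar = reg_covar
        self.random_state = random_state

    def fit(self, X, y=None) -> "LatentProfileAnalysis":
        X = np.asarray(X, dtype=float)
        if self.covariance not in ("diag", "tied", "full"):
            raise ValueError("covariance must be one of diag/tied/full")
        n = X.shape[0]
        ss = np.random.SeedSequence(self.random_state)
        seeds = ss.generate_state(self.n_starts) % (2**31)
        best = None
        for s in seeds:
            gm = GaussianMixture(
                n_components=self.n_classes,
                covariance_type=self.covariance,
                max_iter=1,
                warm_start=True,
                init_params="random_from_data" if n >= self.n_classes else "random",
                reg_covar=self.reg_covar,
                random_state=int(s),
                n_init=1,
            )
            trace = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for _ in range(self.max_iter):
                    gm.fit(X)
                    trace.append(float(gm.lower_bound_) * n)
                    if len(trace) > 1 and trace[-1] - trace[-2] < self.tol:
                        break
            if best is None or trace[-1] > best[1][-1]:
                best = (gm, trace)
        gm, trace = best
        order = np.argsort(-gm.weights_, kind="stable")
        self._gm = gm
        self._order = order
        self.weights_ = gm.weights_[order]
        self.means_ = gm.means_[order]
        if self.covariance == "tied":
            self.covariances_ = gm.covariances_
        else:
            self.covariances_ = gm.covariances_[order]
        self.loglik_trace_ = trace
        self.loglik_ = trace[-1]
        self.n_iter_ = len(trace)
        self.converged_ = len(trace) < self.max_iter
        self.bic_ = float(gm.bic(X))
        self.entropy_ = relative_entropy(self.predict_proba(X), self.n_classes)
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self._gm.predict_proba(np.asarray(X, dtype=float))[:, self._order]

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1) + 1


# -- thin functional wrappers (operation surface) ---------------------------


def fit_lca(design, n_classes, n_starts=20, max_iter=500, tol=1e-6, seed=None,
            init_scores=None):
    return LatentClassAnalysis(
        n_classes=n_classes,
        n_starts=n_starts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(design, init_scores=init_scores)


def posterior(model: LatentClassAnalysis, design) -> np.ndarray:
    return model.predict_proba(design)


def simulate_from_model(model: LatentClassAnalysis, n: int, seed=None) -> CategoricalDesign:
    return model.sample(n, random_state=seed)


def fit_lpa(scores, n_classes, covariance="diag", seed=None, **kwargs):
    model = LatentProfileAnalysis(
        n_classes=n_classes, covariance=covariance, random_state=seed, **kwargs
    ).fit(scores)
    return model, model.predict_proba(scores)
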