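"""Seeded synthetic cohorts with known latent-class structure.

The real derivation and validation cohorts behind this kind of plasma-
proteomic stratification are not publicly deposited, so the package ships a
generator that emulates the data-generating situation the model assumes:

* a latent K-group structure expressed as mean shifts on a subset of
  "driver" proteins, on top of a correlated factor-structured background
  plus unit Gaussian noise (so PCA has recoverable structure);
* class-conditional categorical clinical variables with missing-completely-
  at-random injection;
* exponential survival times whose hazards differ by latent group, with
  independent exponential censoring tuned numerically to a target censoring
  fraction and administrative truncation at a follow-up horizon.

All randomness flows from one root seed: ``SeedSequence(seed)`` is spawned
into four child streams, consumed in the fixed order labels, proteins,
clinical, survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SimConfig", "SyntheticCohort", "generate_cohort", "sample_survival",
           "generate_clinical", "default_clinical_spec", "write_cohort", "read_cohort"]

ENDPOINTS = ("major_cv", "hf_hosp", "cv_death", "all_cause_death")

# per-endpoint multipliers of the reference-class baseline hazard, chosen so
# the simulated 3-year event counts resemble a chronic-HFrEF cohort in which
# roughly 30% experience a major CV event and ~10% die within follow-up
DEFAULT_ENDPOINT_SCALE = {
    "major_cv": 1.0,
    "hf_hosp": 0.75,
    "cv_death": 0.23,
    "all_cause_death": 0.30,
}


def default_clinical_spec(n_classes: int = 3) -> list[tuple[str, np.ndarray]]:
    """Class-conditional category probabilities for six baseline variables.

    Modeled loosely on the clinical variables a heart-failure clustering
    would use (age band, aetiology, CAD, arrhythmia, hypertension, smoking);
    the exact probabilities are invented test scaffolding.
    """
    spec = [
        ("age_band", [[0.2, 0.5, 0.3], [0.1, 0.3, 0.6], [0.6, 0.3, 0.1]]),
        ("aetiology", [[0.7, 0.2, 0.1], [0.2, 0.6, 0.2], [0.15, 0.15, 0.7]]),
        ("cad", [[0.1, 0.9], [0.5, 0.5], [0.8, 0.2]]),
        ("arrhythmia", [[0.7, 0.3], [0.45, 0.55], [0.8, 0.2]]),
        ("hypertension", [[0.5, 0.5], [0.15, 0.85], [0.7, 0.3]]),
        ("smoking", [[0.5, 0.5], [0.6, 0.4], [0.4, 0.6]]),
    ]
    out = []
    for name, probs in spec:
        p = np.asarray(probs, dtype=float)
        if p.shape[0] != n_classes:
            # recycle rows for other class counts
            p = p[np.arange(n_classes) % p.shape[0]]
        out.append((name, p))
    return out


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Defaults mirror the study conditions the package is exercised under: a
    379-patient cohort with three latent classes mixed 0.5/0.3/0.2, driver-
    protein shifts of 3 SD on 120 of 300 proteins (so the class contrasts
    dominate the leading principal components, as the stratification method
    presumes), a five-factor correlated background whose dispersion grows
    with class severity, and class hazard ratios (1, 2.3, 5.8) with
    follow-up truncated at 3 years.
    """

    n_samples: int = 379
    n_proteins: int = 300
    n_informative: int = 120
    n_classes: int = 3
    mixing: tuple[float, ...] = (0.5, 0.3, 0.2)
    effect_size: float = 3.0
    n_factors: int = 5
    factor_strength: float = 0.25
    factor_dispersion: float = 0.35
    clinical_spec: list | None = None
    missing_rate: float = 0.02
    baseline_hazard: float = 0.07
    endpoint_scale: dict = field(default_factory=lambda: dict(DEFAULT_ENDPOINT_SCALE))
    class_hazard_ratios: tuple[float, ...] = (1.0, 2.3, 5.8)
    censor_rate: float = 0.70
    admin_horizon: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_proteins", "n_informative", "n_classes", "n_factors"):
            if int(getattr(self, name)) < (0 if name == "n_factors" else 1):
                raise ValueError(f"{name} must be positive")
        self.mixing = tuple(float(x) for x in self.mixing)
        if len(self.mixing) != self.n_classes:
            raise ValueError("mixing must have n_classes entries")
        if abs(sum(self.mixing) - 1.0) > 1e-12 or min(self.mixing) <= 0:
            raise ValueError("mixing must be positive and sum to 1 within 1e-12")
        if self.n_informative > self.n_proteins:
            raise ValueError("n_informative must not exceed n_proteins")
        if not (0 <= self.factor_strength < 1):
            raise ValueError("factor_strength must lie in [0, 1)")
        if self.factor_dispersion < 0:
            raise ValueError("factor_dispersion must be non-negative")
        self.class_hazard_ratios = tuple(float(x) for x in self.class_hazard_ratios)
        if len(self.class_hazard_ratios) != self.n_classes:
            raise ValueError("class_hazard_ratios must have n_classes entries")
        if self.class_hazard_ratios[0] != 1.0:
            raise ValueError("class_hazard_ratios[0] is the reference and must be 1")
        if min(self.class_hazard_ratios) <= 0 or self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard and class_hazard_ratios must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.admin_horizon <= 0:
            raise ValueError("admin_horizon must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.clinical_spec is None:
            self.clinical_spec = default_clinical_spec(self.n_classes)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_proteins": self.n_proteins,
            "n_informative": self.n_informative,
            "n_classes": self.n_classes,
            "mixing": list(self.mixing),
            "effect_size": self.effect_size,
            "n_factors": self.n_factors,
            "factor_strength": self.factor_strength,
            "factor_dispersion": self.factor_dispersion,
            "clinical_spec": [[name, np.asarray(p).tolist()] for name, p in self.clinical_spec],
            "missing_rate": self.missing_rate,
            "baseline_hazard": self.baseline_hazard,
            "endpoint_scale": dict(self.endpoint_scale),
            "class_hazard_ratios": list(self.class_hazard_ratios),
            "censor_rate": self.censor_rate,
            "admin_horizon": self.admin_horizon,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "clinical_spec" in d and d["clinical_spec"] is not None:
            d["clinical_spec"] = [(name, np.asarray(p, dtype=float)) for name, p in d["clinical_spec"]]
        if "mixing" in d:
            d["mixing"] = tuple(d["mixing"])
        if "class_hazard_ratios" in d:
            d["class_hazard_ratios"] = tuple(d["class_hazard_ratios"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A generated cohort; all tables share sample identifiers and order."""

    proteins: pd.DataFrame  # samples x proteins
    clinical: pd.DataFrame  # samples x variables, Int64 codes with NA
    clinical_meta: dict  # variable -> {baseline: bool, group: str|None}
    outcomes: pd.DataFrame  # time_<ep>, event_<ep> per endpoint
    true_labels: pd.Series  # 1..K
    config: SimConfig


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("labels", "proteins", "clinical", "survival")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (proteins, clinical, outcomes, labels)."""
    rngs = _streams(config.seed)
    n, p, K = config.n_samples, config.n_proteins, config.n_classes

    labels = rngs["labels"].choice(K, size=n, p=np.asarray(config.mixing)) + 1

    # class mean shifts: informative proteins split into K blocks, block k
    # elevated by effect_size in class k (one-vs-rest spike pattern)
    shifts = np.zeros((K, p))
    blocks = np.array_split(np.arange(config.n_informative), K)
    for k, block in enumerate(blocks):
        shifts[k, block] = config.effect_size

    rng = rngs["proteins"]
    q = config.n_factors
    if q > 0 and config.factor_strength > 0:
        loadings = (
            config.factor_strength
            * rng.choice([-1.0, 1.0], size=(p, q))
            / np.sqrt(q)
        )
        # classes also differ in factor dispersion (later classes more
        # dysregulated), interpolated up to factor_dispersion * effect_size
        # so a zero effect size removes every trace of class structure
        disp = 1.0 + (
            config.factor_dispersion
            * config.effect_size
            * np.arange(K)
            / max(K - 1, 1)
        )
        factors = rng.standard_normal((n, q)) * disp[labels - 1][:, None]
        background = factors @ loadings.T
    else:
        background = 0.0
    values = shifts[labels - 1] + background + rng.standard_normal((n, p))

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    protein_ids = [f"prot{j + 1:04d}" for j in range(p)]
    proteins = pd.DataFrame(values, index=sample_ids, columns=protein_ids)
    proteins.index.name = "sample_id"

    clinical, meta = generate_clinical(
        labels, config.clinical_spec, config.missing_rate, rng=rngs["clinical"]
    )
    clinical.index = sample_ids
    clinical.index.name = "sample_id"

    outcomes = sample_survival(labels, config, rng=rngs["survival"])
    outcomes.index = sample_ids
    outcomes.index.name = "sample_id"

    true_labels = pd.Series(labels, index=sample_ids, name="true_class")
    return SyntheticCohort(proteins, clinical, meta, outcomes, true_labels, config)


def _censor_rate_given(c: float, lams: np.ndarray, mix: np.ndarray, horizon: float) -> float:
    """Analytic censored fraction under Exp(c) censoring truncated at horizon."""
    # event observed iff T <= min(C, horizon); for T ~ Exp(lam), C ~ Exp(c):
    # P(event) = lam/(lam+c) * (1 - exp(-(lam+c) * horizon))
    lam = np.asarray(lams, dtype=float)
    p_event = lam / (lam + c) * (1.0 - np.exp(-(lam + c) * horizon)) if c > 0 else (
        1.0 - np.exp(-lam * horizon)
    )
    return float(1.0 - np.sum(np.asarray(mix) * p_event))


def _tune_censor_hazard(config: SimConfig, endpoint_rate: float) -> float:
    """Bisection for the exponential censoring hazard hitting censor_rate."""
    lams = endpoint_rate * np.asarray(config.class_hazard_ratios)
    mix = np.asarray(config.mixing)
    target = config.censor_rate
    lo = _censor_rate_given(0.0, lams, mix, config.admin_horizon)
    if target <= lo + 1e-12:
        return 0.0  # administrative censoring alone already meets/exceeds target
    a, b = 0.0, 1.0
    while _censor_rate_given(b, lams, mix, config.admin_horizon) < target:
        b *= 2.0
        if b > 1e8:
            raise ValueError("cannot reach the requested censor_rate")
    for _ in range(200):
        m = 0.5 * (a + b)
        if _censor_rate_given(m, lams, mix, config.admin_horizon) < target:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def sample_survival(
    labels: np.ndarray, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Exponential event times with class-specific hazards, per endpoint.

    Event time for class k has rate ``baseline_hazard * endpoint_scale *
    class_hazard_ratios[k]``.  A single independent Exp censoring time per
    endpoint is tuned by bisection to the configured censored fraction
    (administrative truncation at ``admin_horizon`` included).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > config.n_classes:
        raise ValueError("labels must lie in 1..n_classes")
    if rng is None:
        rng = _streams(config.seed)["survival"]
    hrs = np.asarray(config.class_hazard_ratios)
    n = labels.shape[0]
    out = {}
    for ep in ENDPOINTS:
        scale = config.endpoint_scale.get(ep, 1.0)
        rate0 = config.baseline_hazard * scale
        rates = rate0 * hrs[labels - 1]
        t_event = rng.exponential(1.0 / rates)
        c_haz = _tune_censor_hazard(config, rate0)
        t_cens = (
            rng.exponential(1.0 / c_haz, size=n) if c_haz > 0 else np.full(n, np.inf)
        )
        t_cens = np.minimum(t_cens, config.admin_horizon)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        out[f"time_{ep}"] = time
        out[f"event_{ep}"] = event
    return pd.DataFrame(out)


def generate_clinical(
    labels: np.ndarray,
    clinical_spec: list,
    missing_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Class-conditional categorical clinical variables with MCAR missingness.

    Each spec entry is ``(name, K x C probability matrix)``; codes are
    1-based, missing entries are pandas NA.  Returns the table and a
    metadata dict (all variables baseline, ungrouped) consumable by the
    variable-selection filters.
    """
    labels = np.asarray(labels, dtype=int)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = labels.shape[0]
    data = {}
    meta = {}
    for name, probs in clinical_spec:
        p = np.asarray(probs, dtype=float)
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-8) or np.any(p < 0):
            raise ValueError(f"category probabilities for {name!r} must sum to 1 per class")
        cdf = np.cumsum(p, axis=1)
        u = rng.random(n)
        codes = (u[:, None] > cdf[labels - 1]).sum(axis=1) + 1
        col = pd.array(codes, dtype="Int64")
        if missing_rate > 0:
            mask = rng.random(n) < missing_rate
            col[mask] = pd.NA
        data[name] = col
        meta[name] = {"baseline": True, "group": None}
    return pd.DataFrame(data), meta


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort as four CSVs plus a YAML manifest of its SimConfig."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.proteins.to_csv(outdir / "proteins.csv")
    cohort.clinical.to_csv(outdir / "clinical.csv")
    cohort.outcomes.to_csv(outdir / "outcomes.csv")
    cohort.true_labels.to_frame().to_csv(outdir / "labels.csv")
    manifest = {"sim_config": cohort.config.to_dict(), "clinical_meta": cohort.clinical_meta}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_cohort(outdir: str | Path) -> SyntheticCohort:
    outdir = Path(outdir)
    with open(outdir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    config = SimConfig.from_dict(manifest["sim_config"])
    proteins = pd.read_csv(outdir / "proteins.csv", index_col=0)
    clinical = pd.read_csv(outdir / "clinical.csv", index_col=0).astype("Int64")
    outcomes = pd.read_csv(outdir / "outcomes.csv", index_col=0)
    labels = pd.read_csv(outdir / "labels.csv", index_col=0)["true_class"]
    return SyntheticCohort(
        proteins, clinical, manifest["clinical_meta"], outcomes, labels, config
    )
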