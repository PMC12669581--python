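"""Genetic-algorithm selection of clinical clustering variables.

Candidate categorical clinical variables are first filtered (missingness
above 5%, non-baseline variables, one representative per declared
relatedness group); a genetic algorithm then searches over variable subsets
for the one whose K-class latent class model is best supported.  The default
fitness is the BIC evidence for clustering — BIC of the one-class
(independence) model minus BIC of the K-class model on the same variables
and samples — so larger is better and uninformative variables contribute
nothing but their parameter penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lca import CategoricalDesign, LatentClassAnalysis

__all__ = [
    "GAConfig",
    "GAResult",
    "filter_candidates",
    "ga_select",
    "discretize_continuous",
    "build_design",
]


def filter_candidates(
    table: pd.DataFrame,
    meta: dict | None = None,
    max_missing: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the candidate-variable filters.

    Excludes variables with missingness above ``max_missing``, variables not
    flagged as baseline, and all but one representative per relatedness
    group (the one with fewest missing values, ties broken lexicographically).
    ``meta`` maps variable -> {"baseline": bool, "group": str|None}; absent
    metadata defaults to baseline and ungrouped.  Returns the surviving
    variables and an exclusion report (variable, reason).
    """
    meta = meta or {}
    exclusions = []
    survivors = []
    for var in table.columns:
        m = meta.get(var, {})
        frac = float(table[var].isna().mean())
        if not m.get("baseline", True):
            exclusions.append((var, "non-baseline"))
        elif frac > max_missing:
            exclusions.append((var, f"missingness {frac:.3f} > {max_missing}"))
        else:
            survivors.append(var)
    groups: dict[str, list[str]] = {}
    for var in survivors:
        g = (meta.get(var, {}) or {}).get("group")
        if g is not None:
            groups.setdefault(g, []).append(var)
    for g, members in groups.items():
        keep = sorted(members, key=lambda v: (table[v].isna().sum(), v))[0]
        for var in members:
            if var != keep:
                exclusions.append((var, f"related to {keep!r} (group {g!r})"))
    dropped = {v for v, _ in exclusions}
    final = [v for v in survivors if v not in dropped]
    report = pd.DataFrame(exclusions, columns=["variable", "reason"])
    if not final:
        raise ValueError("no candidate variables survive the filters")
    return final, report


def build_design(table: pd.DataFrame, variables: list[str]) -> tuple[CategoricalDesign, np.ndarray]:
    """Complete-case categorical design over ``variables``.

    Rows with missing values in any selected variable are dropped; category
    codes are recoded to a contiguous 1..R per variable.  Returns the design
    and the boolean row mask of retained samples.
    """
    sub = table[variables]
    mask = ~sub.isna().any(axis=1)
    sub = sub[mask]
    codes = np.empty((len(sub), len(variables)), dtype=np.int64)
    ncat = np.empty(len(variables), dtype=np.int64)
    for j, var in enumerate(variables):
        vals = sub[var].to_numpy()
        uniq = np.unique(vals)
        lookup = {v: i + 1 for i, v in enumerate(uniq)}
        codes[:, j] = [lookup[v] for v in vals]
        ncat[j] = len(uniq)
    return CategoricalDesign(codes, ncat, list(variables)), mask.to_numpy()


@dataclass
class GAConfig:
    """Genetic-algorithm settings for variable-subset search."""

    population_size: int = 24
    n_generations: int = 15
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1/L per bit
    elitism: int = 2
    n_classes: int = 3
    fitness: str = "bic_diff"  # or "entropy"
    tournament_size: int = 2
    min_subset: int = 1
    max_subset: int | None = None
    lca_starts: int = 5
    lca_max_iter: int = 300
    lca_tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for r in ("crossover_rate",):
            v = getattr(self, r)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{r} must lie in [0, 1]")
        if self.mutation_rate is not None and not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.elitism < 0 or self.elitism > self.population_size:
            raise ValueError("elitism must lie in [0, population_size]")
        if self.fitness not in ("bic_diff", "entropy"):
            raise ValueError("fitness must be 'bic_diff' or 'entropy'")


@dataclass
class GAResult:
    selected: list[str]
    best_fitness: float
    history: list[float]  # best-ever fitness per generation
    final_population: np.ndarray
    evaluations: int = 0


def _fitness(
    chrom: np.ndarray,
    candidates: list[str],
    table: pd.DataFrame,
    config: GAConfig,
    seed: int,
) -> float:
    if chrom.sum() == 0:
        return -np.inf
    variables = [v for v, bit in zip(candidates, chrom) if bit]
    if len(variables) < config.min_subset:
        return -np.inf
    if config.max_subset is not None and len(variables) > config.max_subset:
        return -np.inf
    design, _ = build_design(table, variables)
    if design.n_samples < 10:
        return -np.inf
    kwargs = dict(
        n_starts=config.lca_starts,
        max_iter=config.lca_max_iter,
        tol=config.lca_tol,
    )
    try:
        model = LatentClassAnalysis(
            n_classes=config.n_classes, random_state=seed, **kwargs
        ).fit(design)
    except ValueError:
        return -np.inf
    if config.fitness == "entropy":
        return float(model.entropy_)
    one = LatentClassAnalysis(n_classes=1, random_state=seed, **kwargs).fit(design)
    return float(one.bic_ - model.bic_)


def ga_select(
    candidates: list[str],
    table: pd.DataFrame,
    config: GAConfig,
) -> GAResult:
    """Search variable subsets with a generational GA.

    Binary-mask chromosomes over the candidates; tournament selection
    (size 2), uniform crossover, per-bit mutation (default rate 1/L),
    elitism.  Fitness evaluations are cached per chromosome, and the
    best-ever chromosome is returned, so best fitness is non-decreasing
    across generations.  Fully deterministic for a given config.
    """
    if len(candidates) < 2:
        raise ValueError("at least two candidate variables are required")
    L = len(candidates)
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / L
    rng = np.random.default_rng(config.seed)
    cache: dict[bytes, float] = {}
    evals = 0

    def fitness(chrom: np.ndarray) -> float:
        nonlocal evals
        key = chrom.tobytes()
        if key not in cache:
            cache[key] = _fitness(chrom, candidates, table, config, seed=config.seed)
            evals += 1
        return cache[key]

    pop = (rng.random((config.population_size, L)) < 0.5).astype(np.int8)
    for i in range(config.population_size):  # no all-zero chromosomes at start
        if pop[i].sum() == 0:
            pop[i, rng.integers(L)] = 1
    scores = np.array([fitness(c) for c in pop])
    best_idx = int(np.argmax(scores))
    best_chrom, best_score = pop[best_idx].copy(), float(scores[best_idx])
    history = [best_score]

    for _ in range(config.n_generations):
        order = np.argsort(-scores, kind="stable")
        new_pop = [pop[i].copy() for i in order[: config.elitism]]
        while len(new_pop) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(config.population_size, size=config.tournament_size)
                parents.append(pop[contenders[np.argmax(scores[contenders])]])
            a, b = parents
            if rng.random() < config.crossover_rate:
                mask = rng.random(L) < 0.5
                child = np.where(mask, a, b).astype(np.int8)
            else:
                child = a.copy()
            flips = rng.random(L) < mut
            child = np.where(flips, 1 - child, child).astype(np.int8)
            new_pop.append(child)
        pop = np.array(new_pop[: config.population_size])
        scores = np.array([fitness(c) for c in pop])
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best_score = float(scores[gen_best])
            best_chrom = pop[gen_best].copy()
        history.append(best_score)

    selected = [v for v, bit in zip(candidates, best_chrom) if bit]
    return GAResult(selected, best_score, history, pop, evals)


def discretize_continuous(
    values,
    cutoffs,
    lower: float = -np.inf,
) -> pd.array:
    """Half-open clinical binning of a continuous variable.

    Bins are ``[lower, c1), [c1, c2), ..., [c_m, inf)`` with 1-based codes;
    a value equal to a cutoff falls in the upper bin (BMI 25.0 with cutoffs
    (25, 30) is category 2).  Values below ``lower`` or non-finite map to
    missing.
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if cutoffs.size < 1 or np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoffs must be strictly increasing")
    values = np.asarray(values, dtype=float)
    codes = np.digitize(values, cutoffs) + 1
    out = pd.array(codes, dtype="Int64")
    bad = ~np.isfinite(values) | (values < lower)
    out[bad] = pd.NA
    return out
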