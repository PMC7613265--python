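"""Genetic-algorithm ensemble selection against a target scattering curve.

A candidate ensemble is a fixed-length multiset of pool-model indices
(multiplicity encodes weight); its theoretical curve is the unweighted mean
of the member curves.  Fitness is the reduced chi-square against the target
after an analytic least-squares scale factor.  Flexibility of a selection is
quantified by the entropy-based Rflex metric of its Rg histogram and by
Rsigma, the ratio of ensemble to pool Rg standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformers import Pool
from .scattering import ScatteringCurve

__all__ = [
    "GAConfig",
    "EnsembleFit",
    "FlexMetrics",
    "chi2",
    "ensemble_curve",
    "gajoe",
    "rflex",
    "rsigma",
    "size_distributions",
]


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    Defaults: ensembles of 20 slots, population 100, 500 generations,
    per-slot mutation 0.1, one-point crossover probability 0.5, 2 elites,
    and 10 independent repeats (the pipeline this follows ran its selector
    ten times and pooled the winners).
    """

    ensemble_size: int = 20
    population: int = 100
    generations: int = 500
    mutation_rate: float = 0.1
    crossover_rate: float = 0.5
    elites: int = 2
    repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.ensemble_size, self.population, self.generations,
               self.elites, self.repeats) < 1:
            raise ValueError("all GA sizes must be positive")
        for rate in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class EnsembleFit:
    """Best selection found by the genetic algorithm."""

    member_indices: np.ndarray          # L pool indices (with repetition)
    chi2: float
    mu: float                           # least-squares scale of the fit
    per_repeat_best: list = field(default_factory=list)  # (indices, chi2) per repeat
    history: list = field(default_factory=list)  # best chi2 per generation, per repeat

    def __post_init__(self):
        self.member_indices = np.asarray(self.member_indices, dtype=int)
        if self.chi2 < 0:
            raise ValueError("chi2 must be >= 0")

    @property
    def distinct_models(self) -> list[tuple[int, float]]:
        """(pool index, weight) pairs; weight = multiplicity / L."""
        idx, counts = np.unique(self.member_indices, return_counts=True)
        L = len(self.member_indices)
        return [(int(i), float(c) / L) for i, c in zip(idx, counts)]


@dataclass
class FlexMetrics:
    rflex_ensemble: float  # percent
    rflex_pool: float      # percent
    rsigma: float
    bins: int
    bin_range: tuple[float, float]


def chi2(theory: ScatteringCurve, target: ScatteringCurve) -> tuple[float, float]:
    """Reduced chi-square and analytic scale between theory and target.

    mu = sum(I_t I_e / s^2) / sum(I_t^2 / s^2);
    chi2 = 1/(K-1) * sum(((mu I_t - I_e)/s)^2).
    The two curves must share the q-grid exactly (no silent interpolation).
    """
    if len(theory) != len(target) or not np.array_equal(theory.q, target.q):
        raise ValueError("q-grids differ; resample explicitly before comparing")
    if target.sigma is None or np.any(target.sigma <= 0):
        raise ValueError("target must carry positive sigma")
    s2 = target.sigma ** 2
    mu = float(np.sum(theory.I * target.I / s2) / np.sum(theory.I ** 2 / s2))
    k = len(target)
    value = float(np.sum((mu * theory.I - target.I) ** 2 / s2) / (k - 1))
    return value, mu


def ensemble_curve(pool: Pool, member_indices) -> ScatteringCurve:
    """Unweighted mean of the member curves (multiplicity = weight)."""
    member_indices = np.asarray(member_indices, dtype=int)
    if member_indices.size == 0:
        raise ValueError("empty member list")
    if pool.curves is None:
        raise ValueError("pool curves not computed")
    I = pool.curves[member_indices].mean(axis=0)
    return ScatteringCurve(q=pool.curve_q.copy(), I=I)


def _chi2_batch(pool_I: np.ndarray, chroms: np.ndarray,
                target_I: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Reduced chi-square for every chromosome (vectorized)."""
    ens = pool_I[chroms].mean(axis=1)               # (pop, K)
    s2 = sigma ** 2
    mu = (ens * target_I / s2).sum(axis=1) / (ens ** 2 / s2).sum(axis=1)
    resid = (mu[:, None] * ens - target_I) / sigma
    return (resid ** 2).sum(axis=1) / (len(target_I) - 1)


def gajoe(pool: Pool, target: ScatteringCurve, config: GAConfig | None = None) -> EnsembleFit:
    """Select a best-fitting sub-ensemble of pool models by a genetic algorithm.

    Chromosome = list of ``ensemble_size`` pool indices with repetition.
    Each repeat runs an independent population with elitism, one-point
    crossover and per-slot mutation to a uniform random index; the best
    chi-square is non-increasing across generations within a repeat.  The
    overall winner across repeats is returned together with every
    per-repeat winner.  Fully reproducible from ``config.seed``.
    """
    config = config or GAConfig()
    L, pop_n = config.ensemble_size, config.population
    if pool.curves is None:
        raise ValueError("pool curves not computed")
    if len(pool) < L:
        raise ValueError(f"pool of {len(pool)} smaller than ensemble size {L}")
    if not np.array_equal(pool.curve_q, target.q):
        raise ValueError("pool curves are not on the target q-grid")
    if target.sigma is None:
        raise ValueError("target must carry sigma")
    pool_I = pool.curves
    n_models = len(pool)
    rng = np.random.default_rng(config.seed)

    per_repeat = []
    histories = []
    for _rep in range(config.repeats):
        chroms = rng.integers(n_models, size=(pop_n, L))
        fitness = _chi2_batch(pool_I, chroms, target.I, target.sigma)
        best_per_gen = []
        for _gen in range(config.generations):
            order = np.argsort(fitness, kind="stable")
            chroms, fitness = chroms[order], fitness[order]
            elite = chroms[: config.elites].copy()
            # tournament-free rank selection: parents drawn from the top half
            half = max(2, pop_n // 2)
            parents = chroms[rng.integers(half, size=(pop_n - config.elites, 2))]
            children = parents[:, 0].copy()
            do_cx = rng.random(len(children)) < config.crossover_rate
            cut = rng.integers(1, L, size=len(children))
            for i in np.nonzero(do_cx)[0]:
                children[i, cut[i]:] = parents[i, 1, cut[i]:]
            mutate = rng.random(children.shape) < config.mutation_rate
            children[mutate] = rng.integers(n_models, size=int(mutate.sum()))
            chroms = np.vstack([elite, children])
            fitness = _chi2_batch(pool_I, chroms, target.I, target.sigma)
            best_per_gen.append(float(fitness.min()))
        best_i = int(np.argmin(fitness))
        best = np.sort(chroms[best_i])  # sorted for deterministic tie reporting
        per_repeat.append((best, float(fitness[best_i])))
        histories.append(np.array(best_per_gen))

    win_idx = int(np.argmin([c for _m, c in per_repeat]))
    members, best_chi2 = per_repeat[win_idx]
    _, mu = chi2(ensemble_curve(pool, members), target)
    return EnsembleFit(member_indices=members, chi2=best_chi2, mu=mu,
                       per_repeat_best=per_repeat, history=histories)


def rflex(rg_values, bins: int = 100, bin_range=None) -> float:
    """Entropy-based flexibility of a set of Rg values, in percent.

    Shannon entropy of the occupancy histogram relative to the maximal
    (uniform) entropy: 0% for a degenerate pool, 100% when every bin is
    equally occupied.
    """
    rg_values = np.asarray(rg_values, dtype=float)
    if rg_values.size < 1:
        raise ValueError("need >= 1 value")
    if bins < 2:
        raise ValueError("need >= 2 bins")
    if bin_range is None:
        bin_range = (float(rg_values.min()), float(rg_values.max()))
    lo, hi = bin_range
    if np.any(rg_values < lo) or np.any(rg_values > hi):
        raise ValueError("values outside bin range")
    if hi == lo:                      # degenerate pool: all mass in one bin
        return 0.0
    hist, _ = np.histogram(rg_values, bins=bins, range=(lo, hi))
    occupied = hist[hist > 0]
    if len(occupied) == 1:
        return 0.0
    if len(occupied) == bins and np.all(occupied == occupied[0]):
        return 100.0  # uniform occupancy is maximal entropy, exactly
    p = occupied / hist.sum()
    entropy = -np.sum(p * np.log(p))
    return float(100.0 * entropy / np.log(bins))


def rsigma(ensemble_rgs, pool_rgs) -> float:
    """Ratio of ensemble to pool Rg standard deviation."""
    ensemble_rgs = np.asarray(ensemble_rgs, dtype=float)
    pool_rgs = np.asarray(pool_rgs, dtype=float)
    if ensemble_rgs.size < 2 or pool_rgs.size < 2:
        raise ValueError("need >= 2 values in each set")
    sd_pool = float(np.std(pool_rgs))
    if sd_pool == 0:
        raise ValueError("pool Rg standard deviation is zero")
    return float(np.std(ensemble_rgs)) / sd_pool


def size_distributions(pool: Pool, ensembles, bins: int = 50):
    """Unit-area histograms of Rg and Dmax for the pool vs the selected models.

    The selected-model histogram aggregates the members of every per-repeat
    winner, weighted by multiplicity.  Returns a dict with ``rg`` and
    ``dmax`` entries, each ``(bin_centres, pool_density, ensemble_density)``.
    """
    sel_parts = []
    for e in ensembles:
        if isinstance(e, EnsembleFit) and e.per_repeat_best:
            sel_parts.extend(np.asarray(m, dtype=int) for m, _c in e.per_repeat_best)
        elif isinstance(e, EnsembleFit):
            sel_parts.append(e.member_indices)
        else:
            sel_parts.append(np.asarray(e, dtype=int))
    sel = np.concatenate(sel_parts)
    out = {}
    for name, values in (("rg", pool.rg), ("dmax", pool.dmax)):
        rng_ = (float(values.min()), float(values.max()))
        if rng_[0] == rng_[1]:
            rng_ = (rng_[0] - 0.5, rng_[1] + 0.5)
        pool_h, edges = np.histogram(values, bins=bins, range=rng_, density=True)
        ens_h, _ = np.histogram(values[sel], bins=bins, range=rng_, density=True)
        out[name] = (0.5 * (edges[:-1] + edges[1:]), pool_h, ens_h)
    return out
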