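"""Training-set optimization by the CDmean criterion and a genetic algorithm.

CDmean is the expected reliability of contrast predictions: for each target
individual i, the contrast c_i between i and the population mean has
coefficient of determination

    CD(c_i) = c_i' (G - lambda C22) c_i / (c_i' G c_i)

where C22 is the genetic-effect block of the inverse mixed-model coefficient
matrix built from the training-set design (intercept-only fixed effect, one
record per training member) and lambda = s2_e / s2_g is the variance ratio
(1 corresponds to h2 = 0.5).  The criterion is the mean CD over targets.

The subset search uses a genetic algorithm over fixed-size index sets with
tournament selection, uniform membership crossover with repair, single-swap
mutation and elitism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import GenomicRelationship


@dataclass
class TsOptProblem:
    """A CDmean training-set selection problem.

    ``fixed_ts_ids`` are always in the training set (e.g. the families
    already phenotyped in the surrogate location, entering as
    environment-collapsed records); the search chooses ``n_select``
    additional members among ``candidate_ids``.
    """

    G: GenomicRelationship
    candidate_ids: list
    target_ids: list
    n_select: int
    lam: float = 1.0
    fixed_ts_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_select > len(self.candidate_ids):
            raise ValueError("n_select exceeds number of candidates")
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        self._Ginv = np.linalg.inv(self.G.G)
        self._all_index = pd.Index(self.G.ids)
        self._target_pos = self.G.indexer(self.target_ids)
        n = len(self.G.ids)
        # contrasts: individual vs the population mean, over all individuals
        C = np.full((n, len(self._target_pos)), -1.0 / n)
        C[self._target_pos, np.arange(len(self._target_pos))] += 1.0
        self._contrasts = C
        self._denoms = np.einsum("ij,ij->j", C, self.G.G @ C)


@dataclass
class GaSettings:
    """Genetic-algorithm settings (published defaults: 200/300/10)."""

    n_iterations: int = 200
    pop_size: int = 300
    n_elites: int = 10
    seed: int = 0
    mutation_rate: float = 0.1
    crossover_rate: float = 0.9

    def __post_init__(self):
        if not self.n_elites < self.pop_size:
            raise ValueError("n_elites must be < pop_size")


def cdmean(problem: TsOptProblem, ts_subset) -> float:
    """Mean CD of target-vs-mean contrasts for a given training subset."""
    ts_ids = list(dict.fromkeys(list(ts_subset) + list(problem.fixed_ts_ids)))
    if not ts_ids:
        raise ValueError("empty training set")
    if not set(ts_subset) <= set(problem.candidate_ids):
        raise ValueError("ts_subset must be drawn from the candidates")
    pos = problem.G.indexer(ts_ids)
    n_all = len(problem.G.ids)
    m = len(pos)
    Z = np.zeros((m, n_all))
    Z[np.arange(m), pos] = 1.0
    lam = problem.lam
    # coefficient matrix of (1 X | Z) mixed-model equations, fixed block first
    C11 = np.array([[float(m)]])
    C12 = Z.sum(axis=0, keepdims=True)
    C22 = Z.T @ Z + lam * problem._Ginv
    M = np.block([[C11, C12], [C12.T, C22]])
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        M = M + 1e-8 * np.trace(M) / len(M) * np.eye(len(M))
        Minv = np.linalg.inv(M)
    C22inv = Minv[1:, 1:]
    C = problem._contrasts
    nums = np.einsum("ij,ij->j", C, (problem.G.G - lam * C22inv) @ C)
    return float(np.mean(nums / problem._denoms))


@dataclass
class GaResult:
    selected: list
    criterion: float
    trajectory: pd.DataFrame  # columns generation, best, mean

    def to_csv(self, path) -> None:
        self.trajectory.to_csv(path, index=False)


def random_select(candidates, n_select: int, seed: int) -> list:
    """Uniform draw of ``n_select`` candidates without replacement."""
    if n_select > len(candidates):
        raise ValueError("n_select exceeds number of candidates")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_select, replace=False)
    return [candidates[i] for i in sorted(idx)]


def ga_select(problem: TsOptProblem, settings: GaSettings | None = None) -> GaResult:
    """Genetic-algorithm search for the CDmean-optimal subset.

    Fixed-size index-set encoding; elitism preserves the best solutions each
    generation, so the best-so-far criterion trajectory is non-decreasing.
    """
    settings = settings or GaSettings()
    rng = np.random.default_rng(settings.seed)
    cands = sorted(problem.candidate_ids)
    n_c, k = len(cands), problem.n_select
    if k == n_c:
        full = list(cands)
        val = cdmean(problem, full)
        traj = pd.DataFrame([(0, val, val)], columns=["generation", "best", "mean"])
        return GaResult(full, val, traj)

    def fitness(member: frozenset) -> float:
        return cdmean(problem, [cands[i] for i in sorted(member)])

    pop = [frozenset(rng.choice(n_c, size=k, replace=False)) for _ in range(settings.pop_size)]
    cache: dict = {}

    def fit_cached(m):
        if m not in cache:
            cache[m] = fitness(m)
        return cache[m]

    def repair(members: set) -> frozenset:
        members = set(members)
        pool = [i for i in range(n_c) if i not in members]
        while len(members) > k:
            members.remove(rng.choice(sorted(members)))
        while len(members) < k:
            j = rng.integers(len(pool))
            members.add(pool.pop(j))
        return frozenset(members)

    traj_rows = []
    for gen in range(settings.n_iterations):
        scores = np.array([fit_cached(m) for m in pop])
        order = np.argsort(-scores)
        traj_rows.append((gen, float(scores[order[0]]), float(scores.mean())))
        elites = [pop[i] for i in order[: settings.n_elites]]
        children = list(elites)
        while len(children) < settings.pop_size:
            picks = rng.integers(settings.pop_size, size=3)
            pa = pop[picks[np.argmax(scores[picks])]]
            picks = rng.integers(settings.pop_size, size=3)
            pb = pop[picks[np.argmax(scores[picks])]]
            if rng.random() < settings.crossover_rate:
                common = pa & pb
                rest = list((pa | pb) - common)
                child = set(common)
                rng.shuffle(rest)
                for i in rest:
                    if len(child) < k and rng.random() < 0.5:
                        child.add(i)
                child = set(repair(child))
            else:
                child = set(pa)
            if rng.random() < settings.mutation_rate:
                out = rng.choice(sorted(child))
                child.remove(out)
                child = set(repair(child))
            children.append(frozenset(child))
        pop = children

    scores = np.array([fit_cached(m) for m in pop])
    best = pop[int(np.argmax(scores))]
    selected = [cands[i] for i in sorted(best)]
    traj = pd.DataFrame(traj_rows, columns=["generation", "best", "mean"])
    # best-so-far is what elitism guarantees; expose it directly
    traj["best"] = traj.best.cummax()
    return GaResult(selected, float(scores.max()), traj)
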