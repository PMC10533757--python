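"""Declarative calibration/validation scenarios and their replicated execution.

Five scenario archetypes cover the ways a two-location shuttle-breeding
program can calibrate a genomic prediction model for its target location
(SRO), using the training subpopulation (A), the validation subpopulation
(B), earlier selfing generations, and sparse phenotyping at the target:

* Uni1   - 70/30 cross-validation within B at SRO (single-environment model);
* Uni2/3 - calibrate on A (S0:2 / S0:3) at SRO, validate on all of B
  (deterministic: no random training draw);
* Multi1 - all of B at PAL plus 70% of B at SRO, validate the held-out 30%
  at SRO with a G x E model (MM / MDs / MDe);
* Multi2 - all of A at PAL (S0:2) plus a 25/50/75% fraction of A at SRO
  (S0:3), chosen randomly or by CDmean, validate on all of B at SRO.

Training/validation phenotypes are trial-adjusted genotype means (BLUEs);
predictive ability is their correlation with predicted genetic values over
the validation families.  Replicates are compared on Fisher-Z transformed
predictive abilities with a fixed-effect linear model and Tukey HSD letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import GenomicRelationship, filter_markers, impute_mean, vanraden_g
from .phenotypes import TrialBlues
from .prediction import (GBLUP, KernelSet, McmcSettings, build_kernels,
                         fisher_z, predictive_ability)
from .simulate import SimConfig, StudyBundle, simulate_study
from .tsopt import GaResult, GaSettings, TsOptProblem, ga_select, random_select

SCENARIO_NAMES = ("Uni1", "Uni2", "Uni3", "Multi1", "Multi2")
MULTI2_FRACTIONS = (0.25, 0.50, 0.75)

#: GA settings used when a scenario asks for CDmean sampling at desk scale.
DESK_GA = GaSettings(n_iterations=30, pop_size=40, n_elites=4)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class TsComponent:
    population: str        # "A" or "B"
    generation: int
    location: str
    fraction: float
    sampling: str = "all"  # all | random | cdmean


@dataclass(frozen=True)
class VsComponent:
    population: str
    generation: int
    location: str
    fraction: float


@dataclass
class ScenarioSpec:
    name: str
    ts_components: list
    vs_component: VsComponent
    model: str
    n_replicates: int
    traits: list = field(default_factory=list)

    @property
    def deterministic(self) -> bool:
        return self.name in ("Uni2", "Uni3")


def build_scenario(
    name: str,
    model: str | None = None,
    fraction: float | None = None,
    sampling: str = "random",
    n_replicates: int = 100,
    traits: list | None = None,
    allow_nonstandard_fraction: bool = False,
) -> ScenarioSpec:
    """Resolve a named scenario into a fully specified :class:`ScenarioSpec`."""
    if name not in SCENARIO_NAMES:
        raise ScenarioError(f"unknown scenario {name!r}")
    traits = traits or []
    if name.startswith("Uni"):
        if model not in (None, "SM"):
            raise ScenarioError(f"{name} is a single-environment scenario (model SM)")
        model = "SM"
    else:
        model = model or "MDs"
        if model not in ("MM", "MDs", "MDe"):
            raise ScenarioError(f"{name} requires a multi-environment model")
    if name == "Uni1":
        ts = [TsComponent("B", 4, "SRO", 0.70, "random")]
        vs = VsComponent("B", 4, "SRO", 0.30)
    elif name == "Uni2":
        ts = [TsComponent("A", 2, "SRO", 1.0, "all")]
        vs = VsComponent("B", 4, "SRO", 1.0)
        n_replicates = 1
    elif name == "Uni3":
        ts = [TsComponent("A", 3, "SRO", 1.0, "all")]
        vs = VsComponent("B", 4, "SRO", 1.0)
        n_replicates = 1
    elif name == "Multi1":
        ts = [TsComponent("B", 4, "PAL", 1.0, "all"),
              TsComponent("B", 4, "SRO", 0.70, "random")]
        vs = VsComponent("B", 4, "SRO", 0.30)
    else:  # Multi2
        f = 0.50 if fraction is None else float(fraction)
        if f not in MULTI2_FRACTIONS and not allow_nonstandard_fraction:
            raise ScenarioError("Multi2 fraction must be 0.25, 0.50 or 0.75 "
                                "(pass allow_nonstandard_fraction=True to override)")
        if sampling not in ("random", "cdmean"):
            raise ScenarioError("Multi2 sampling must be random or cdmean")
        ts = [TsComponent("A", 2, "PAL", 1.0, "all"),
              TsComponent("A", 3, "SRO", f, sampling)]
        vs = VsComponent("B", 4, "SRO", 1.0)
    if n_replicates < 1:
        raise ScenarioError("n_replicates must be >= 1")
    return ScenarioSpec(name, ts, vs, model, n_replicates, traits)


# ------------------------------------------------------------------ data

@dataclass
class StudyData:
    """Genomic relationship + per-trial adjusted means, scenario-ready."""

    G: GenomicRelationship
    blues: pd.DataFrame   # population, generation, location, trait, family, blue
    info: pd.DataFrame    # family, population, is_check

    @classmethod
    def from_bundle(cls, bundle: StudyBundle, traits: list | None = None) -> "StudyData":
        markers, _ = filter_markers(bundle.markers)
        G = vanraden_g(impute_mean(markers))
        traits = traits or bundle.config.traits
        rows = []
        rec = bundle.records
        for (pop, loc, year), trial in rec.groupby(["population", "location", "year"]):
            gen = int(trial.loc[~trial.is_check, "generation"].iloc[0])
            own = set(trial.loc[~trial.is_check, "family"])
            for trait in traits:
                bt = TrialBlues(trial, trait).fit()
                tb = bt.table[bt.table.family.isin(own)]
                for _, r in tb.iterrows():
                    rows.append((pop, gen, loc, trait, r.family, r.blue))
        blues = pd.DataFrame(rows, columns=["population", "generation", "location",
                                            "trait", "family", "blue"])
        return cls(G, blues, bundle.info)

    @classmethod
    def simulate(cls, cfg: SimConfig | None = None, **cfg_kwargs) -> "StudyData":
        cfg = cfg or SimConfig(**cfg_kwargs)
        return cls.from_bundle(simulate_study(cfg))

    def component_blues(self, pop: str, gen: int, loc: str, trait: str) -> pd.Series:
        sel = self.blues[(self.blues.population == pop)
                         & (self.blues.generation == gen)
                         & (self.blues.location == loc)
                         & (self.blues.trait == trait)]
        if sel.empty:
            raise ScenarioError(
                f"no adjusted means for component ({pop}, S0:{gen}, {loc}, {trait})")
        return sel.set_index("family").blue


# ----------------------------------------------------------------- results

@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    trait: str
    replicates: pd.DataFrame      # replicate, seed, pa, z
    gebv_mean: pd.Series          # VS family -> mean predicted genetic value
    vs_blues: pd.Series

    @property
    def mean_pa(self) -> float:
        return float(self.replicates.pa.mean())

    @property
    def sd_pa(self) -> float:
        return float(self.replicates.pa.std(ddof=1)) if len(self.replicates) > 1 else 0.0

    def label(self) -> str:
        return f"{self.spec.name}-{self.spec.model}-{self.trait}"

    def summary(self) -> pd.Series:
        return pd.Series({"scenario": self.spec.name, "model": self.spec.model,
                          "trait": self.trait, "n_replicates": len(self.replicates),
                          "mean_pa": self.mean_pa, "sd_pa": self.sd_pa})


def _partition_families(pool: list, vs_fraction: float, rng: np.random.Generator):
    """Random VS draw; the complement is the within-location training part."""
    n_vs = int(round(vs_fraction * len(pool)))
    n_vs = min(max(n_vs, 1), len(pool) - 1)
    vs_idx = rng.choice(len(pool), size=n_vs, replace=False)
    vs = sorted(pool[i] for i in vs_idx)
    ts = sorted(set(pool) - set(vs))
    return ts, vs


def run_scenario(
    spec: ScenarioSpec,
    data: StudyData,
    seed: int,
    trait: str,
    settings: McmcSettings | None = None,
    ga_settings: GaSettings | None = None,
) -> ScenarioResult:
    """Execute a scenario for one trait over its replicates.

    Every replicate draws fresh training membership from a replicate-indexed
    seed stream; validation families' phenotypes in the prediction
    environment never enter the training response (hard assertion).  Kernel
    eigendecompositions are shared across replicates: training membership
    enters only through which records carry an observed phenotype.
    """
    settings = settings or McmcSettings()
    multi_env = not spec.name.startswith("Uni")
    vs_env = spec.vs_component.location

    vs_pool = sorted(data.info[(data.info.population == spec.vs_component.population)
                               & ~data.info.is_check].family)
    comp_blues = {c: data.component_blues(c.population, c.generation, c.location, trait)
                  for c in spec.ts_components}
    vs_blues = data.component_blues(spec.vs_component.population,
                                    spec.vs_component.generation, vs_env, trait)

    # fixed record universe (per-replicate membership only toggles observed y)
    records, base_y = [], []
    slot = {}
    for c in spec.ts_components:
        env = c.location if multi_env else vs_env
        for fam, blue in comp_blues[c].items():
            slot[(fam, env, c.generation)] = len(records)
            records.append((fam, env))
            base_y.append(blue)
    vs_slot = {}
    for fam in vs_pool:
        key = (fam, vs_env)
        vs_slot[fam] = len(records)
        records.append(key)
        base_y.append(np.nan)
    base_y = np.asarray(base_y, float)
    kernels = build_kernels(data.G, records, spec.model)

    # CDmean selection is deterministic given G: computed once, reused
    cd_selection = {}
    for c in spec.ts_components:
        if c.sampling == "cdmean":
            fams = sorted(comp_blues[c].index)
            fixed = [f for cc in spec.ts_components if cc.sampling == "all"
                     for f in comp_blues[cc].index]
            problem = TsOptProblem(data.G, fams, vs_pool,
                                   n_select=int(round(c.fraction * len(fams))),
                                   lam=1.0, fixed_ts_ids=sorted(set(fixed)))
            result: GaResult = ga_select(problem, ga_settings or DESK_GA)
            cd_selection[c] = set(result.selected)

    rep_rows = []
    gebv_sum = pd.Series(0.0, index=vs_pool)
    for rep in range(spec.n_replicates):
        ss = np.random.SeedSequence(seed, spawn_key=(rep,))
        rng = np.random.default_rng(ss)
        mcmc_seed = int(ss.generate_state(1)[0] % (2**31))

        y = np.full(len(records), np.nan)
        vs_fams = vs_pool
        for c in spec.ts_components:
            fams = sorted(comp_blues[c].index)
            if c.sampling == "all" or c.fraction >= 1.0:
                chosen = fams
            elif c.sampling == "cdmean":
                chosen = sorted(cd_selection[c])
            else:
                if (c.population == spec.vs_component.population
                        and c.location == vs_env
                        and c.generation == spec.vs_component.generation):
                    chosen, vs_fams = _partition_families(fams, spec.vs_component.fraction, rng)
                else:
                    n_sel = int(round(c.fraction * len(fams)))
                    idx = rng.choice(len(fams), size=n_sel, replace=False)
                    chosen = [fams[i] for i in sorted(idx)]
            env = c.location if multi_env else vs_env
            for fam in chosen:
                i = slot.get((fam, env, c.generation))
                if i is None:
                    raise ScenarioError(f"family {fam} missing from record universe")
                y[i] = comp_blues[c].loc[fam]

        # leakage guard: a validation family must carry no observed phenotype
        # in the prediction environment
        for fam in vs_fams:
            assert np.isnan(y[vs_slot[fam]]), \
                f"training/validation leakage for family {fam} in {vs_env}"

        rep_settings = replace(settings, seed=mcmc_seed)
        result = GBLUP(y, kernels).fit(rep_settings)
        pred = np.array([result.gebv.iloc[vs_slot[f]] for f in vs_fams])
        obs = vs_blues.reindex(vs_fams).to_numpy()
        pa = predictive_ability(pred, obs)
        z = fisher_z(pa) if abs(pa) < 1 else np.nan
        rep_rows.append((rep, mcmc_seed, pa, z))
        gebv_all = pd.Series({f: result.gebv.iloc[vs_slot[f]] for f in vs_pool})
        gebv_sum = gebv_sum.add(gebv_all, fill_value=0.0)

    reps = pd.DataFrame(rep_rows, columns=["replicate", "seed", "pa", "z"])
    return ScenarioResult(spec, trait, reps, gebv_sum / spec.n_replicates, vs_blues)


# ------------------------------------------------------------- comparison

def _compact_letters(labels: list, different: set) -> dict:
    """Compact letter display: groups not significantly different share a letter."""
    import string

    letters = {lab: "" for lab in labels}
    assigned = []  # list of sets of labels sharing one letter
    for lab in labels:
        placed = False
        for grp in assigned:
            if all((lab, o) not in different and (o, lab) not in different for o in grp):
                grp.add(lab)
                placed = True
        if not placed:
            assigned.append({lab})
    # absorb subsets
    assigned = [g for i, g in enumerate(assigned)
                if not any(g < h for j, h in enumerate(assigned) if i != j)]
    for letter, grp in zip(string.ascii_lowercase, assigned):
        for lab in grp:
            letters[lab] += letter
    return letters


def compare_scenarios(results: list, alpha: float = 0.05) -> pd.DataFrame:
    """Fixed-effect comparison of scenarios on Fisher-Z predictive abilities.

    A one-way linear model with the scenario as the only fixed effect,
    followed by Tukey HSD pairwise comparisons at ``alpha`` and a compact
    letter display.  Deterministic single-replicate scenarios cannot enter
    the test and are reported as reference rows (no letter).
    """
    groups = [r for r in results if len(r.replicates) >= 2]
    refs = [r for r in results if len(r.replicates) < 2]
    rows = []
    letters = {}
    if len(groups) >= 2:
        z = np.concatenate([g.replicates.z.to_numpy() for g in groups])
        lab = np.concatenate([[g.label()] * len(g.replicates) for g in groups])
        ok = ~np.isnan(z)
        z, lab = z[ok], lab[ok]
        degenerate = {g.label() for g in groups if g.replicates.z.std(ddof=1) == 0}
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tuk = pairwise_tukeyhsd(z, lab, alpha=alpha)
        different = set()
        res = tuk.summary().data[1:]
        for g1, g2, *_rest, reject in res:
            if reject:
                different.add((str(g1), str(g2)))
        order = sorted({g.label() for g in groups},
                       key=lambda L: -np.mean(z[lab == L]))
        letters = _compact_letters(order, different)
        for g in groups:
            rows.append((g.label(), g.spec.name, g.spec.model, g.trait,
                         len(g.replicates), g.mean_pa, g.sd_pa,
                         letters[g.label()],
                         g.label() in degenerate))
    elif len(groups) == 1:
        g = groups[0]
        rows.append((g.label(), g.spec.name, g.spec.model, g.trait,
                     len(g.replicates), g.mean_pa, g.sd_pa, "a", False))
    for r in refs:
        rows.append((r.label(), r.spec.name, r.spec.model, r.trait,
                     len(r.replicates), r.mean_pa, r.sd_pa, "", False))
    return pd.DataFrame(rows, columns=["label", "scenario", "model", "trait",
                                       "n", "mean_pa", "sd_pa", "letters",
                                       "degenerate"])


def top_k_overlap(result_a: ScenarioResult, result_b: ScenarioResult, k: int) -> int:
    """Families ranked in the top k by predicted genetic value in both runs."""
    common = result_a.gebv_mean.index.intersection(result_b.gebv_mean.index)
    if k > len(common):
        raise ValueError("k exceeds the number of shared validation families")
    top_a = set(result_a.gebv_mean.loc[common].nlargest(k).index)
    top_b = set(result_b.gebv_mean.loc[common].nlargest(k).index)
    return len(top_a & top_b)
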