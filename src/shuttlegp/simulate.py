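"""Synthetic breeding-population generator.

Emulates a two-subpopulation upland rice recurrent-selection study: S0
plants drawn from one unstructured synthetic population, split into a
training subpopulation (A) and a validation subpopulation (B) plus a set of
temporal-check families, genotyped at several thousand biallelic SNPs on 12
chromosomes, advanced by bulk selfing (heterozygosity halves per selfing
step), and phenotyped in two-location lattice trials (3 replicates x 8
incomplete blocks) for four traits with controlled heritability and G x E
share.

Every quantity is driven by one seeded generator so runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import MarkerMatrix

LOCATIONS = ("PAL", "SRO")

#: Trait architecture defaults: entry-mean heritability (2 locations x 3
#: reps), share of genetic variance that is location-specific, location
#: means in trait units, and the scale (trait units per genetic SD).
TRAIT_DEFAULTS = {
    "FL": dict(h2=0.51, gxe_share=0.59, means={"PAL": 87.4, "SRO": 81.7}, scale=4.5),
    "PH": dict(h2=0.02, gxe_share=0.98, means={"PAL": 120.4, "SRO": 97.8}, scale=6.0),
    "YLD": dict(h2=0.24, gxe_share=0.84, means={"PAL": 759.6, "SRO": 137.0}, scale=80.0),
    "ZN": dict(h2=0.51, gxe_share=0.57, means={"PAL": 14.7, "SRO": 27.3}, scale=2.5),
}


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults mirror the real study's design: 384 training (A, incl. 50
    temporal checks) + 334 validation (B) S0 plants, ~10k SNPs (2000 at desk
    scale) on 12 chromosomes with MAF >= 2.5%, bulk-selfing advance with
    15-20 plants, and two-location trials with 3 reps x 8 blocks.
    """

    n_individuals_A: int = 384
    n_individuals_B: int = 334
    n_checks: int = 50
    n_snps: int = 2000
    n_chromosomes: int = 12
    maf_min: float = 0.025
    target_h2: dict = field(default_factory=lambda: {t: v["h2"] for t, v in TRAIT_DEFAULTS.items()})
    gxe_share: dict = field(default_factory=lambda: {t: v["gxe_share"] for t, v in TRAIT_DEFAULTS.items()})
    loc_effects: dict = field(default_factory=lambda: {t: dict(v["means"]) for t, v in TRAIT_DEFAULTS.items()})
    trait_scale: dict = field(default_factory=lambda: {t: v["scale"] for t, v in TRAIT_DEFAULTS.items()})
    residual_var: dict = field(default_factory=dict)  # optional per-trait override
    n_reps: int = 3
    n_blocks: int = 8
    n_bulk_plants: int = 18
    block_var: float = 0.15
    rep_effect_sd: float = 0.2
    year_effect_sd: float = 0.0
    locations: tuple = LOCATIONS
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_individuals_A, self.n_individuals_B, self.n_snps,
                  self.n_chromosomes, self.n_reps, self.n_blocks, self.n_bulk_plants)
        if any(c <= 0 for c in counts):
            raise InvalidConfigError("counts must be positive")
        if self.n_checks < 0 or self.n_checks > self.n_individuals_A:
            raise InvalidConfigError("n_checks must be in [0, n_individuals_A]")
        if not (0 < self.maf_min < 0.5):
            raise InvalidConfigError("maf_min must be in (0, 0.5)")
        if self.n_snps < self.n_chromosomes:
            raise InvalidConfigError("need at least one SNP per chromosome")
        for t, h2 in self.target_h2.items():
            if not 0 <= h2 <= 1:
                raise InvalidConfigError(f"target_h2[{t}] outside [0,1]")
        for t, s in self.gxe_share.items():
            if not 0 <= s <= 1:
                raise InvalidConfigError(f"gxe_share[{t}] outside [0,1]")

    @property
    def traits(self) -> list:
        return list(self.target_h2)

    def rng_for(self, stream: str) -> np.random.Generator:
        """Named child stream of the master seed (independently reproducible)."""
        import zlib

        key = zlib.crc32(stream.encode()) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class FamilyGenotypeState:
    """Expected genotype frequencies of a bulk-selfed family.

    Under no selection and an effectively infinite bulk (15-20 plants per
    advance), the expected per-locus heterozygosity after t selfing steps is
    the S0 heterozygosity x (1/2)^t while the expected dosage is unchanged.
    """

    family_id: str
    generation_t: int
    expected_dosage: np.ndarray
    expected_heterozygosity: np.ndarray


def make_family_states(markers: MarkerMatrix, generation_t: int = 0) -> list:
    """One state per individual row of ``markers`` (taken as S0 plants)."""
    states = []
    for i, fam in enumerate(markers.individual_ids):
        d0 = markers.dosage[i, :].astype(float)
        het0 = np.isclose(d0, 1.0).astype(float)
        s = FamilyGenotypeState(str(fam), 0, d0, het0)
        if generation_t:
            s = advance_generation_bulk(s, generation_t)
        states.append(s)
    return states


def advance_generation_bulk(state: FamilyGenotypeState, n_steps: int) -> FamilyGenotypeState:
    """Advance a family by ``n_steps`` of bulk selfing (expectation dynamics)."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    factor = 0.5 ** n_steps
    return replace(
        state,
        generation_t=state.generation_t + n_steps,
        expected_heterozygosity=state.expected_heterozygosity * factor,
    )


def sample_family_genotypes(
    state: FamilyGenotypeState, n_plants: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample realized plant dosages from the family's genotype frequencies."""
    het = state.expected_heterozygosity
    p_hom_alt = np.clip((state.expected_dosage - het) / 2.0, 0.0, 1.0)
    p_hom_ref = np.clip(1.0 - het - p_hom_alt, 0.0, 1.0)
    probs = np.stack([p_hom_ref, het, p_hom_alt], axis=1)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n_plants, len(het)))
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(float)


# ------------------------------------------------------------- S0 genotypes

def simulate_s0_genotypes(cfg: SimConfig) -> MarkerMatrix:
    """Simulate S0 plants as unions of two founder gametes.

    Founder allele frequencies are Beta-distributed, truncated so the
    realized sample MAF stays >= ``maf_min``; the Beta(0.7, 0.7) shape keeps
    rare alleles present (a GBS-like U-shaped spectrum) while S0 plants stay
    highly heterozygous.  A and B subpopulations are random fractions of the
    same founder pool, so the sample carries no structure.
    """
    cfg.validate()
    rng = cfg.rng_for("s0_genotypes")
    n = cfg.n_individuals_A + cfg.n_individuals_B
    ids = [f"A{i + 1:03d}" for i in range(cfg.n_individuals_A)]
    ids += [f"B{i + 1:03d}" for i in range(cfg.n_individuals_B)]

    dosage = np.empty((n, cfg.n_snps))
    for j in range(cfg.n_snps):
        for _ in range(200):
            p = rng.beta(0.7, 0.7)
            if not (cfg.maf_min < p < 1 - cfg.maf_min):
                continue
            col = rng.binomial(2, p, size=n).astype(float)
            freq = col.mean() / 2.0
            if cfg.maf_min <= min(freq, 1 - freq) <= 0.5 and 0 < freq < 1:
                dosage[:, j] = col
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a SNP satisfying the MAF floor")

    # spread SNPs evenly over chromosomes, ~1 per 40 kb
    base, extra = divmod(cfg.n_snps, cfg.n_chromosomes)
    chroms, positions = [], []
    for c in range(cfg.n_chromosomes):
        k = base + (1 if c < extra else 0)
        length = max(k * 40_000, k + 1)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=k, replace=False))
        chroms += [f"chr{c + 1}"] * k
        positions += list(pos)
    return MarkerMatrix(np.asarray(ids, object),
                        np.asarray([f"{c}_{p}" for c, p in zip(chroms, positions)], object),
                        np.asarray(chroms, object), np.asarray(positions), dosage)


# -------------------------------------------------------- trait architecture

@dataclass
class TraitEffects:
    """Additive marker effects and realized genetic values for one trait.

    ``g_main`` has variance 1 - gxe_share and each location deviation has
    variance gxe_share (in-sample standardization), so the between-location
    genetic correlation is 1 - gxe_share and the total genetic variance is 1
    on the simulation scale.  ``sigma2_e`` is the plot residual variance
    solving the entry-mean heritability identity for the reference design.
    """

    trait: str
    beta_main: np.ndarray
    beta_loc: dict
    g_main: pd.Series
    g_loc: dict
    sigma2_e: float
    h2: float
    gxe_share: float


def _standardized_values(X: np.ndarray, beta: np.ndarray, target_var: float):
    g = X @ beta
    sd = g.std(ddof=0)
    if sd == 0 or target_var == 0:
        return np.zeros_like(g), np.zeros_like(beta)
    f = np.sqrt(target_var) / sd
    g = (g - g.mean()) * f
    return g, beta * f


def simulate_trait_architecture(cfg: SimConfig, markers: MarkerMatrix) -> dict:
    """Draw per-trait marker effects (main + per-location deviations).

    Returns a dict trait -> :class:`TraitEffects`.  The empirical variance
    partition matches ``target_h2`` / ``gxe_share`` by in-sample scaling.
    """
    cfg.validate()
    if markers.n_snps == 0 or markers.n_individuals == 0:
        raise ValueError("markers must be nonempty")
    rng = cfg.rng_for("trait_architecture")
    Xc = markers.dosage - markers.dosage.mean(axis=0, keepdims=True)
    ids = pd.Index(markers.individual_ids)
    out = {}
    for trait in cfg.traits:
        h2 = cfg.target_h2[trait]
        share = cfg.gxe_share[trait]
        if not 0 <= share <= 1:
            raise InvalidConfigError("gxe_share must be in [0,1]")
        var_main = (1.0 - share) if h2 > 0 else 0.0
        var_dev = share if h2 > 0 else 0.0
        b = rng.standard_normal(markers.n_snps)
        g_main, b_main = _standardized_values(Xc, b, var_main)
        g_loc, b_loc = {}, {}
        for loc in cfg.locations:
            bd = rng.standard_normal(markers.n_snps)
            gd, bds = _standardized_values(Xc, bd, var_dev)
            g_loc[loc] = pd.Series(gd, index=ids)
            b_loc[loc] = bds
        # entry-mean H2 at the reference design (NE locations, NR plots):
        # h2 = s2g / (s2g + s2gl/NE + s2e/NR)  =>  solve for s2e
        ne = len(cfg.locations)
        nr = cfg.n_reps * ne
        if trait in cfg.residual_var:
            sigma2_e = float(cfg.residual_var[trait])
        elif h2 > 0:
            sigma2_e = max(nr * (var_main / h2 - var_main - var_dev / ne), 0.05)
        else:
            sigma2_e = 1.0
        out[trait] = TraitEffects(trait, b_main, b_loc, pd.Series(g_main, index=ids),
                                  g_loc, float(sigma2_e), h2, share)
    return out


# ------------------------------------------------------------------- trials

@dataclass(frozen=True)
class TrialPlan:
    population: str  # "A" or "B"
    generation: int  # selfing steps of the family entries
    location: str
    year: int


def default_schedule() -> list:
    """The six study trials: A at S0:2 and S0:3, B at S0:4, both locations."""
    return [
        TrialPlan("A", 2, "PAL", 2017), TrialPlan("A", 2, "SRO", 2017),
        TrialPlan("A", 3, "PAL", 2018), TrialPlan("A", 3, "SRO", 2018),
        TrialPlan("B", 4, "PAL", 2019), TrialPlan("B", 4, "SRO", 2020),
    ]


def family_info(cfg: SimConfig) -> pd.DataFrame:
    """Individual -> subpopulation and temporal-check flag.

    The checks are the last ``n_checks`` entries of subpopulation A,
    mirroring checks being drawn from the training subpopulation.
    """
    rows = []
    for i in range(cfg.n_individuals_A):
        fam = f"A{i + 1:03d}"
        rows.append((fam, "A", i >= cfg.n_individuals_A - cfg.n_checks))
    for i in range(cfg.n_individuals_B):
        rows.append((f"B{i + 1:03d}", "B", False))
    return pd.DataFrame(rows, columns=["family", "population", "is_check"])


def simulate_trials(
    cfg: SimConfig,
    effects: dict,
    schedule: list | None = None,
) -> pd.DataFrame:
    """Simulate long-format plot records for the trial schedule.

    Each trial holds the subpopulation's non-check families plus the
    temporal checks (always at generation 2), laid out in ``n_reps``
    replicates of ``n_blocks`` incomplete blocks filled as evenly as
    possible.  The plot value is

        location mean + rep effect + block effect
        + scale * (g_main + g_dev(location) + residual)

    with block effects ~ N(0, block_var) nested in rep nested in location,
    fixed rep offsets, and optional year effects (zero by default, since in
    the emulated design year is confounded with generation).
    """
    cfg.validate()
    if schedule is None:
        schedule = default_schedule()
    info = family_info(cfg)
    rng = cfg.rng_for("trials")
    year_eff = {}
    rep_eff = {(loc, r): rng.normal(0, cfg.rep_effect_sd)
               for loc in cfg.locations for r in range(1, cfg.n_reps + 1)}
    rows = []
    for plan in schedule:
        if cfg.year_effect_sd > 0:
            ye = year_eff.setdefault((plan.location, plan.year),
                                     rng.normal(0, cfg.year_effect_sd))
        else:
            ye = 0.0
        members = info[(info.population == plan.population) & ~info.is_check]
        checks = info[info.is_check]
        entries = pd.concat([members.assign(generation=plan.generation),
                             checks.assign(generation=2)], ignore_index=True)
        n_entries = len(entries)
        for trait, eff in effects.items():
            scale = cfg.trait_scale.get(trait, 1.0)
            mu = cfg.loc_effects[trait][plan.location]
            g = (eff.g_main.reindex(entries.family).to_numpy()
                 + eff.g_loc[plan.location].reindex(entries.family).to_numpy())
            for rep in range(1, cfg.n_reps + 1):
                block_eff = rng.normal(0, np.sqrt(cfg.block_var), size=cfg.n_blocks)
                order = rng.permutation(n_entries)
                blocks = np.array_split(order, cfg.n_blocks)
                eps = rng.normal(0, np.sqrt(eff.sigma2_e), size=n_entries)
                for b_idx, plot_idx in enumerate(blocks):
                    for i in plot_idx:
                        val = (mu + ye
                               + scale * (rep_eff[(plan.location, rep)]
                                          + block_eff[b_idx] + g[i] + eps[i]))
                        rows.append((entries.family.iloc[i], plan.population,
                                     plan.location, plan.year,
                                     int(entries.generation.iloc[i]), rep,
                                     b_idx + 1, trait, val,
                                     bool(entries.is_check.iloc[i])))
    return pd.DataFrame(rows, columns=["family", "population", "location", "year",
                                       "generation", "rep", "block", "trait",
                                       "value", "is_check"])


# ------------------------------------------------------------ full study

@dataclass
class StudyBundle:
    """Everything the downstream pipeline consumes, from one seeded run."""

    config: SimConfig
    markers: MarkerMatrix
    effects: dict
    records: pd.DataFrame
    info: pd.DataFrame


def simulate_study(cfg: SimConfig, schedule: list | None = None) -> StudyBundle:
    markers = simulate_s0_genotypes(cfg)
    effects = simulate_trait_architecture(cfg, markers)
    records = simulate_trials(cfg, effects, schedule)
    return StudyBundle(cfg, markers, effects, records, family_info(cfg))


def write_study(bundle: StudyBundle, outdir) -> dict:
    """Write genotypes (VCF + dosage CSV) and trial records (CSV)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "dosage": os.path.join(outdir, "genotypes_dosage.csv"),
        "records": os.path.join(outdir, "trial_records.csv"),
        "info": os.path.join(outdir, "family_info.csv"),
    }
    bundle.markers.to_vcf(paths["vcf"])
    bundle.markers.to_dosage_csv(paths["dosage"])
    bundle.records.to_csv(paths["records"], index=False)
    bundle.info.to_csv(paths["info"], index=False)
    return paths
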