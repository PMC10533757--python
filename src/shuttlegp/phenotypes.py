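"""Stage-1 phenotype statistics for multi-location lattice trials.

Covers boxplot-style outlier screening, the nested variance decomposition

    y = mu + Loc + Rep(Loc) + Bl(Rep(Loc)) + g + g(Loc) + e

with fixed location and replicate effects and random block, genotype and
genotype-within-location effects, entry-mean broad-sense heritability

    H2 = s2_g / (s2_g + s2_g(Loc)/NE + s2_e/NR),

per-trial adjusted genotype means (BLUEs, genotype fixed, blocks random),
and the descriptive summary (mean, SD, CV%, between-location correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reml import RemlFit, em_reml, indicator

REQUIRED_COLUMNS = {"family", "location", "year", "generation", "rep", "block",
                    "trait", "value"}


def _check_records(records: pd.DataFrame) -> None:
    missing = REQUIRED_COLUMNS - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")


# ------------------------------------------------------------- outliers

def tukey_hinges(x: np.ndarray) -> tuple[float, float]:
    """Lower/upper hinge (medians of the data halves, median included if odd)."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def flag_outliers(records: pd.DataFrame, coef: float = 1.5) -> pd.Series:
    """Flag plot values outside coef x IQR beyond the hinges, per trial x trait.

    Flags are informational: nothing is removed.  Groups with fewer than 4
    observations yield no flags (with a warning).
    """
    _check_records(records)
    flags = pd.Series(False, index=records.index)
    for (loc, year, trait), grp in records.groupby(["location", "year", "trait"]):
        if len(grp) < 4:
            warnings.warn(f"<4 observations for {loc}/{year}/{trait}; no outlier flags")
            continue
        q1, q3 = tukey_hinges(grp.value.to_numpy())
        iqr = q3 - q1
        lo, hi = q1 - coef * iqr, q3 + coef * iqr
        flags.loc[grp.index] = (grp.value < lo) | (grp.value > hi)
    return flags


# -------------------------------------------------- variance decomposition

def harmonic_means(records: pd.DataFrame) -> tuple[float, float]:
    """Harmonic-mean locations (NE) and plots per genotype (NR) over families."""
    if len(records) == 0:
        raise ValueError("empty records")
    plots = records.drop_duplicates(subset=[c for c in ("family", "location", "year", "rep")
                                            if c in records.columns])
    ne = plots.groupby("family").location.nunique()
    nr = plots.groupby("family").size()
    return float(len(ne) / (1.0 / ne).sum()), float(len(nr) / (1.0 / nr).sum())


@dataclass
class VarianceComponents:
    """Variance decomposition estimates for one trait."""

    trait: str
    sigma2_g: float
    sigma2_gxloc: float | None   # None for the single-location model
    sigma2_block: float
    sigma2_e: float
    fixed_estimates: dict
    converged: bool
    n_iter: int
    ne: float
    nr: float

    @property
    def proportions(self) -> dict:
        comps = {"genotype": self.sigma2_g, "block": self.sigma2_block,
                 "residual": self.sigma2_e}
        if self.sigma2_gxloc is not None:
            comps["location:genotype"] = self.sigma2_gxloc
        total = sum(comps.values())
        return {k: 100.0 * v / total for k, v in comps.items()}

    def heritability(self) -> float:
        return heritability(self, self.ne, self.nr)

    def summary(self) -> pd.DataFrame:
        props = self.proportions
        rows = [("genotype", self.sigma2_g, props["genotype"])]
        if self.sigma2_gxloc is not None:
            rows.append(("location:genotype", self.sigma2_gxloc, props["location:genotype"]))
        rows += [("block", self.sigma2_block, props["block"]),
                 ("residual", self.sigma2_e, props["residual"])]
        df = pd.DataFrame(rows, columns=["component", "variance", "pct_of_total"])
        df.attrs["H2"] = self.heritability()
        df.attrs["converged"] = self.converged
        return df


def heritability(vc: "VarianceComponents | tuple", ne: float, nr: float) -> float:
    """Entry-mean broad-sense heritability.

    ``vc`` may be a :class:`VarianceComponents` or a tuple
    (sigma2_g, sigma2_gxloc_or_None, sigma2_e).  For the within-location
    model the interaction term is absent (treated as 0).
    """
    if ne <= 0 or nr <= 0:
        raise ValueError("NE and NR must be positive")
    if isinstance(vc, VarianceComponents):
        s2g, s2gl, s2e = vc.sigma2_g, vc.sigma2_gxloc, vc.sigma2_e
    else:
        s2g, s2gl, s2e = vc
    s2gl = 0.0 if s2gl is None else s2gl
    denom = s2g + s2gl / ne + s2e / nr
    if denom == 0:
        raise ValueError("all variance components are zero; H2 undefined")
    return s2g / denom


class VarianceDecomposition:
    """Mixed-model variance decomposition for one trait.

    Two-location model: fixed intercept, location, replicate-within-location;
    random genotype, genotype-within-location, block-within-(location, rep).
    With ``single_location`` the location terms drop and blocks nest in reps.
    """

    def __init__(self, records: pd.DataFrame, trait: str,
                 single_location: str | None = None):
        _check_records(records)
        df = records[records.trait == trait]
        if single_location is not None:
            df = df[df.location == single_location]
        if df.empty:
            raise ValueError(f"no records for trait {trait!r}")
        dup = df.duplicated(subset=["family", "location", "year", "rep", "trait"])
        if dup.any():
            raise ValueError("duplicate (family, location, year, rep) records")
        self.records = df.reset_index(drop=True)
        self.trait = trait
        self.single_location = single_location
        if single_location is None and df.location.nunique() < 2:
            raise ValueError("two-location model needs >=2 locations; "
                             "pass single_location= for the within-location variant")

    def _design(self):
        df = self.records
        y = df.value.to_numpy(float)
        cols = [np.ones(len(df))]
        names = ["intercept"]
        if self.single_location is None:
            locs = sorted(df.location.unique())
            for loc in locs[1:]:
                cols.append((df.location == loc).to_numpy(float))
                names.append(f"location[{loc}]")
            for loc in locs:
                reps = sorted(df.loc[df.location == loc, "rep"].unique())
                for r in reps[1:]:
                    cols.append(((df.location == loc) & (df.rep == r)).to_numpy(float))
                    names.append(f"rep[{loc}:{r}]")
        else:
            for r in sorted(df.rep.unique())[1:]:
                cols.append((df.rep == r).to_numpy(float))
                names.append(f"rep[{r}]")
        X = np.column_stack(cols)
        Z = {}
        Z["genotype"], _ = indicator(df.family)
        if self.single_location is None:
            Z["location:genotype"], _ = indicator(df.location.astype(str) + ":" + df.family.astype(str))
            blk = df.location.astype(str) + ":" + df.rep.astype(str) + ":" + df.block.astype(str)
        else:
            blk = df.rep.astype(str) + ":" + df.block.astype(str)
        Z["block"], _ = indicator(blk)
        return y, X, names, Z

    def fit(self, tol: float = 1e-6, max_iter: int = 500) -> VarianceComponents:
        y, X, names, Z = self._design()
        fit: RemlFit = em_reml(y, X, Z, tol=tol, max_iter=max_iter)
        if not fit.converged:
            warnings.warn(f"REML did not converge in {fit.n_iter} iterations "
                          f"for trait {self.trait}; returning last iterate")
        ne, nr = harmonic_means(self.records)
        fixed = dict(zip(names, fit.beta)) if len(fit.beta) == len(names) else \
            {f"b{i}": b for i, b in enumerate(fit.beta)}
        return VarianceComponents(
            trait=self.trait,
            sigma2_g=fit.sigma2["genotype"],
            sigma2_gxloc=fit.sigma2.get("location:genotype")
            if self.single_location is None else None,
            sigma2_block=fit.sigma2["block"],
            sigma2_e=fit.sigma2_e,
            fixed_estimates=fixed,
            converged=fit.converged,
            n_iter=fit.n_iter,
            ne=ne, nr=nr,
        )


fit_variance_model = VarianceDecomposition  # imperative alias


# --------------------------------------------------------------- BLUEs

@dataclass
class BlueTable:
    """Adjusted genotype means for one trial x trait."""

    location: str
    year: int
    trait: str
    table: pd.DataFrame  # columns family, blue, se
    sigma2_block: float
    sigma2_e: float

    def series(self) -> pd.Series:
        return self.table.set_index("family").blue


class TrialBlues:
    """Per-trial adjusted genotype means (genotype fixed, blocks random).

    Model y = mu + Rep + Bl(Rep) + g + e with Rep and g fixed; the block
    variance is estimated by REML and the genotype means are the GLS
    solutions, re-centred so their mean equals the trial mean.
    """

    def __init__(self, records: pd.DataFrame, trait: str):
        _check_records(records)
        df = records[records.trait == trait]
        if df.location.nunique() != 1 or df.year.nunique() != 1:
            raise ValueError("TrialBlues expects a single location-year trial")
        self.records = df.reset_index(drop=True)
        self.trait = trait

    def fit(self, tol: float = 1e-6, max_iter: int = 500) -> BlueTable:
        df = self.records
        y = df.value.to_numpy(float)
        fams = sorted(df.family.unique())
        cols = [np.ones(len(df))]
        names = ["intercept"]
        reps = sorted(df.rep.unique())
        for r in reps[1:]:
            cols.append((df.rep == r).to_numpy(float))
            names.append(f"rep[{r}]")
        for f in fams[1:]:
            cols.append((df.family == f).to_numpy(float))
            names.append(f"g[{f}]")
        X = np.column_stack(cols)
        blk = df.rep.astype(str) + ":" + df.block.astype(str)
        Zb, _ = indicator(blk)
        fit = em_reml(y, X, {"block": Zb}, tol=tol, max_iter=max_iter)
        s2b, s2e = fit.sigma2["block"], fit.sigma2_e

        # GLS at the estimated variances, with covariance for standard errors
        n = len(y)
        V = s2e * np.eye(n) + s2b * (Zb @ Zb.T)
        Vinv = np.linalg.inv(V)
        XtVinvX = X.T @ Vinv @ X
        cov = np.linalg.inv(XtVinvX)
        beta = cov @ (X.T @ Vinv @ y)
        name_idx = {nm: i for i, nm in enumerate(names)}
        rep_cols = [name_idx[f"rep[{r}]"] for r in reps[1:]]
        base = np.zeros(len(names))
        base[name_idx["intercept"]] = 1.0
        for c in rep_cols:  # average over replicates
            base[c] = 1.0 / len(reps)
        rows = []
        for f in fams:
            c = base.copy()
            if f != fams[0]:
                c[name_idx[f"g[{f}]"]] = 1.0
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            rows.append((f, est, se))
        table = pd.DataFrame(rows, columns=["family", "blue", "se"])
        table["blue"] += y.mean() - table.blue.mean()
        return BlueTable(str(df.location.iloc[0]), int(df.year.iloc[0]),
                         self.trait, table, s2b, s2e)


def fit_blues(records: pd.DataFrame, trait: str) -> BlueTable:
    return TrialBlues(records, trait).fit()


# -------------------------------------------------------- descriptive stats

def descriptive_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Per (trait, location) mean/SD/min/max/CV% and between-location
    correlation of family means.

    SD uses the n-1 denominator.  CV% = 100 SD / mean (missing when the mean
    is 0).  The correlation pairs family means across the two locations.
    """
    _check_records(records)
    rows = []
    for (trait, loc), grp in records.groupby(["trait", "location"]):
        v = grp.value
        mean, sd = v.mean(), v.std(ddof=1)
        cv = 100.0 * sd / mean if mean != 0 else np.nan
        rows.append((trait, loc, mean, sd, v.min(), v.max(), cv))
    out = pd.DataFrame(rows, columns=["trait", "location", "mean", "sd",
                                      "min", "max", "cv_pct"])
    corrs = {}
    for trait, grp in records.groupby("trait"):
        locs = sorted(grp.location.unique())
        if len(locs) == 2:
            means = grp.groupby(["family", "location"]).value.mean().unstack()
            both = means.dropna()
            if len(both) >= 3 and both[locs[0]].std() > 0 and both[locs[1]].std() > 0:
                corrs[trait] = float(both[locs[0]].corr(both[locs[1]]))
    out["corr_between_locations"] = out.trait.map(corrs)
    return out
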