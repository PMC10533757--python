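"""Single- and multi-environment Bayesian GBLUP.

The genetic covariance of records (individual, environment) is expressed as
a sum of environment-stacked kernels built from the genomic relationship
matrix G:

* SM  - single-environment model, one kernel (main effects only);
* MM  - multi-environment, main-effect kernel shared across environments;
* MDs - MM plus one G x E deviation kernel with a common variance
  (block-diagonal copies of G within environment);
* MDe - MM plus one deviation kernel per environment, each with its own
  variance.

Fitting is by Gibbs sampling on the eigenbasis of each kernel with
scaled-inverse-chi-square variance updates, flat-prior fixed effects
(intercept + environment), and data augmentation for records whose
phenotype is missing (the prediction targets).  A closed-form GBLUP at a
fixed variance ratio serves as an analytic cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import GenomicRelationship

MODELS = ("SM", "MM", "MDs", "MDe")


@dataclass
class McmcSettings:
    """Gibbs sampler settings.

    The "full" preset (burn-in 2000, 70000 iterations, thin 100) is the
    long-chain configuration for production analyses; the "desk" preset
    keeps replicated scenario runs tractable on one CPU.
    """

    burn_in: int = 500
    n_iter: int = 5000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "McmcSettings":
        if name == "full":
            return cls(burn_in=2000, n_iter=70_000, thin=100, seed=seed)
        if name == "desk":
            return cls(burn_in=500, n_iter=5000, thin=5, seed=seed)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class KernelSet:
    """Environment-stacked covariance kernels over (individual, environment) records."""

    individuals: np.ndarray
    environments: np.ndarray
    kernels: list            # list of (role, matrix)
    model: str

    _eig_cache: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.environments = np.asarray(self.environments, dtype=object)
        n = len(self.individuals)
        if len(self.environments) != n:
            raise ValueError("record vectors must have equal length")
        for role, K in self.kernels:
            if K.shape != (n, n):
                raise ValueError(f"kernel {role} has wrong shape")
            if not np.allclose(K, K.T, atol=1e-8):
                raise ValueError(f"kernel {role} not symmetric")

    @property
    def n_records(self) -> int:
        return len(self.individuals)

    @property
    def roles(self) -> list:
        return [r for r, _ in self.kernels]

    def fixed_design(self) -> tuple[np.ndarray, list]:
        envs = sorted(set(self.environments))
        cols = [np.ones(self.n_records)]
        names = ["intercept"]
        for e in envs[1:]:
            cols.append((self.environments == e).astype(float))
            names.append(f"env[{e}]")
        return np.column_stack(cols), names

    def eigendecompositions(self, min_eigval: float = 1e-8) -> list:
        """Cached (U, d) per kernel, components with eigenvalue < cutoff dropped."""
        if not self._eig_cache:
            for role, K in self.kernels:
                d, U = np.linalg.eigh(K)
                keep = d >= min_eigval
                if keep.sum() == 0:
                    raise ValueError(f"kernel {role} has no usable eigencomponents")
                self._eig_cache.append((role, U[:, keep], d[keep]))
        return self._eig_cache

    def record_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.individuals, self.environments], names=["individual", "environment"])


def build_kernels(G: GenomicRelationship, records, model: str) -> KernelSet:
    """Build the kernel stack for a model over (individual, environment) records."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    inds = np.asarray([r[0] for r in records], dtype=object)
    envs = np.asarray([r[1] for r in records], dtype=object)
    idx = G.indexer(inds)  # raises on unknown individual
    K_main = G.G[np.ix_(idx, idx)]
    env_levels = sorted(set(envs))
    if model == "SM" and len(env_levels) != 1:
        raise ValueError("SM is a single-environment model")
    if model == "MDe" and len(env_levels) < 2:
        raise ValueError("MDe needs >= 2 environments")
    kernels = [("main", K_main)]
    if model in ("MDs", "MDe"):
        same_env = (envs[:, None] == envs[None, :])
        if model == "MDs":
            kernels.append(("gxe_common", K_main * same_env))
        else:
            for e in env_levels:
                in_e = (envs == e)
                mask = in_e[:, None] & in_e[None, :]
                kernels.append((f"gxe_env:{e}", K_main * mask))
    return KernelSet(inds, envs, kernels, model)


# ----------------------------------------------------------- closed form

def gblup_closed_form(K: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """GBLUP genetic values at a fixed variance ratio lambda = s2_e / s2_g.

    Training records are the non-missing entries of ``y``; the fixed part is
    the training mean.  Held-out records are predicted through the
    cross-covariance: u_pred = K_pt (K_tt + lam I)^-1 (y_t - ybar).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    y = np.asarray(y, float)
    train = ~np.isnan(y)
    if train.sum() < 2:
        raise ValueError("need >= 2 training records")
    yt = y[train]
    Ktt = K[np.ix_(train, train)]
    A = Ktt + lam * np.eye(train.sum())
    try:
        alpha = np.linalg.solve(A, yt - yt.mean())
    except np.linalg.LinAlgError:
        A = A + 1e-8 * np.trace(A) / len(A) * np.eye(len(A))
        alpha = np.linalg.solve(A, yt - yt.mean())
    return K[:, train] @ alpha


# --------------------------------------------------------------- results

@dataclass
class PredictionResult:
    """Posterior summaries from :meth:`GBLUP.fit`."""

    gebv: pd.Series                      # (individual, environment) -> posterior mean
    variance_posterior_means: dict       # kernel role + "residual" -> variance
    fixed_posterior_means: dict
    effective_samples: int
    model: str

    def summary(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.variance_posterior_means.items()]
        df = pd.DataFrame(rows, columns=["component", "posterior_mean_variance"])
        df.attrs["model"] = self.model
        df.attrs["kept_samples"] = self.effective_samples
        return df

    def to_csv(self, path) -> None:
        out = self.gebv.rename("gebv").reset_index()
        out.to_csv(path, index=False)


class GBLUP:
    """Bayesian GBLUP over a kernel set.

    ``y`` is aligned with the kernel records; NaN marks prediction records
    (their genetic values are inferred through the joint kernel covariance
    via data augmentation).
    """

    def __init__(self, y: np.ndarray, kernels: KernelSet):
        y = np.asarray(y, float)
        if len(y) != kernels.n_records:
            raise ValueError("y not aligned with kernel records")
        if (~np.isnan(y)).sum() < 3:
            raise ValueError("need >= 3 training records")
        self.y = y
        self.kernels = kernels

    def fit(self, settings: McmcSettings | None = None,
            fixed_variances: dict | None = None) -> PredictionResult:
        """Run the Gibbs sampler and return posterior means.

        ``fixed_variances`` (role -> variance, plus "residual") clamps
        variances instead of sampling them - used for analytic cross-checks
        against the closed-form GBLUP at a known variance ratio.
        """
        settings = settings or McmcSettings()
        rng = np.random.default_rng(settings.seed)
        ks = self.kernels
        eigs = ks.eigendecompositions()
        n = ks.n_records
        X, fixed_names = ks.fixed_design()
        XtX_inv = np.linalg.inv(X.T @ X)
        Lx = np.linalg.cholesky(XtX_inv)

        train = ~np.isnan(self.y)
        y_aug = self.y.copy()
        y_aug[~train] = self.y[train].mean()

        vy = float(np.var(self.y[train])) or 1.0
        n_kern = len(eigs)
        df0 = settings.prior_df
        scale0 = vy / (n_kern + 1)   # equal partition across kernels + residual

        fixed = fixed_variances or {}
        sig = {role: fixed.get(role, scale0) for role, _, _ in eigs}
        sig_e = fixed.get("residual", scale0)

        a = {role: np.zeros(len(d)) for role, _, d in eigs}
        u = {role: np.zeros(n) for role, _, _ in eigs}
        beta = XtX_inv @ (X.T @ y_aug)

        keep = range(settings.burn_in, settings.n_iter, settings.thin)
        n_keep = len(keep)
        if n_keep < 2:
            raise ValueError("fewer than 2 kept samples; increase n_iter")
        keep_set = set(keep)

        sum_u_total = np.zeros(n)
        sum_sig = {role: 0.0 for role, _, _ in eigs}
        sum_sig_e = 0.0
        sum_beta = np.zeros(X.shape[1])
        kept = 0

        u_total = np.zeros(n)
        for it in range(settings.n_iter):
            # fixed effects (flat prior)
            r = y_aug - u_total
            beta_hat = XtX_inv @ (X.T @ r)
            beta = beta_hat + np.sqrt(sig_e) * (Lx @ rng.standard_normal(X.shape[1]))
            xb = X @ beta

            # kernel effects in the eigenbasis: W = U sqrt(d), W'W = diag(d)
            u_cond = np.zeros(n)  # Rao-Blackwellized E[u|rest] accumulator
            for role, U, d in eigs:
                r = y_aug - xb - (u_total - u[role])
                w_r = np.sqrt(d) * (U.T @ r)
                prec = d / sig_e + 1.0 / sig[role]
                mean = (w_r / sig_e) / prec
                a[role] = mean + rng.standard_normal(len(d)) / np.sqrt(prec)
                new_u = U @ (np.sqrt(d) * a[role])
                u_cond += U @ (np.sqrt(d) * mean)
                u_total += new_u - u[role]
                u[role] = new_u
                if role not in fixed:
                    ss = a[role] @ a[role]
                    sig[role] = (df0 * scale0 + ss) / rng.chisquare(df0 + len(d))

            e = y_aug - xb - u_total
            if "residual" not in fixed:
                sig_e = (df0 * scale0 + e @ e) / rng.chisquare(df0 + n)

            # impute the missing phenotypes from the current model state
            if (~train).any():
                mu_miss = xb[~train] + u_total[~train]
                y_aug[~train] = mu_miss + np.sqrt(sig_e) * rng.standard_normal((~train).sum())

            if it in keep_set:
                kept += 1
                sum_u_total += u_cond
                sum_beta += beta
                for role in sig:
                    sum_sig[role] += sig[role]
                sum_sig_e += sig_e

        gebv = pd.Series(sum_u_total / kept, index=ks.record_index())
        variances = {role: s / kept for role, s in sum_sig.items()}
        variances["residual"] = sum_sig_e / kept
        fixed_means = dict(zip(fixed_names, sum_beta / kept))
        return PredictionResult(gebv, variances, fixed_means, kept, ks.model)


def fit_gibbs(kernels: KernelSet, y: np.ndarray,
              settings: McmcSettings | None = None,
              fixed_variances: dict | None = None) -> PredictionResult:
    return GBLUP(y, kernels).fit(settings, fixed_variances)


# ----------------------------------------------------------- comparison

def predictive_ability(predictions, observed) -> float:
    """Pearson correlation between predictions and trial-adjusted means.

    Returns NaN when either vector is degenerate (zero variance).
    """
    p = np.asarray(predictions, float)
    o = np.asarray(observed, float)
    ok = ~(np.isnan(p) | np.isnan(o))
    p, o = p[ok], o[ok]
    if len(p) < 3:
        raise ValueError("need >= 3 paired values")
    if p.std() == 0 or o.std() == 0:
        return float("nan")
    return float(np.corrcoef(p, o)[0, 1])


def fisher_z(pa: float) -> float:
    """Fisher transformation Z = 0.5 log((1 + r) / (1 - r))."""
    if not abs(pa) < 1:
        raise ValueError("|PA| must be < 1")
    return 0.5 * float(np.log((1 + pa) / (1 - pa)))
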