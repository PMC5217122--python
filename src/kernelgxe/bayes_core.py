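"""Gibbs samplers for single- and multi-environment kernel regression.

Three models are fitted by exact block Gibbs sampling:

* model 1 — per-environment kernel regression ``y = 1μ + u + ε`` with
  ``u ~ N(0, σu² K)``;
* model 2 — multi-environment model ``y = μ + u + ε`` with
  ``u ~ N(0, UE ⊗ K)``, ``ε ~ N(0, Σ ⊗ I)``;
* model 3 — model 2 plus a non-marker genetic effect ``f ~ N(0, FE ⊗ I)``.

The ``u`` update exploits a one-time eigendecomposition ``K = V Λ Vᵀ``:
in eigencoordinates the n·m-dimensional conditional factorizes into n
independent m-variate Gaussians with precision ``UE⁻¹/λ_k + Σ⁻¹``.
Between-environment covariances get inverse-Wishart priors, variances get
scaled inverse chi-squared priors, intercepts are flat.  Missing phenotype
cells are handled by data augmentation; residual variances are updated from
observed cells only (a partially collapsed step — the augmented cells are
redrawn before anything conditions on them again).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kernels import KernelMatrix, add_jitter

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeTable",
    "PriorSpec",
    "McmcConfig",
    "EnvCovariance",
    "PosteriorChain",
    "default_single_prior",
    "default_multi_prior",
    "sample_scaled_inv_chi2",
    "sample_inv_wishart",
    "fit_single",
    "fit_multi",
    "successive_conditional_check",
    "CheckReport",
    "effective_sample_size",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Line-by-environment phenotype grid with an observed-cell mask.

    ``values[i, j]`` is the phenotype of line ``i`` in environment ``j``;
    entries where ``observed`` is False are ignored by all likelihood code.
    ``standardization`` records the per-environment (mean, SD) that was
    applied, if any.
    """

    line_ids: list
    env_ids: list
    values: np.ndarray
    observed: np.ndarray | None = None
    standardization: dict | None = None

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.env_ids = list(self.env_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        n, m = len(self.line_ids), len(self.env_ids)
        if self.values.shape != (n, m):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {m})")
        if self.observed is None:
            self.observed = ~np.isnan(self.values)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != (n, m):
            raise ValueError("observed mask shape mismatch")
        if np.isnan(self.values[self.observed]).any():
            raise ValueError("observed cells contain NaN")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicated line_ids")

    @property
    def n(self) -> int:
        return len(self.line_ids)

    @property
    def m(self) -> int:
        return len(self.env_ids)

    def env(self, j) -> "PhenotypeTable":
        """Single-environment slice (by index or env_id)."""
        if not isinstance(j, (int, np.integer)):
            j = self.env_ids.index(j)
        return PhenotypeTable(
            line_ids=self.line_ids,
            env_ids=[self.env_ids[j]],
            values=self.values[:, [j]],
            observed=self.observed[:, [j]],
            standardization=self.standardization,
        )

    def standardize(self, on: str = "full",
                    train_mask: np.ndarray | None = None) -> "PhenotypeTable":
        """Standardize each environment to mean 0, SD 1 over its observed cells.

        ``on="train"`` computes the statistics only from cells flagged True in
        ``train_mask`` (test values never enter), but applies the affine map
        to the whole column.
        """
        if on not in ("full", "train"):
            raise ValueError(f"unknown standardization mode {on!r}")
        if on == "train":
            if train_mask is None:
                raise ValueError('standardize(on="train") needs train_mask')
            stat_mask = self.observed & np.asarray(train_mask, bool)
        else:
            stat_mask = self.observed
        vals = self.values.copy()
        record = {}
        for j, env in enumerate(self.env_ids):
            sel = stat_mask[:, j]
            if sel.sum() < 2:
                raise ValueError(f"environment {env!r} has <2 cells to standardize on")
            mu = float(vals[sel, j].mean())
            sd = float(vals[sel, j].std(ddof=1))
            if sd == 0.0:
                raise ValueError(f"environment {env!r} has zero variance")
            vals[:, j] = (vals[:, j] - mu) / sd
            record[env] = (mu, sd)
        return PhenotypeTable(self.line_ids, self.env_ids, vals,
                              observed=self.observed.copy(), standardization=record)

    def mask_cells(self, keep: np.ndarray) -> "PhenotypeTable":
        """Copy with observed cells restricted to ``observed & keep``."""
        return PhenotypeTable(self.line_ids, self.env_ids, self.values.copy(),
                              observed=self.observed & np.asarray(keep, bool),
                              standardization=self.standardization)


@dataclass
class PriorSpec:
    """Hyperparameters for the variance priors.

    Scalar variances use the scaled inverse chi-squared convention with
    density ∝ (σ²)^-(df/2+1) exp(-S/(2σ²)) (prior mode S/(df+2), prior mean
    S/(df-2) for df > 2).  Covariance matrices use inverse-Wishart (S0, df0)
    with prior mean S0/(df0-m-1) when defined.
    """

    df_eps: float | np.ndarray = 5.0
    S_eps: float | np.ndarray = 3.5
    df_u: float = 5.0
    S_u: float = 3.5
    S0: np.ndarray | None = None
    df0: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.df_eps) <= 0) or self.df_u <= 0:
            raise ValueError("degrees of freedom must be positive")
        if np.any(np.asarray(self.S_eps) <= 0) or self.S_u <= 0:
            raise ValueError("prior scales must be positive")
        if self.S0 is not None:
            self.S0 = np.asarray(self.S0, dtype=float)
            if not np.allclose(self.S0, self.S0.T):
                raise ValueError("S0 must be symmetric")
            np.linalg.cholesky(self.S0)  # PD check
            if self.df0 is None or self.df0 < self.S0.shape[0]:
                raise ValueError("df0 must be >= m for an m x m S0")

    def eps_params(self, m: int) -> tuple[np.ndarray, np.ndarray]:
        df = np.broadcast_to(np.asarray(self.df_eps, float), (m,)).copy()
        S = np.broadcast_to(np.asarray(self.S_eps, float), (m,)).copy()
        return df, S


@dataclass
class McmcConfig:
    """Gibbs sampler schedule; the standard analysis default is 30,000 / 5,000 / 5."""

    iterations: int = 30_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    store_effects: bool = False

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    @property
    def retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class EnvCovariance:
    """Between-environment covariance components UE, FE and residual Σ."""

    UE: np.ndarray
    Sigma: np.ndarray
    FE: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.UE = np.asarray(self.UE, float)
        self.Sigma = np.asarray(self.Sigma, float).ravel()
        _check_spd(self.UE, "UE")
        if self.FE is not None:
            self.FE = np.asarray(self.FE, float)
            _check_spd(self.FE, "FE")
        if np.any(self.Sigma <= 0):
            raise ValueError("Sigma entries must be positive")

    @property
    def m(self) -> int:
        return self.UE.shape[0]


def _check_spd(A: np.ndarray, name: str) -> None:
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric to 1e-10")
    try:
        np.linalg.cholesky(A + 1e-12 * np.trace(A) / A.shape[0] * np.eye(A.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc


@dataclass
class PosteriorChain:
    """Retained MCMC draws plus running posterior means.

    Model 1 chains use ``m = 1`` with ``UE`` holding the 1x1 σu² draws so a
    single container serves all three models.  ``predicted`` is the posterior
    mean of μ + u (+ f) on the full line-by-environment grid — the quantity
    used for cross-validation prediction.
    """

    line_ids: list
    env_ids: list
    mu: np.ndarray            # (R, m)
    UE: np.ndarray            # (R, m, m)
    Sigma: np.ndarray         # (R, m)
    FE: np.ndarray | None     # (R, m, m) or None
    u_mean: np.ndarray        # (n, m)
    f_mean: np.ndarray | None
    predicted: np.ndarray     # (n, m)
    imputed_mean: np.ndarray | None  # (n, m), NaN at observed cells
    u_draws: np.ndarray | None = None
    f_draws: np.ndarray | None = None

    @property
    def retained(self) -> int:
        return self.mu.shape[0]

    @property
    def m(self) -> int:
        return len(self.env_ids)

    # convenience accessors for single-environment chains -------------------
    @property
    def sigma_u2(self) -> np.ndarray:
        if self.m != 1:
            raise AttributeError("sigma_u2 is only defined for m=1 chains")
        return self.UE[:, 0, 0]

    @property
    def sigma_eps2(self) -> np.ndarray:
        if self.m != 1:
            raise AttributeError("sigma_eps2 is only defined for m=1 chains")
        return self.Sigma[:, 0]

    def env_covariance(self) -> EnvCovariance:
        """Posterior-mean covariance components as an :class:`EnvCovariance`."""
        UE = self.UE.mean(axis=0)
        return EnvCovariance(
            UE=(UE + UE.T) / 2.0,
            Sigma=self.Sigma.mean(axis=0),
            FE=((self.FE.mean(axis=0) + self.FE.mean(axis=0).T) / 2.0
                if self.FE is not None else None),
        )

    def scalar_draws(self) -> dict:
        """Flat dict of named scalar chains (for ESS / CSV export)."""
        out = {}
        for j, env in enumerate(self.env_ids):
            out[f"mu[{env}]"] = self.mu[:, j]
            out[f"Sigma[{env}]"] = self.Sigma[:, j]
        for a in range(self.m):
            for b in range(a, self.m):
                out[f"UE[{self.env_ids[a]},{self.env_ids[b]}]"] = self.UE[:, a, b]
                if self.FE is not None:
                    out[f"FE[{self.env_ids[a]},{self.env_ids[b]}]"] = self.FE[:, a, b]
        return out

    def ess(self) -> dict:
        return {k: effective_sample_size(v) for k, v in self.scalar_draws().items()}

    def summary(self) -> dict:
        draws = self.scalar_draws()
        return {
            "retained": self.retained,
            "posterior_mean": {k: float(v.mean()) for k, v in draws.items()},
            "posterior_sd": {k: float(v.std(ddof=1)) for k, v in draws.items()},
            "ess": self.ess(),
        }


def effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-based ESS with Geweke-style truncation at the first
    nonpositive autocorrelation."""
    x = np.asarray(x, float)
    n = x.size
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * xc.var())
    s = 0.0
    for k in range(1, min(n - 1, 1000)):
        if acf[k] <= 0.0:
            break
        s += acf[k]
    return float(min(n, n / (1.0 + 2.0 * s)))


# ---------------------------------------------------------------------------
# priors and elementary samplers
# ---------------------------------------------------------------------------

def default_single_prior(y_env: np.ndarray, K: KernelMatrix,
                         df: float = 5.0) -> PriorSpec:
    """Default prior rule for the single-environment model.

    ``S_eps = 0.5 var(y) (df_eps + 2)`` and
    ``S_u = 0.5 var(y) (df_u + 2) / mean(diag K)`` with ``df_eps = df_u = 5``,
    so the prior mode of σε² sits at half the phenotypic variance.
    """
    y = np.asarray(y_env, float).ravel()
    y = y[~np.isnan(y)]
    if y.size < 2:
        raise ValueError("need at least 2 observed phenotypes")
    v = float(np.var(y, ddof=1))
    if v == 0.0:
        raise ValueError("phenotype variance is zero; cannot set default prior")
    mdk = float(np.diag(K.values).mean())
    return PriorSpec(df_eps=df, S_eps=0.5 * v * (df + 2.0),
                     df_u=df, S_u=0.5 * v * (df + 2.0) / mdk)


def default_multi_prior(m: int) -> PriorSpec:
    """Default multi-environment prior: S0 = I_m, df0 = m; residual scaled-inv-χ²(1, 1)."""
    if m < 2:
        raise ValueError("multi-environment prior needs m >= 2 (use model 1)")
    return PriorSpec(df_eps=1.0, S_eps=1.0, df_u=5.0, S_u=3.5,
                     S0=np.eye(m), df0=float(m))


def sample_scaled_inv_chi2(df: float, S: float, rng: np.random.Generator) -> float:
    """One draw of σ² ~ scaled-inv-χ²(df, S), i.e. S / χ²_df."""
    if df <= 0 or S <= 0:
        raise ValueError("df and S must be positive")
    return float(S / rng.chisquare(df))


def sample_inv_wishart(S0: np.ndarray, df0: float,
                       rng: np.random.Generator) -> np.ndarray:
    """One inverse-Wishart(S0, df0) draw (mean S0/(df0-m-1) when defined)."""
    S0 = np.asarray(S0, float)
    m = S0.shape[0]
    _check_spd(S0, "S0")
    if df0 < m:
        raise ValueError("df0 must be >= m")
    W = stats.invwishart.rvs(df=df0, scale=S0, random_state=rng)
    W = np.atleast_2d(W)
    return (W + W.T) / 2.0


def _draw_spd(S_post: np.ndarray, df_post: float,
              rng: np.random.Generator, name: str) -> np.ndarray:
    """Inverse-Wishart draw with one re-symmetrize + jitter retry on failure."""
    S_post = (S_post + S_post.T) / 2.0
    try:
        W = sample_inv_wishart(S_post, df_post, rng)
        np.linalg.cholesky(W)
        return W
    except (np.linalg.LinAlgError, ValueError):
        m = S_post.shape[0]
        S_j = S_post + 1e-8 * np.trace(S_post) / m * np.eye(m)
        logger.warning("re-symmetrizing and jittering %s scale matrix once", name)
        W = sample_inv_wishart(S_j, df_post, rng)
        np.linalg.cholesky(W)  # raises if still broken
        return W


# ---------------------------------------------------------------------------
# Gibbs machinery
# ---------------------------------------------------------------------------

def _eigen_kernel(K: KernelMatrix, line_ids: list) -> tuple[np.ndarray, np.ndarray]:
    Km = K.reorder(line_ids).values if list(K.line_ids) != list(line_ids) else K.values
    Kj = add_jitter(Km)
    lam, V = np.linalg.eigh((Kj + Kj.T) / 2.0)
    if lam[0] <= 0:
        raise ValueError("kernel is not PSD after jitter")
    return lam, V


class _SingleGibbs:
    """Mutable Gibbs state for model 1 on one environment.

    Sweep order: augment missing y, μ, u (eigencoordinates), σu², σε².
    The σε² update uses observed cells only; augmented cells are redrawn at
    the top of the next sweep before any step conditions on them.
    """

    def __init__(self, y: np.ndarray, observed: np.ndarray, lam: np.ndarray,
                 V: np.ndarray, prior: PriorSpec, rng: np.random.Generator,
                 fix_mu: float | None = None, fix_sigma_u2: float | None = None,
                 fix_sigma_eps2: float | None = None):
        self.obs = np.asarray(observed, bool)
        self.n = y.size
        self.n_obs = int(self.obs.sum())
        self.lam, self.V = lam, V
        self.prior, self.rng = prior, rng
        self.fix_mu = fix_mu
        self.fix_su2, self.fix_se2 = fix_sigma_u2, fix_sigma_eps2
        yo = y[self.obs]
        self.y = np.where(self.obs, y, yo.mean())
        self.mu = float(yo.mean()) if fix_mu is None else fix_mu
        v = float(np.var(yo, ddof=1)) if yo.size > 1 else 1.0
        self.su2 = 0.5 * max(v, 1e-6) if fix_sigma_u2 is None else fix_sigma_u2
        self.se2 = 0.5 * max(v, 1e-6) if fix_sigma_eps2 is None else fix_sigma_eps2
        self.b = np.zeros(self.n)
        self.u = np.zeros(self.n)

    def set_data(self, y: np.ndarray) -> None:
        self.y = np.where(self.obs, y, self.y)

    def sweep(self) -> None:
        rng, lam = self.rng, self.lam
        # 1. data augmentation at unobserved cells
        miss = ~self.obs
        if miss.any():
            self.y[miss] = (self.mu + self.u[miss]
                            + np.sqrt(self.se2) * rng.standard_normal(miss.sum()))
        # 2. intercept (flat prior)
        if self.fix_mu is None:
            r = self.y - self.u
            self.mu = float(rng.normal(r.mean(), np.sqrt(self.se2 / self.n)))
        # 3. genetic effect in eigencoordinates
        yt = self.V.T @ (self.y - self.mu)
        prec = 1.0 / self.se2 + 1.0 / (self.su2 * lam)
        mean = (yt / self.se2) / prec
        self.b = mean + rng.standard_normal(self.n) / np.sqrt(prec)
        self.u = self.V @ self.b
        # 4. genetic variance
        if self.fix_su2 is None:
            quad = float(np.sum(self.b**2 / lam))
            self.su2 = sample_scaled_inv_chi2(
                self.prior.df_u + self.n, self.prior.S_u + quad, rng)
        # 5. residual variance (observed cells only; partially collapsed)
        if self.fix_se2 is None:
            df_e, S_e = self.prior.eps_params(1)
            resid = self.y[self.obs] - self.mu - self.u[self.obs]
            self.se2 = sample_scaled_inv_chi2(
                float(df_e[0]) + self.n_obs, float(S_e[0]) + float(resid @ resid), rng)


class _MultiGibbs:
    """Mutable Gibbs state for models 2 (include_f=False) and 3."""

    def __init__(self, Y: np.ndarray, observed: np.ndarray, lam: np.ndarray,
                 V: np.ndarray, prior: PriorSpec, rng: np.random.Generator,
                 include_f: bool, fix_mu: np.ndarray | None = None,
                 fix_UE: np.ndarray | None = None, fix_FE: np.ndarray | None = None,
                 fix_Sigma: np.ndarray | None = None):
        self.n, self.m = Y.shape
        self.obs = np.asarray(observed, bool)
        self.lam, self.V = lam, V
        self.prior, self.rng = prior, rng
        self.include_f = include_f
        self.fix_mu, self.fix_UE = fix_mu, fix_UE
        self.fix_FE, self.fix_Sigma = fix_FE, fix_Sigma
        self.n_obs_j = self.obs.sum(axis=0)
        col_means = np.array([
            Y[self.obs[:, j], j].mean() if self.n_obs_j[j] else 0.0
            for j in range(self.m)
        ])
        self.Y = np.where(self.obs, Y, col_means[None, :])
        self.mu = col_means.copy() if fix_mu is None else np.asarray(fix_mu, float)
        self.UE = 0.5 * np.eye(self.m) if fix_UE is None else np.asarray(fix_UE, float)
        self.FE = None
        if include_f:
            self.FE = (0.5 * np.eye(self.m) if fix_FE is None
                       else np.asarray(fix_FE, float))
        self.Sigma = (np.full(self.m, 0.5) if fix_Sigma is None
                      else np.asarray(fix_Sigma, float).ravel().copy())
        self.B = np.zeros((self.n, self.m))
        self.U = np.zeros((self.n, self.m))
        self.F = np.zeros((self.n, self.m))
        if prior.S0 is None and (fix_UE is None or (include_f and fix_FE is None)):
            raise ValueError("multi-environment fit needs an inverse-Wishart prior (S0, df0)")

    def set_data(self, Y: np.ndarray) -> None:
        self.Y = np.where(self.obs, Y, self.Y)

    @staticmethod
    def _inv_spd(A: np.ndarray, name: str) -> np.ndarray:
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            m = A.shape[0]
            A = (A + A.T) / 2.0 + 1e-8 * np.trace(A) / m * np.eye(m)
            logger.warning("re-symmetrizing and jittering %s once before inverse", name)
            L = np.linalg.cholesky(A)  # raises if still broken
        Linv = np.linalg.inv(L)
        return Linv.T @ Linv

    def sweep(self) -> None:
        rng, n, m = self.rng, self.n, self.m
        # 1. data augmentation
        miss = ~self.obs
        if miss.any():
            mean_grid = self.mu[None, :] + self.U + self.F
            noise = rng.standard_normal((n, m)) * np.sqrt(self.Sigma)[None, :]
            self.Y[miss] = (mean_grid + noise)[miss]
        # 2. intercepts (flat prior)
        if self.fix_mu is None:
            R = self.Y - self.U - self.F
            self.mu = rng.normal(R.mean(axis=0), np.sqrt(self.Sigma / n))
        # 3. u-block in eigencoordinates: n independent m-variate Gaussians
        UEinv = self._inv_spd(self.UE, "UE")
        Sinv = 1.0 / self.Sigma
        R = self.Y - self.mu[None, :] - self.F
        Yt = self.V.T @ R
        P = (UEinv[None, :, :] / self.lam[:, None, None]
             + np.diag(Sinv)[None, :, :])
        L = np.linalg.cholesky(P)
        rhs = Yt * Sinv[None, :]
        mean = np.linalg.solve(P, rhs[:, :, None])[:, :, 0]
        z = rng.standard_normal((n, m))
        extra = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
        self.B = mean + extra
        self.U = self.V @ self.B
        # 4. UE | u ~ IW(S0 + Bᵀ Λ⁻¹ B, df0 + n)
        if self.fix_UE is None:
            quad = self.B.T @ (self.B / self.lam[:, None])
            self.UE = _draw_spd(self.prior.S0 + quad, self.prior.df0 + n, rng, "UE")
        # 5. f-block: n independent m-variate Gaussians, common precision
        if self.include_f:
            FEinv = self._inv_spd(self.FE, "FE")
            Pf = FEinv + np.diag(Sinv)
            Lf = np.linalg.cholesky(Pf)
            W = self.Y - self.mu[None, :] - self.U
            meanF = np.linalg.solve(Pf, (W * Sinv[None, :]).T).T
            zf = rng.standard_normal((n, m))
            self.F = meanF + np.linalg.solve(Lf.T, zf.T).T
            if self.fix_FE is None:
                self.FE = _draw_spd(self.prior.S0 + self.F.T @ self.F,
                                    self.prior.df0 + n, rng, "FE")
        # 6. residual variances (observed cells only; partially collapsed)
        if self.fix_Sigma is None:
            df_e, S_e = self.prior.eps_params(m)
            E = self.Y - self.mu[None, :] - self.U - self.F
            for j in range(m):
                sse = float(np.sum(E[self.obs[:, j], j] ** 2))
                self.Sigma[j] = sample_scaled_inv_chi2(
                    df_e[j] + self.n_obs_j[j], S_e[j] + sse, rng)


def _run_chain(state, mcmc: McmcConfig, line_ids: list, env_ids: list,
               observed: np.ndarray) -> PosteriorChain:
    """Drive a Gibbs state through the schedule and accumulate the chain."""
    n, m = len(line_ids), len(env_ids)
    R = mcmc.retained
    mu_d = np.empty((R, m))
    UE_d = np.empty((R, m, m))
    Sig_d = np.empty((R, m))
    FE_d = np.empty((R, m, m)) if getattr(state, "include_f", False) else None
    u_sum = np.zeros((n, m))
    f_sum = np.zeros((n, m)) if FE_d is not None else None
    pred_sum = np.zeros((n, m))
    imp_sum = np.zeros((n, m))
    u_draws = np.empty((R, n, m)) if mcmc.store_effects else None
    f_draws = np.empty((R, n, m)) if (mcmc.store_effects and FE_d is not None) else None
    single = isinstance(state, _SingleGibbs)
    r = 0
    for t in range(1, mcmc.iterations + 1):
        state.sweep()
        if t <= mcmc.burn_in or (t - mcmc.burn_in) % mcmc.thin != 0:
            continue
        if single:
            mu_d[r, 0] = state.mu
            UE_d[r, 0, 0] = state.su2
            Sig_d[r, 0] = state.se2
            u = state.u[:, None]
            pred = state.mu + u
            ycur = state.y[:, None]
        else:
            mu_d[r] = state.mu
            UE_d[r] = state.UE
            Sig_d[r] = state.Sigma
            if FE_d is not None:
                FE_d[r] = state.FE
                if f_draws is not None:
                    f_draws[r] = state.F
                f_sum += state.F
            u = state.U
            pred = state.mu[None, :] + state.U + state.F
            ycur = state.Y
        u_sum += u
        pred_sum += pred
        imp_sum += ycur
        if u_draws is not None:
            u_draws[r] = u
        r += 1
    assert r == R
    imputed = np.where(observed, np.nan, imp_sum / R)
    return PosteriorChain(
        line_ids=line_ids, env_ids=env_ids,
        mu=mu_d, UE=UE_d, Sigma=Sig_d, FE=FE_d,
        u_mean=u_sum / R,
        f_mean=(f_sum / R) if f_sum is not None else None,
        predicted=pred_sum / R,
        imputed_mean=imputed if (~observed).any() else None,
        u_draws=u_draws, f_draws=f_draws,
    )


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_single(y: PhenotypeTable, K: KernelMatrix, prior: PriorSpec,
               mcmc: McmcConfig, fix_mu: float | None = None,
               fix_sigma_u2: float | None = None,
               fix_sigma_eps2: float | None = None) -> PosteriorChain:
    """Fit the single-environment kernel regression (model 1) by Gibbs sampling.

    ``y`` must hold exactly one environment; unobserved cells are imputed by
    data augmentation and predicted via the posterior mean of μ + u.  The
    ``fix_*`` arguments freeze a parameter at a known value (used by the
    conjugate-oracle tests); identical inputs and seed give identical chains.
    """
    if y.m != 1:
        raise ValueError("fit_single expects a single-environment PhenotypeTable")
    yv = y.values[:, 0]
    obs = y.observed[:, 0]
    if obs.sum() < 10:
        raise ValueError("need >= 10 observed values in the environment")
    if not np.isfinite(yv[obs]).all():
        raise ValueError("non-finite phenotype values")
    lam, V = _eigen_kernel(K, y.line_ids)
    rng = np.random.default_rng(mcmc.seed)
    state = _SingleGibbs(yv, obs, lam, V, prior, rng, fix_mu=fix_mu,
                         fix_sigma_u2=fix_sigma_u2, fix_sigma_eps2=fix_sigma_eps2)
    return _run_chain(state, mcmc, y.line_ids, y.env_ids, y.observed)


def fit_multi(y: PhenotypeTable, K: KernelMatrix, include_f: bool,
              prior: PriorSpec, mcmc: McmcConfig,
              fix_mu: np.ndarray | None = None, fix_UE: np.ndarray | None = None,
              fix_FE: np.ndarray | None = None,
              fix_Sigma: np.ndarray | None = None) -> PosteriorChain:
    """Fit the multi-environment G×E model (2, or 3 with ``include_f=True``).

    All environments must share the line set of ``y`` and every line must be
    observed in at least one environment.  Returns retained draws of μ, UE
    (FE), Σ, posterior-mean effect grids, and predictions μ̂ + û (+ f̂) for
    every cell.
    """
    if y.m < 2:
        raise ValueError("fit_multi needs m >= 2 environments")
    empty_env = np.where(y.observed.sum(axis=0) == 0)[0]
    if empty_env.size:
        raise ValueError(f"environment {y.env_ids[empty_env[0]]!r} has no observed cells")
    uncovered = np.where(y.observed.sum(axis=1) == 0)[0]
    if uncovered.size:
        raise ValueError(
            f"line {y.line_ids[uncovered[0]]!r} observed in no environment; "
            "its effects are unidentifiable under CV2")
    if not np.isfinite(y.values[y.observed]).all():
        raise ValueError("non-finite phenotype values")
    lam, V = _eigen_kernel(K, y.line_ids)
    rng = np.random.default_rng(mcmc.seed)
    state = _MultiGibbs(y.values, y.observed, lam, V, prior, rng,
                        include_f=include_f, fix_mu=fix_mu, fix_UE=fix_UE,
                        fix_FE=fix_FE, fix_Sigma=fix_Sigma)
    return _run_chain(state, mcmc, y.line_ids, y.env_ids, y.observed)


# ---------------------------------------------------------------------------
# getting-it-right harness
# ---------------------------------------------------------------------------

@dataclass
class CheckReport:
    """Result of the successive-conditional (getting-it-right) simulator."""

    rows: list
    passed: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"{r['param']:>12s}: chain {r['chain_mean']:+.4f}  "
            f"prior {r['prior_mean']:+.4f}  z={r['z']:+.2f}  "
            f"{'ok' if r['ok'] else 'FAIL'}"
            for r in self.rows
        ]
        return "\n".join(lines + [f"passed: {self.passed}"])


def _batch_se(x: np.ndarray, n_batches: int = 50) -> float:
    """Batch-means standard error for an autocorrelated chain."""
    n = x.size // n_batches
    bm = x[: n * n_batches].reshape(n_batches, n).mean(axis=1)
    return float(bm.std(ddof=1) / np.sqrt(n_batches))


def successive_conditional_check(
    model: str,
    dims: dict,
    prior: PriorSpec,
    cycles: int = 20_000,
    seed: int = 0,
    _corrupt: float = 1.0,
) -> CheckReport:
    """Geweke-style successive-conditional test of the Gibbs conditionals.

    Alternates (data | parameters) and one Gibbs sweep (parameters | data);
    the marginal distribution of the parameter chain must equal the prior.
    Tracked prior moments are compared with direct prior draws; any moment
    off by more than 4 combined standard errors fails.  Intercepts are fixed
    at 0 (their flat prior cannot be sampled).  Use a prior with finite
    element variances (scalar df > 4, df0 >= m + 4) for a meaningful check.

    ``_corrupt`` multiplies the residual-variance draws each cycle — a test
    hook to verify the harness detects a broken conditional.
    """
    if model not in ("single", "multi2", "multi3"):
        raise ValueError(f"unknown model {model!r}")
    n = int(dims.get("n", 10))
    m = int(dims.get("m", 2))
    rng = np.random.default_rng(seed)
    # fixed, well-conditioned kernel for the whole check
    X = rng.standard_normal((n, 2 * n))
    K = X @ X.T / (2 * n)
    lam, V = np.linalg.eigh(K + 1e-6 * np.eye(n))
    Lk = np.linalg.cholesky(K + 1e-6 * np.eye(n))
    df_e, S_e = prior.eps_params(m if model != "single" else 1)

    tracked: dict[str, list] = {}

    def track(name: str, val: float) -> None:
        tracked.setdefault(name, []).append(val)

    if model == "single":
        obs = np.ones(n, bool)
        state = _SingleGibbs(np.zeros(n), obs, lam, V, prior, rng, fix_mu=0.0)
        state.su2 = sample_scaled_inv_chi2(prior.df_u, prior.S_u, rng)
        state.se2 = sample_scaled_inv_chi2(float(df_e[0]), float(S_e[0]), rng)
        state.b = rng.standard_normal(n) * np.sqrt(state.su2 * lam)
        state.u = V @ state.b
        for _ in range(cycles):
            ydat = state.u + np.sqrt(state.se2) * rng.standard_normal(n)
            state.set_data(ydat)
            state.sweep()
            state.se2 *= _corrupt
            track("sigma_u2", state.su2)
            track("sigma_eps2", state.se2)
        prior_draws = {
            "sigma_u2": prior.S_u / rng.chisquare(prior.df_u, cycles),
            "sigma_eps2": float(S_e[0]) / rng.chisquare(float(df_e[0]), cycles),
        }
    else:
        include_f = model == "multi3"
        obs = np.ones((n, m), bool)
        state = _MultiGibbs(np.zeros((n, m)), obs, lam, V, prior, rng,
                            include_f=include_f, fix_mu=np.zeros(m))
        state.UE = sample_inv_wishart(prior.S0, prior.df0, rng)
        state.Sigma = np.array([
            sample_scaled_inv_chi2(df_e[j], S_e[j], rng) for j in range(m)])
        state.B = (rng.standard_normal((n, m)) @ np.linalg.cholesky(state.UE).T
                   * np.sqrt(lam)[:, None])
        state.U = V @ state.B
        if include_f:
            state.FE = sample_inv_wishart(prior.S0, prior.df0, rng)
            state.F = rng.standard_normal((n, m)) @ np.linalg.cholesky(state.FE).T
        for _ in range(cycles):
            ydat = (state.U + state.F
                    + rng.standard_normal((n, m)) * np.sqrt(state.Sigma)[None, :])
            state.set_data(ydat)
            state.sweep()
            state.Sigma = state.Sigma * _corrupt
            track("UE[0,0]", state.UE[0, 0])
            track("UE[0,1]", state.UE[0, 1])
            track("Sigma[0]", state.Sigma[0])
            if include_f:
                track("FE[0,0]", state.FE[0, 0])
                track("FE[0,1]", state.FE[0, 1])
        iw = stats.invwishart.rvs(df=prior.df0, scale=prior.S0,
                                  size=cycles, random_state=rng)
        iw = iw.reshape(cycles, m, m)
        prior_draws = {
            "UE[0,0]": iw[:, 0, 0],
            "UE[0,1]": iw[:, 0, 1],
            "Sigma[0]": S_e[0] / rng.chisquare(df_e[0], cycles),
        }
        if include_f:
            iw2 = stats.invwishart.rvs(df=prior.df0, scale=prior.S0,
                                       size=cycles, random_state=rng).reshape(cycles, m, m)
            prior_draws["FE[0,0]"] = iw2[:, 0, 0]
            prior_draws["FE[0,1]"] = iw2[:, 0, 1]

    rows = []
    for name, chain in tracked.items():
        chain = np.asarray(chain)
        pd_draws = prior_draws[name]
        se = float(np.hypot(_batch_se(chain),
                            pd_draws.std(ddof=1) / np.sqrt(pd_draws.size)))
        z = (chain.mean() - pd_draws.mean()) / se if se > 0 else np.inf
        rows.append({
            "param": name,
            "chain_mean": float(chain.mean()),
            "prior_mean": float(pd_draws.mean()),
            "se": se,
            "z": float(z),
            "ok": bool(abs(z) <= 4.0),
        })
    return CheckReport(rows=rows, passed=all(r["ok"] for r in rows))
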