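"""Simulation of marker matrices and multi-environment phenotypes.

Generates data with exactly the generative structure the samplers assume
(y = μ + u + f + ε with u ~ N(0, UE⊗K), f ~ N(0, FE⊗I), ε ~ N(0, Σ⊗I)),
plus an epistatic variant in which the genetic values come from marker main
effects and sparse pairwise marker-product effects, so the linear kernel is
misspecified while the Gaussian kernel can capture the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .bayes_core import PhenotypeTable
from .kernels import KernelMatrix, MarkerMatrix, add_jitter

__all__ = [
    "SimulationScenario",
    "simulate_markers",
    "simulate_multienv_phenotypes",
    "scenario_from_yaml",
    "corr_to_cov",
]


def corr_to_cov(corr: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Covariance matrix from a correlation matrix and per-env variances."""
    sd = np.sqrt(np.asarray(variances, float))
    return np.asarray(corr, float) * np.outer(sd, sd)


@dataclass
class SimulationScenario:
    """Parameters of one synthetic multi-environment data set.

    Mirrors the scale of the motivating field data: n lines (hundreds)
    phenotyped in m environments (3-5), p biallelic markers, standardized
    per-environment phenotypes, and between-environment genetic correlations
    anywhere in [-1, 1].
    """

    n: int
    m: int
    p: int
    UE_true: np.ndarray
    Sigma_true: np.ndarray
    FE_true: np.ndarray | None = None
    maf_range: tuple = (0.05, 0.5)
    mu_true: np.ndarray | None = None
    architecture: str = "additive"      # additive | epistatic
    additive_share: float = 0.5         # epistatic architecture only
    kernel_for_u: str = "linear"        # linear | gaussian
    bandwidth: float | None = None      # gaussian generation kernel only
    seed: int = 0

    def __post_init__(self) -> None:
        self.UE_true = np.asarray(self.UE_true, float)
        self.Sigma_true = np.asarray(self.Sigma_true, float).ravel()
        if self.UE_true.shape != (self.m, self.m):
            raise ValueError("UE_true must be m x m")
        np.linalg.cholesky(self.UE_true + 1e-12 * np.eye(self.m))
        if self.FE_true is not None:
            self.FE_true = np.asarray(self.FE_true, float)
            if self.FE_true.shape != (self.m, self.m):
                raise ValueError("FE_true must be m x m")
            # PD up to the FE=0 degenerate case, which is allowed
            w = np.linalg.eigvalsh((self.FE_true + self.FE_true.T) / 2.0)
            if w[0] < -1e-10:
                raise ValueError("FE_true must be positive semidefinite")
        if self.Sigma_true.size != self.m or np.any(self.Sigma_true <= 0):
            raise ValueError("Sigma_true must be m positive variances")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.architecture not in ("additive", "epistatic"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not (0.0 <= self.additive_share <= 1.0):
            raise ValueError("additive_share must be in [0, 1]")
        if self.mu_true is not None:
            self.mu_true = np.asarray(self.mu_true, float).ravel()
            if self.mu_true.size != self.m:
                raise ValueError("mu_true must have length m")


def simulate_markers(n: int, p: int, maf_range: tuple = (0.05, 0.5),
                     seed: int | None = None) -> MarkerMatrix:
    """Raw biallelic genotypes: per-marker allele frequency uniform on
    ``maf_range``, genotypes binomial(2, freq) per line."""
    if n < 2 or p < 2:
        raise ValueError("need n >= 2 lines and p >= 2 markers")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=p)
    vals = rng.binomial(2, freqs[None, :], size=(n, p)).astype(float)
    return MarkerMatrix(
        line_ids=[f"L{i:04d}" for i in range(n)],
        marker_ids=[f"M{j:05d}" for j in range(p)],
        values=vals,
        is_standardized=False,
    )


def _chol_psd(A: np.ndarray) -> np.ndarray:
    """Cholesky factor, tolerating an exactly-zero matrix."""
    if np.allclose(A, 0.0):
        return np.zeros_like(A)
    return np.linalg.cholesky(add_jitter(A, rel=1e-10) if _needs_jitter(A) else A)


def _needs_jitter(A: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(A)
        return False
    except np.linalg.LinAlgError:
        return True


def simulate_multienv_phenotypes(
    scenario: SimulationScenario,
    K: KernelMatrix,
    markers: MarkerMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, dict]:
    """Draw one phenotype grid from the generative model of the samplers.

    ``additive`` architecture: u ~ N(0, UE⊗K) via Cholesky factors of UE and
    the (jittered) kernel.  ``epistatic``: genetic values are X·β + Z_S·γ
    with |S| = p random marker pairs; β rows iid N(0, w·UE/p) and γ rows iid
    N(0, (1−w)·UE/|S|), w = ``additive_share`` — between-environment
    correlations still follow UE but line-line similarity is non-linear in
    the markers.  Returns the table (all cells observed) and a truth record
    with u, f and the noise.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    n, m = scenario.n, scenario.m
    if K.n != n:
        raise ValueError("kernel size does not match scenario n")
    if scenario.FE_true is not None and scenario.FE_true.shape[0] != m:
        raise ValueError("FE_true dimension does not match m")
    Lu = np.linalg.cholesky(scenario.UE_true + 1e-12 * np.eye(m)) \
        if not np.allclose(scenario.UE_true, 0) else np.zeros((m, m))

    if scenario.architecture == "additive":
        Lk = np.linalg.cholesky(add_jitter(K.values))
        U = Lk @ rng.standard_normal((n, m)) @ Lu.T
    else:
        if markers is None or not markers.is_standardized:
            raise ValueError("epistatic architecture needs standardized markers")
        X = markers.values
        p = X.shape[1]
        w = scenario.additive_share
        beta = rng.standard_normal((p, m)) @ (np.sqrt(w / p) * Lu).T
        n_pairs = p
        ii = rng.integers(0, p, size=n_pairs)
        jj = rng.integers(0, p, size=n_pairs)
        redraw = ii == jj
        while redraw.any():
            jj[redraw] = rng.integers(0, p, size=int(redraw.sum()))
            redraw = ii == jj
        Z = X[:, ii] * X[:, jj]
        gamma = rng.standard_normal((n_pairs, m)) @ (np.sqrt((1 - w) / n_pairs) * Lu).T
        U = X @ beta + Z @ gamma

    if scenario.FE_true is not None and not np.allclose(scenario.FE_true, 0):
        Lf = np.linalg.cholesky(scenario.FE_true + 1e-12 * np.eye(m))
        F = rng.standard_normal((n, m)) @ Lf.T
    else:
        F = np.zeros((n, m))

    E = rng.standard_normal((n, m)) * np.sqrt(scenario.Sigma_true)[None, :]
    mu = scenario.mu_true if scenario.mu_true is not None else np.zeros(m)
    Y = mu[None, :] + U + F + E
    table = PhenotypeTable(
        line_ids=K.line_ids,
        env_ids=[f"E{j + 1}" for j in range(m)],
        values=Y,
        observed=np.ones((n, m), bool),
    )
    truth = {"mu": mu, "u": U, "f": F, "eps": E}
    return table, truth


def scenario_from_yaml(path) -> SimulationScenario:
    """Load a scenario preset; correlations + variances are expanded to UE."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("scenario file must be a YAML mapping")
    known = {"n", "m", "p", "UE_corr", "UE_var", "UE_true", "FE_true", "FE_corr",
             "FE_var", "Sigma_true", "maf_range", "mu_true", "architecture",
             "additive_share", "kernel_for_u", "bandwidth", "seed", "name"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    m = int(doc["m"])
    if "UE_true" in doc:
        UE = np.asarray(doc["UE_true"], float)
    else:
        UE = corr_to_cov(np.asarray(doc["UE_corr"], float),
                         np.asarray(doc.get("UE_var", np.ones(m)), float))
    FE = None
    if "FE_true" in doc:
        FE = np.asarray(doc["FE_true"], float)
    elif "FE_corr" in doc:
        FE = corr_to_cov(np.asarray(doc["FE_corr"], float),
                         np.asarray(doc.get("FE_var", np.ones(m)), float))
    return SimulationScenario(
        n=int(doc["n"]), m=m, p=int(doc["p"]),
        UE_true=UE, FE_true=FE,
        Sigma_true=np.asarray(doc["Sigma_true"], float),
        maf_range=tuple(doc.get("maf_range", (0.05, 0.5))),
        mu_true=np.asarray(doc["mu_true"], float) if "mu_true" in doc else None,
        architecture=doc.get("architecture", "additive"),
        additive_share=float(doc.get("additive_share", 0.5)),
        kernel_for_u=doc.get("kernel_for_u", "linear"),
        bandwidth=doc.get("bandwidth"),
        seed=int(doc.get("seed", 0)),
    )
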