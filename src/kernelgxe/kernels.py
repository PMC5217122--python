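"""Marker quality control and kernel construction.

Builds the two relationship kernels used throughout the package: the linear
(GBLUP) kernel ``K = X Xᵀ / p`` on centered-and-scaled genotypes, and the
Gaussian kernel ``K = exp(-h d²)`` on marker distances, together with a
marginal-likelihood grid search for the bandwidth ``h``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "KernelMatrix",
    "QCReport",
    "SquaredDistances",
    "standardize_markers",
    "linear_kernel",
    "squared_distances",
    "gaussian_kernel",
    "estimate_bandwidth",
    "add_jitter",
]

#: relative diagonal jitter applied once before factorizing a kernel
JITTER_REL = 1e-8


@dataclass
class MarkerMatrix:
    """Genotype matrix of ``n`` lines by ``p`` markers.

    Raw matrices hold biallelic codes {0, 1, 2} (or dosages) with ``nan``
    for missing calls.  Standardized matrices are real-valued with every
    column centered to mean 0 and scaled to population SD 1, no missing.
    """

    line_ids: list
    marker_ids: list
    values: np.ndarray
    is_standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        if self.values.ndim != 2:
            raise ValueError("marker values must be 2-D (lines x markers)")
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"marker matrix shape {self.values.shape} does not match "
                f"{len(self.line_ids)} line_ids x {len(self.marker_ids)} marker_ids"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicated line_ids in marker matrix")
        if self.is_standardized:
            if np.isnan(self.values).any():
                raise ValueError("standardized marker matrix contains missing values")
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0)
            if not (np.all(np.abs(mu) <= 1e-8) and np.all(np.abs(sd - 1.0) <= 1e-8)):
                raise ValueError("standardized marker columns must have mean 0 and SD 1")

    @property
    def n(self) -> int:
        return len(self.line_ids)

    @property
    def p(self) -> int:
        return len(self.marker_ids)


@dataclass
class QCReport:
    """Outcome of marker QC: which markers survived and why others did not."""

    kept: list
    dropped: list  # list of (marker_id, reason)
    n_imputed: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"QCReport(kept={len(self.kept)}, dropped={len(self.dropped)}, "
            f"imputed_calls={self.n_imputed})"
        )


@dataclass
class KernelMatrix:
    """An ``n x n`` symmetric PSD relationship matrix between lines."""

    line_ids: list
    values: np.ndarray
    kind: str = "custom"  # linear | gaussian | custom
    bandwidth: float | None = None
    distance_scale: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = list(self.line_ids)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel shape {self.values.shape} != ({n}, {n})")
        if self.kind not in ("linear", "gaussian", "custom"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        self.validate()

    def validate(self) -> None:
        K = self.values
        if not np.allclose(K, K.T, atol=1e-10, rtol=0.0):
            raise ValueError("kernel is not symmetric to 1e-10")
        w = np.linalg.eigvalsh((K + K.T) / 2.0)
        if w[0] < -1e-8 * max(w[-1], 0.0) - 1e-12:
            raise ValueError(f"kernel is not PSD: min eigenvalue {w[0]:.3e}")
        if self.kind == "gaussian":
            if self.bandwidth is None or self.bandwidth <= 0:
                raise ValueError("gaussian kernel requires positive bandwidth metadata")
            if not np.all(np.diag(K) == 1.0):
                raise ValueError("gaussian kernel diagonal must be exactly 1")
            if np.any(K <= 0.0) or np.any(K > 1.0):
                raise ValueError("gaussian kernel entries must lie in (0, 1]")

    @property
    def n(self) -> int:
        return len(self.line_ids)

    def reorder(self, line_ids: list) -> "KernelMatrix":
        """Return a copy aligned to ``line_ids`` (must be a subset-free match)."""
        idx = _index_of(self.line_ids, line_ids, what="kernel")
        return KernelMatrix(
            line_ids=list(line_ids),
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
            bandwidth=self.bandwidth,
            distance_scale=self.distance_scale,
        )


@dataclass
class SquaredDistances:
    """Pairwise squared marker distances with the scaling that was applied."""

    line_ids: list
    values: np.ndarray
    scale: str = "median"
    scale_value: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _index_of(have: list, want: list, what: str = "lines") -> np.ndarray:
    pos = {lid: i for i, lid in enumerate(have)}
    missing = [lid for lid in want if lid not in pos]
    if missing:
        raise KeyError(f"{what} is missing line_ids {missing[:5]}")
    return np.array([pos[lid] for lid in want], dtype=int)


def standardize_markers(
    raw: MarkerMatrix,
    maf_threshold: float = 0.05,
    impute_mode: str = "mean",
    seed: int | None = None,
) -> tuple[MarkerMatrix, QCReport]:
    """QC, impute and standardize a raw genotype matrix.

    Markers with minor allele frequency below ``maf_threshold`` (computed on
    observed calls, before imputation) or with zero variance are removed.
    Missing calls are imputed with the column mean (``impute_mode="mean"``)
    or with draws from the column's empirical marginal genotype distribution
    (``impute_mode="bernoulli_draw"``).  Surviving columns are centered and
    scaled to unit population SD.

    Returns the standardized matrix and a :class:`QCReport` listing every
    dropped marker with its reason.
    """
    if raw.is_standardized:
        raise ValueError("input marker matrix is already standardized")
    if not (0.0 <= maf_threshold < 0.5):
        raise ValueError(f"maf_threshold must be in [0, 0.5), got {maf_threshold}")
    if impute_mode not in ("mean", "bernoulli_draw"):
        raise ValueError(f"unknown impute_mode {impute_mode!r}")

    X = raw.values.copy()
    obs = ~np.isnan(X)
    all_missing = np.where(~obs.any(axis=1))[0]
    if all_missing.size:
        raise ValueError(
            f"line {raw.line_ids[all_missing[0]]!r} has all genotypes missing"
        )

    rng = np.random.default_rng(seed)
    kept_idx: list[int] = []
    dropped: list[tuple] = []
    for j, mid in enumerate(raw.marker_ids):
        col = X[obs[:, j], j]
        if col.size == 0 or np.ptp(col) == 0.0:
            dropped.append((mid, "zero_variance"))
            continue
        freq = col.mean() / 2.0
        maf = min(freq, 1.0 - freq)
        if maf < maf_threshold:
            dropped.append((mid, f"maf<{maf_threshold:g}"))
            continue
        kept_idx.append(j)

    if not kept_idx:
        raise ValueError("no markers survive QC")

    kept_idx_arr = np.array(kept_idx, dtype=int)
    Xk = X[:, kept_idx_arr]
    n_imputed = int(np.isnan(Xk).sum())
    for jj in range(Xk.shape[1]):
        miss = np.isnan(Xk[:, jj])
        if not miss.any():
            continue
        seen = Xk[~miss, jj]
        if impute_mode == "mean":
            Xk[miss, jj] = seen.mean()
        else:
            Xk[miss, jj] = rng.choice(seen, size=int(miss.sum()), replace=True)

    mu = Xk.mean(axis=0)
    sd = Xk.std(axis=0)  # population SD, ddof=0 (documented convention)
    # bernoulli_draw imputation can in principle collapse a column; guard
    zero_sd = np.where(sd == 0.0)[0]
    if zero_sd.size:
        keep = np.setdiff1d(np.arange(Xk.shape[1]), zero_sd)
        for jj in zero_sd:
            dropped.append((raw.marker_ids[kept_idx_arr[jj]], "zero_variance_after_impute"))
        if keep.size == 0:
            raise ValueError("no markers survive QC")
        kept_idx_arr = kept_idx_arr[keep]
        Xk, mu, sd = Xk[:, keep], mu[keep], sd[keep]

    Xs = (Xk - mu) / sd
    kept_ids = [raw.marker_ids[j] for j in kept_idx_arr]
    out = MarkerMatrix(raw.line_ids, kept_ids, Xs, is_standardized=True)
    report = QCReport(kept=kept_ids, dropped=dropped, n_imputed=n_imputed)
    logger.info(
        "marker QC: kept %d / %d markers, imputed %d calls",
        len(kept_ids), raw.p, n_imputed,
    )
    return out, report


def linear_kernel(X: MarkerMatrix) -> KernelMatrix:
    """Linear (GBLUP) kernel ``K = X Xᵀ / p`` on standardized markers."""
    if not X.is_standardized:
        raise ValueError("linear_kernel requires a standardized MarkerMatrix")
    if X.p < 1:
        raise ValueError("need at least one marker")
    K = X.values @ X.values.T / X.p
    K = (K + K.T) / 2.0
    logger.info("linear kernel: mean diagonal = %.6f", float(np.diag(K).mean()))
    return KernelMatrix(line_ids=X.line_ids, values=K, kind="linear")


def squared_distances(X: MarkerMatrix, scale: str = "median") -> SquaredDistances:
    """Pairwise squared Euclidean marker distances, optionally rescaled.

    ``scale="median"`` (default) divides by the median off-diagonal squared
    distance so a bandwidth near 1 is a natural grid center; ``"mean"`` uses
    the mean instead; ``"none"`` leaves raw squared distances.
    """
    if not X.is_standardized:
        raise ValueError("squared_distances requires a standardized MarkerMatrix")
    if scale not in ("none", "median", "mean"):
        raise ValueError(f"unknown scale {scale!r}")
    if X.n < 2 and scale != "none":
        raise ValueError("need at least 2 lines to scale by an off-diagonal summary")
    d2_cond = pdist(X.values, metric="sqeuclidean")
    scale_value = 1.0
    if scale == "median":
        scale_value = float(np.median(d2_cond))
    elif scale == "mean":
        scale_value = float(np.mean(d2_cond))
    if scale != "none":
        if scale_value <= 0.0:
            raise ValueError("off-diagonal distance summary is zero; cannot scale")
        d2_cond = d2_cond / scale_value
    D2 = squareform(d2_cond)
    np.fill_diagonal(D2, 0.0)
    return SquaredDistances(line_ids=X.line_ids, values=D2, scale=scale,
                            scale_value=scale_value)


def gaussian_kernel(
    d2: SquaredDistances | np.ndarray,
    h: float,
    line_ids: list | None = None,
) -> KernelMatrix:
    """Gaussian kernel ``K = exp(-h d²)`` with unit diagonal."""
    if h <= 0:
        raise ValueError(f"bandwidth h must be positive, got {h}")
    if isinstance(d2, SquaredDistances):
        line_ids = d2.line_ids
        scale_value = d2.scale_value
        D2 = d2.values
    else:
        D2 = np.asarray(d2, dtype=float)
        scale_value = None
        if line_ids is None:
            line_ids = [f"L{i}" for i in range(D2.shape[0])]
    if not np.allclose(D2, D2.T, atol=1e-10):
        raise ValueError("squared-distance matrix must be symmetric")
    if np.any(D2 < 0) or np.any(np.diag(D2) != 0.0):
        raise ValueError("squared distances must be nonnegative with zero diagonal")
    K = np.exp(-h * D2)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(line_ids=line_ids, values=K, kind="gaussian",
                        bandwidth=float(h), distance_scale=scale_value)


def add_jitter(K: np.ndarray, rel: float = JITTER_REL) -> np.ndarray:
    """Return K with ``rel * mean(diag)`` added to the diagonal (logged once)."""
    eps = rel * float(np.diag(K).mean())
    logger.info("adding diagonal jitter %.3e to kernel", eps)
    return K + eps * np.eye(K.shape[0])


def _profiled_loglik(lam: np.ndarray, Vt_y: np.ndarray, Vt_1: np.ndarray,
                     ratio: float, n: int) -> float:
    """Log marginal likelihood of y ~ N(1μ, σ²(r K + I)) with μ, σ² profiled."""
    c = ratio * lam + 1.0
    w1, wy = Vt_1 / c, Vt_y / c
    denom = float(Vt_1 @ w1)
    mu_hat = float(Vt_1 @ wy) / denom
    e = Vt_y - mu_hat * Vt_1
    sig2 = float(e @ (e / c)) / n
    if sig2 <= 0 or not np.isfinite(sig2):
        return -np.inf
    return -0.5 * (n * np.log(sig2) + np.log(c).sum() + n)


def estimate_bandwidth(
    y,
    d2: SquaredDistances | np.ndarray,
    grid: list | np.ndarray,
    ratio_grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Grid-search the Gaussian-kernel bandwidth by profiled marginal likelihood.

    For each ``h`` in ``grid``, builds ``K(h) = exp(-h d²)`` and evaluates the
    log marginal likelihood of the single-environment kernel regression with
    the intercept profiled out by GLS, the residual variance profiled
    analytically, and the signal-to-noise ratio σu²/σε² maximized over an
    inner grid.  Returns ``(h_star, criterion_trace)``; the trace has one
    entry per grid point.  Deterministic given its inputs.

    A criterion flat across the whole grid (no genetic signal to localize
    ``h``) still returns the arg-max but emits a ``UserWarning``.
    """
    yv = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    if np.isnan(yv).any():
        raise ValueError("estimate_bandwidth requires a complete phenotype vector")
    D2 = d2.values if isinstance(d2, SquaredDistances) else np.asarray(d2, float)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("bandwidth grid is empty")
    if np.any(grid <= 0):
        raise ValueError("bandwidth grid must be positive")
    if ratio_grid is None:
        ratio_grid = np.logspace(-2, 2, 21)
    n = yv.size
    ones = np.ones(n)
    trace = np.empty(grid.size)
    for gi, h in enumerate(grid):
        K = np.exp(-h * D2)
        np.fill_diagonal(K, 1.0)
        lam, V = np.linalg.eigh((K + K.T) / 2.0)
        lam = np.clip(lam, 0.0, None)
        Vt_y, Vt_1 = V.T @ yv, V.T @ ones
        trace[gi] = max(
            _profiled_loglik(lam, Vt_y, Vt_1, r, n) for r in ratio_grid
        )
    if not np.isfinite(trace).any():
        raise ValueError("bandwidth criterion is non-finite at every grid point")
    span = float(np.nanmax(trace) - np.nanmin(trace[np.isfinite(trace)]))
    if grid.size > 1 and span < 1e-6 * max(1.0, abs(float(np.nanmax(trace)))):
        warnings.warn(
            "bandwidth criterion is flat across the grid (no genetic signal); "
            "returning the first arg-max", UserWarning, stacklevel=2,
        )
    h_star = float(grid[int(np.nanargmax(trace))])
    return h_star, trace
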