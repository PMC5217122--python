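"""CV2 cross-validation: partition generation, per-environment prediction
ability, and the multi-model / multi-kernel experiment harness.

Under CV2 every line stays observed in at least one environment and is
predicted in the environments where it was masked out; prediction ability is
the Pearson correlation between predicted and observed values over the test
cells of each environment, averaged over random 70/30 partitions.

Note on standardization: per-environment Pearson r is invariant to
per-environment affine maps, so standardizing on the full data (the
default) versus on training cells only cannot change the
reported correlations; ``standardize_on="train"`` exists for strict
no-leakage pipelines and is taint-tested.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bayes_core import (
    McmcConfig,
    PhenotypeTable,
    default_multi_prior,
    default_single_prior,
    fit_multi,
    fit_single,
)
from .kernels import KernelMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CvPartition",
    "PredictionSummary",
    "CvResult",
    "make_cv2_partitions",
    "pearson_by_env",
    "run_cv_experiment",
    "percent_change",
]


@dataclass
class CvPartition:
    """One train/test split of the phenotype grid (True = training cell)."""

    mask: np.ndarray
    partition_id: int
    seed: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)


@dataclass
class PredictionSummary:
    """Mean/SD of Pearson r per (model, method, environment) over partitions."""

    table: pd.DataFrame  # columns: model, method, environment, mean_r, sd_r, n_partitions

    def __post_init__(self) -> None:
        need = {"model", "method", "environment", "mean_r", "sd_r", "n_partitions"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"summary table missing columns {sorted(missing)}")
        r = self.table["mean_r"].dropna()
        if ((r < -1 - 1e-12) | (r > 1 + 1e-12)).any():
            raise ValueError("mean_r outside [-1, 1]")
        sd = self.table["sd_r"].dropna()
        if (sd < 0).any():
            raise ValueError("negative sd_r")

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "PredictionSummary":
        g = (long.groupby(["model", "method", "environment"], sort=True)["r"]
             .agg(mean_r="mean", sd_r=lambda s: s.std(ddof=1),
                  n_partitions="count")
             .reset_index())
        return cls(table=g)


@dataclass
class CvResult:
    summary: PredictionSummary
    long: pd.DataFrame          # partition, model, method, environment, r
    failures: list              # (partition_id, model, method, message)


def make_cv2_partitions(table: PhenotypeTable, train_fraction: float = 0.7,
                        n_partitions: int = 50,
                        seed: int | None = None) -> list[CvPartition]:
    """Random CV2 partitions of the observed cells.

    Each partition marks ``round(train_fraction * n_observed)`` cells as
    training, uniformly at random, subject to every line keeping at least
    one training cell among its observed cells.  Repair of an uncovered
    line moves one of its test cells to training and compensates by moving
    a training cell from a maximally covered line to test, preserving the
    exact split size.  Deterministic given ``seed``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    obs = table.observed
    n, m = obs.shape
    eligible = np.argwhere(obs)
    n_cells = eligible.shape[0]
    n_train = int(round(train_fraction * n_cells))
    # m = 1 is the single-environment 70/30 scheme: held-out lines have no
    # training cell by construction, so the coverage rule does not apply
    enforce_coverage = m > 1
    if enforce_coverage and n_train < n:
        raise ValueError(
            f"train_fraction {train_fraction} gives {n_train} training cells, "
            f"fewer than the {n} lines that must each keep one")
    rng = np.random.default_rng(seed)
    parts: list[CvPartition] = []
    for pid in range(n_partitions):
        sel = rng.choice(n_cells, size=n_train, replace=False)
        mask = np.zeros((n, m), bool)
        mask[eligible[sel, 0], eligible[sel, 1]] = True
        if enforce_coverage:
            _repair_coverage(mask, obs, rng)
        parts.append(CvPartition(mask=mask, partition_id=pid,
                                 seed=seed if seed is not None else -1))
    return parts


def _repair_coverage(mask: np.ndarray, obs: np.ndarray,
                     rng: np.random.Generator, max_rounds: int = 10_000) -> None:
    """In-place repair so every line with observed cells keeps >=1 training cell."""
    for _ in range(max_rounds):
        train_per_line = (mask & obs).sum(axis=1)
        has_obs = obs.any(axis=1)
        bare = np.where(has_obs & (train_per_line == 0))[0]
        if bare.size == 0:
            return
        i = bare[0]
        cand = np.where(obs[i] & ~mask[i])[0]
        j = rng.choice(cand)
        mask[i, j] = True
        # compensate from a line with the most training cells (keep its count >= 2)
        counts = (mask & obs).sum(axis=1)
        counts[i] = -1
        donors = np.where(counts >= 2)[0]
        if donors.size == 0:  # cannot compensate; tolerate +1 training cell
            logger.warning("CV2 repair could not rebalance partition size")
            continue
        d = donors[np.argmax(counts[donors])]
        dj = rng.choice(np.where(mask[d] & obs[d])[0])
        mask[d, dj] = False
    raise RuntimeError("CV2 coverage repair did not converge")


def pearson_by_env(obs: PhenotypeTable, pred: np.ndarray,
                   partition: CvPartition) -> dict:
    """Pearson r between predictions and observations on each environment's
    test cells.  Zero-variance test cells yield ``nan`` (flagged, logged),
    never a silent 0."""
    pred = np.asarray(pred, float)
    if pred.shape != obs.values.shape:
        raise ValueError("prediction grid shape mismatch")
    test = obs.observed & ~partition.mask
    out = {}
    for j, env in enumerate(obs.env_ids):
        sel = test[:, j]
        if sel.sum() < 3:
            raise ValueError(f"environment {env!r} has <3 test cells")
        a, b = obs.values[sel, j], pred[sel, j]
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            logger.warning("undefined correlation in environment %r "
                           "(zero variance); recording NaN", env)
            out[env] = float("nan")
            continue
        out[env] = float(sps.pearsonr(a, b)[0])
    return out


def _child_seed(base: int, *keys) -> int:
    # crc32, not hash(): str hashing is salted per process and would break
    # run-to-run determinism
    parts = [int(base) & 0x7FFFFFFF]
    parts += [zlib.crc32(str(k).encode()) & 0x7FFFFFFF for k in keys]
    return int(np.random.SeedSequence(parts).generate_state(1)[0])


def run_cv_experiment(
    table: PhenotypeTable,
    kernels: dict,
    models=(1, 2, 3),
    partitions: list[CvPartition] | None = None,
    mcmc: McmcConfig | None = None,
    n_partitions: int = 50,
    train_fraction: float = 0.7,
    seed: int = 0,
    standardize_on: str = "full",
    single_prior_df: float = 5.0,
) -> CvResult:
    """Fit every (model, kernel method, partition) combination and summarize.

    ``kernels`` maps method name (e.g. ``"gblup"``, ``"gk"``) to a
    :class:`KernelMatrix`.  For each partition the test cells are set
    unobserved, the model is fitted on the training cells only, test cells
    are predicted from the posterior mean of μ + u (+ f), and per-environment
    Pearson correlations are recorded.  Individual fit failures are logged
    and excluded from aggregation, never silently dropped.
    """
    if mcmc is None:
        mcmc = McmcConfig()
    if not kernels:
        raise ValueError("need at least one kernel method")
    for name, K in kernels.items():
        if list(K.line_ids) != list(table.line_ids):
            kernels[name] = K.reorder(table.line_ids)
    models = sorted(set(int(x) for x in models))
    if any(x not in (1, 2, 3) for x in models):
        raise ValueError("models must be a subset of {1, 2, 3}")
    if table.m == 1 and set(models) - {1}:
        raise ValueError("multi-environment models need m >= 2")

    if standardize_on == "full":
        work_full = table.standardize(on="full")
    elif standardize_on != "train":
        raise ValueError(f"unknown standardize_on {standardize_on!r}")

    if partitions is None:
        partitions = make_cv2_partitions(table, train_fraction, n_partitions, seed)

    rows, failures = [], []
    for part in partitions:
        if standardize_on == "train":
            work = table.standardize(on="train", train_mask=part.mask)
        else:
            work = work_full
        train = work.mask_cells(part.mask)
        for model in models:
            for method, K in kernels.items():
                cseed = _child_seed(mcmc.seed, part.partition_id, model, method)
                cfg = McmcConfig(iterations=mcmc.iterations, burn_in=mcmc.burn_in,
                                 thin=mcmc.thin, seed=cseed,
                                 store_effects=False)
                try:
                    pred = _fit_predict(train, K, model, cfg, single_prior_df)
                    r_by_env = pearson_by_env(work, pred, part)
                except Exception as exc:  # noqa: BLE001 - recorded, not hidden
                    logger.warning("fit failed (partition=%d model=%d method=%s): %s",
                                   part.partition_id, model, method, exc)
                    failures.append((part.partition_id, model, method, str(exc)))
                    continue
                for env, r in r_by_env.items():
                    rows.append({"partition": part.partition_id, "model": model,
                                 "method": method, "environment": env, "r": r})
    long = pd.DataFrame(rows, columns=["partition", "model", "method",
                                       "environment", "r"])
    if long["r"].isna().any():
        logger.warning("%d undefined correlations excluded from aggregation",
                       int(long["r"].isna().sum()))
        long = long.dropna(subset=["r"]).reset_index(drop=True)
    summary = PredictionSummary.from_long(long)
    return CvResult(summary=summary, long=long, failures=failures)


def _fit_predict(train: PhenotypeTable, K: KernelMatrix, model: int,
                 mcmc: McmcConfig, single_prior_df: float) -> np.ndarray:
    if model == 1:
        pred = np.empty_like(train.values)
        for j in range(train.m):
            ysub = train.env(j)
            prior = default_single_prior(ysub.values[ysub.observed], K,
                                         df=single_prior_df)
            cfg = McmcConfig(iterations=mcmc.iterations, burn_in=mcmc.burn_in,
                             thin=mcmc.thin, seed=mcmc.seed + j)
            chain = fit_single(ysub, K, prior, cfg)
            pred[:, j] = chain.predicted[:, 0]
        return pred
    prior = default_multi_prior(train.m)
    chain = fit_multi(train, K, include_f=(model == 3), prior=prior, mcmc=mcmc)
    return chain.predicted


def percent_change(summary: PredictionSummary,
                   comparisons: list | None = None) -> pd.DataFrame:
    """Integer percent change 100·(r_A − r_B)/r_B per environment.

    Default comparisons: GK vs GBLUP within each model, model 2 vs model 1
    and model 3 vs model 2 within each method.  Rounding is half away from
    zero, matching the presentation of the published comparison tables.
    """
    t = summary.table
    if comparisons is None:
        comparisons = []
        methods = sorted(t["method"].unique())
        model_set = sorted(t["model"].unique())
        if {"gblup", "gk"} <= set(methods):
            for mod in model_set:
                comparisons.append(((mod, "gk"), (mod, "gblup"),
                                    f"model{mod}: gk vs gblup"))
        for meth in methods:
            if {1, 2} <= set(model_set):
                comparisons.append(((2, meth), (1, meth),
                                    f"{meth}: model2 vs model1"))
            if {2, 3} <= set(model_set):
                comparisons.append(((3, meth), (2, meth),
                                    f"{meth}: model3 vs model2"))
    rows = []
    idx = t.set_index(["model", "method", "environment"])["mean_r"]
    for (ma, mea), (mb, meb), label in comparisons:
        for env in sorted(t["environment"].unique()):
            try:
                ra = idx.loc[(ma, mea, env)]
                rb = idx.loc[(mb, meb, env)]
            except KeyError:
                continue
            pct = 100.0 * (ra - rb) / rb
            rows.append({"comparison": label, "environment": env,
                         "percent": _round_half_away(pct)})
    return pd.DataFrame(rows, columns=["comparison", "environment", "percent"])


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))
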