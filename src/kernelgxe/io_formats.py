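"""File formats: markers, phenotypes, kernels, partitions, chains, summaries,
YAML run configuration and the JSON run manifest.

Everything is plain text (CSV/TSV, YAML, JSON).  Line ordering is taken from
the phenotype file; marker and kernel inputs are reordered to match and a
set mismatch is an error unless ``allow_subset`` is passed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes_core import McmcConfig, PhenotypeTable, PosteriorChain
from .crossval import CvPartition, PredictionSummary
from .kernels import KernelMatrix, MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_config",
    "read_markers",
    "write_markers",
    "read_phenotypes",
    "write_phenotypes",
    "read_kernel",
    "write_kernel",
    "write_partitions",
    "read_partitions",
    "write_chain",
    "write_summary",
    "read_summary",
    "write_summary_display",
    "align_to_lines",
    "write_manifest",
]

_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "phenotypes", "markers", "kernel", "dialect", "models", "methods",
    "bandwidth", "maf_threshold", "impute_mode", "distance_scale",
    "iterations", "burn_in", "thin", "seed", "partitions", "train_fraction",
    "standardize_on", "out_dir", "log_level", "prior",
}


@dataclass
class RunConfig:
    """Validated run configuration for the CLI front end."""

    phenotypes: str | None = None
    markers: str | None = None
    kernel: str | None = None
    dialect: str = "long"
    models: list = field(default_factory=lambda: [1, 2, 3])
    methods: list = field(default_factory=lambda: ["gblup", "gk"])
    bandwidth: object = "auto"
    maf_threshold: float = 0.05
    impute_mode: str = "mean"
    distance_scale: str = "median"
    iterations: int = 30_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    partitions: int = 50
    train_fraction: float = 0.7
    standardize_on: str = "full"
    out_dir: str = "results"
    log_level: str = "INFO"
    prior: dict = field(default_factory=dict)

    def mcmc(self) -> McmcConfig:
        return McmcConfig(iterations=self.iterations, burn_in=self.burn_in,
                          thin=self.thin, seed=self.seed)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a YAML run config; unknown keys and missing files are errors."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**doc)
    for key in ("phenotypes", "markers", "kernel"):
        p = getattr(cfg, key)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config {key} file does not exist: {p}")
    return cfg


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def read_markers(path, dialect: str = "auto") -> MarkerMatrix:
    """Read a raw genotype table (CSV/TSV with a line_id first column, or
    PLINK RAW with whitespace separation and FID/IID/... meta columns)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if dialect == "auto":
        first = header.split()[:2]
        dialect = "plink_raw" if first[:2] == ["FID", "IID"] else "csv"
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        meta = [c for c in df.columns if c in _PLINK_META]
        line_ids = df["IID"].astype(str).tolist()
        df = df.drop(columns=meta)
    else:
        sep = "\t" if "\t" in header else ","
        df = pd.read_csv(path, sep=sep, na_values=["NA", ""])
        line_ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    vals = df.to_numpy(dtype=float)
    return MarkerMatrix(line_ids=line_ids, marker_ids=list(df.columns),
                        values=vals, is_standardized=False)


def write_markers(mm: MarkerMatrix, path) -> None:
    df = pd.DataFrame(mm.values, columns=mm.marker_ids)
    df.insert(0, "line_id", mm.line_ids)
    df.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path, dialect: str = "long") -> PhenotypeTable:
    """Assemble the line-by-environment grid with first-appearance ordering.

    ``long`` expects columns (line_id, env_id, value); absent cells are
    unobserved and duplicate (line, env) pairs are an error.  ``wide``
    expects one column per environment with NA marking unobserved cells.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty phenotype file: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""])
    if df.empty:
        raise ValueError(f"phenotype file has no rows: {path}")
    if dialect == "long":
        need = ["line_id", "env_id", "value"]
        if list(df.columns[:3]) != need:
            raise ValueError(f"long phenotype file needs columns {need}, "
                             f"got {list(df.columns[:3])}")
        df["line_id"] = df["line_id"].astype(str)
        df["env_id"] = df["env_id"].astype(str)
        dup = df.duplicated(subset=["line_id", "env_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["line_id", "env_id"]].tolist()
            raise ValueError(f"duplicate phenotype cell for (line, env) = {tuple(pair)}")
        if not pd.api.types.is_numeric_dtype(df["value"]):
            bad = df.loc[pd.to_numeric(df["value"], errors="coerce").isna()
                         & df["value"].notna(), "value"]
            raise ValueError(f"non-numeric phenotype value(s): {bad.head(3).tolist()}")
        line_ids = list(dict.fromkeys(df["line_id"]))
        env_ids = list(dict.fromkeys(df["env_id"]))
        n, m = len(line_ids), len(env_ids)
        values = np.full((n, m), np.nan)
        li = {l: i for i, l in enumerate(line_ids)}
        ei = {e: j for j, e in enumerate(env_ids)}
        for l, e, v in df[["line_id", "env_id", "value"]].itertuples(index=False):
            if not np.isnan(v):
                values[li[l], ei[e]] = v
        return PhenotypeTable(line_ids, env_ids, values)
    if dialect == "wide":
        line_ids = df.iloc[:, 0].astype(str).tolist()
        env_ids = list(df.columns[1:])
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        return PhenotypeTable(line_ids, env_ids, values)
    raise ValueError(f"unknown phenotype dialect {dialect!r}")


def write_phenotypes(table: PhenotypeTable, path, dialect: str = "long") -> None:
    if dialect == "long":
        rows = []
        for i, l in enumerate(table.line_ids):
            for j, e in enumerate(table.env_ids):
                if table.observed[i, j]:
                    rows.append((l, e, table.values[i, j]))
        pd.DataFrame(rows, columns=["line_id", "env_id", "value"]).to_csv(
            path, index=False)
    elif dialect == "wide":
        vals = np.where(table.observed, table.values, np.nan)
        df = pd.DataFrame(vals, columns=table.env_ids)
        df.insert(0, "line_id", table.line_ids)
        df.to_csv(path, index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown phenotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def write_kernel(K: KernelMatrix, path, metadata_path=None) -> None:
    """Kernel CSV with line_ids as header and first column; optional JSON
    sidecar with kind/bandwidth/distance_scale."""
    df = pd.DataFrame(K.values, columns=K.line_ids)
    df.insert(0, "line_id", K.line_ids)
    df.to_csv(path, index=False, float_format="%.17g")
    if metadata_path is not None:
        meta = {"kind": K.kind, "bandwidth": K.bandwidth,
                "distance_scale": K.distance_scale,
                "mean_diagonal": float(np.diag(K.values).mean())}
        Path(metadata_path).write_text(json.dumps(meta, indent=2))


def read_kernel(path, metadata_path=None) -> KernelMatrix:
    df = pd.read_csv(path)
    line_ids = df.iloc[:, 0].astype(str).tolist()
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    kind, bw, ds = "custom", None, None
    if metadata_path is not None and Path(metadata_path).exists():
        meta = json.loads(Path(metadata_path).read_text())
        kind = meta.get("kind", "custom")
        bw = meta.get("bandwidth")
        ds = meta.get("distance_scale")
    vals = (vals + vals.T) / 2.0  # round-trip symmetry at full precision
    if kind == "gaussian":
        np.fill_diagonal(vals, 1.0)
    return KernelMatrix(line_ids=line_ids, values=vals, kind=kind,
                        bandwidth=bw, distance_scale=ds)


def align_to_lines(line_ids: list, K: KernelMatrix,
                   allow_subset: bool = False) -> KernelMatrix:
    """Reorder a kernel to the phenotype line ordering.

    By default the line sets must match exactly; with ``allow_subset`` the
    kernel may cover a superset of the phenotype lines.
    """
    have, want = set(K.line_ids), set(line_ids)
    if not want <= have:
        raise ValueError(f"kernel is missing lines {sorted(want - have)[:5]}")
    if not allow_subset and have != want:
        raise ValueError("kernel covers extra lines; pass allow_subset=True to subset")
    return K.reorder(list(line_ids))


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def write_partitions(parts: list[CvPartition], table: PhenotypeTable,
                     out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in parts:
        df = pd.DataFrame(p.mask.astype(int), columns=table.env_ids)
        df.insert(0, "line_id", table.line_ids)
        path = out_dir / f"part_{p.partition_id:03d}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths


def read_partitions(out_dir, seed: int = -1) -> list[CvPartition]:
    paths = sorted(Path(out_dir).glob("part_*.csv"))
    parts = []
    for path in paths:
        df = pd.read_csv(path)
        pid = int(path.stem.split("_")[1])
        parts.append(CvPartition(mask=df.iloc[:, 1:].to_numpy(dtype=bool),
                                 partition_id=pid, seed=seed))
    return parts


# ---------------------------------------------------------------------------
# chains and summaries
# ---------------------------------------------------------------------------

def write_chain(chain: PosteriorChain, csv_path, summary_path=None) -> None:
    """Flat CSV of the retained scalar draws (UE/FE as upper triangles) and
    an optional JSON file of posterior means/SDs/ESS."""
    pd.DataFrame(chain.scalar_draws()).to_csv(csv_path, index=False)
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(chain.summary(), indent=2))


def write_summary(summary: PredictionSummary, path) -> None:
    summary.table.to_csv(path, index=False, float_format="%.17g")


def read_summary(path) -> PredictionSummary:
    df = pd.read_csv(path)
    return PredictionSummary(table=df)


def write_summary_display(summary: PredictionSummary, path) -> None:
    """Human-readable pivot with '0.606 (0.037)'-style mean (SD) cells."""
    t = summary.table.copy()
    t["cell"] = [f"{m:.3f} ({s:.3f})" if np.isfinite(s) else f"{m:.3f} (--)"
                 for m, s in zip(t["mean_r"], t["sd_r"])]
    pivot = t.pivot_table(index="environment", columns=["model", "method"],
                          values="cell", aggfunc="first")
    pivot.to_csv(path)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def write_manifest(out_dir, config: RunConfig | None = None,
                   seed: int | None = None, extra: dict | None = None) -> Path:
    """JSON manifest with seed, library versions and config hash — enough to
    re-run any result file."""
    from importlib.metadata import version

    import scipy

    manifest = {
        "seed": seed if seed is not None else (config.seed if config else None),
        "config_hash": config.digest() if config else None,
        "config": config.__dict__ if config else None,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "click": version("click"),
        },
    }
    if extra:
        manifest.update(extra)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("wrote run manifest %s", path)
    return path
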