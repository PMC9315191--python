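"""Delimited-file readers/writers, analysis configuration and reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ClusteredDataset
from .model import FitResult

__all__ = [
    "AnalysisConfig",
    "load_config",
    "read_dataset",
    "write_dataset",
    "model_selection_report",
    "write_fit_json",
]


@dataclass
class AnalysisConfig:
    """Column mapping and model grid for an analysis run."""

    time_col: str = "time"
    status_col: str = "status"
    cluster_col: str = "cluster"
    x_cols: list[str] = field(default_factory=list)
    x_time_cols: list[str] = field(default_factory=list)
    standardise: list[str] = field(default_factory=list)
    structures: list[str] = field(default_factory=lambda: ["megh1", "megh2", "gh"])
    baselines: list[str] = field(default_factory=lambda: ["pgw", "loglogistic"])
    random_effects: list[str] = field(default_factory=lambda: ["normal"])
    seed: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


def load_config(path) -> AnalysisConfig:
    """Load an analysis configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return AnalysisConfig.from_dict(d)


def read_dataset(path, config: AnalysisConfig, sep=None) -> ClusteredDataset:
    """Read a delimited file into a validated :class:`ClusteredDataset`.

    Continuous covariates named in ``config.standardise`` are centred and
    scaled to unit standard deviation.  Cluster labels may be arbitrary;
    they are recoded in order of first appearance (mapping retained on
    the dataset).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    needed = (
        [config.time_col, config.status_col, config.cluster_col]
        + list(config.x_cols)
        + list(config.x_time_cols)
    )
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path.name}: {missing}")
    status = df[config.status_col]
    if not status.isin([0, 1]).all():
        raise ValueError(f"column {config.status_col!r} must contain only 0/1")
    time = df[config.time_col].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(time) | (time <= 0))
    if bad.size:
        raise ValueError(
            f"column {config.time_col!r} must be positive; offending rows "
            f"(0-based): {bad[:10].tolist()}"
        )
    work = df.copy()
    for col in config.standardise:
        v = work[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"cannot standardise constant column {col!r}")
        work[col] = (v - v.mean()) / sd
    return ClusteredDataset(
        time=time,
        status=status.to_numpy(),
        cluster=df[config.cluster_col].to_numpy(),
        X=work[list(config.x_cols)].to_numpy(dtype=float),
        X_time=work[list(config.x_time_cols)].to_numpy(dtype=float),
        x_names=list(config.x_cols),
        x_time_names=list(config.x_time_cols),
    )


def write_dataset(data: ClusteredDataset, path, config: AnalysisConfig | None = None):
    """Write a dataset back to CSV with full numeric precision."""
    cfg = config or AnalysisConfig()
    df = data.to_frame(cfg.time_col, cfg.status_col, cfg.cluster_col)
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    # pandas' default float formatting is shortest-round-trip exact
    df.to_csv(path, sep=sep, index=False)
    return path


def model_selection_report(
    fits: dict[str, FitResult], re_pvalues: dict[str, float] | None = None
) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending, ties broken by fewer parameters).

    ``re_pvalues`` optionally attaches, per mixed model, the boundary-test
    p-value against its fixed-effects reduction.
    """
    converged = {k: f for k, f in fits.items() if f.converged}
    if not converged:
        raise ValueError("no converged fits to report")
    rows = []
    for label, f in converged.items():
        rows.append(
            {
                "model": label,
                "structure": f.structure.value,
                "loglik": f.loglik,
                "k": f.n_params,
                "aic": f.aic,
                "re_test_pvalue": (re_pvalues or {}).get(label, np.nan),
            }
        )
    report = pd.DataFrame(rows).sort_values(
        ["aic", "k"], kind="stable", ignore_index=True
    )
    report["delta_aic"] = report["aic"] - report["aic"].iloc[0]
    return report


def write_fit_json(fit: FitResult, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(fit.to_dict(), indent=2))
    return path
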