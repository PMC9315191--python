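"""Clustered right-censored survival data container."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClusteredDataset"]


@dataclass
class ClusteredDataset:
    """Right-censored survival data grouped into clusters.

    Parameters
    ----------
    time : (n,) array of strictly positive observed times (min of event and
        censoring time).
    status : (n,) array of 0/1 vital-status indicators (1 = event observed).
    cluster : (n,) array of cluster labels (any hashable type); internally
        recoded to integer codes ``0..r-1`` in order of first appearance.
    X : (n, p) hazard-scale design matrix (may have ``p = 0``).
    X_time : (n, p~) time-scale design matrix (may have ``p~ = 0``);
        typically a subset of the columns of ``X``.
    """

    time: np.ndarray
    status: np.ndarray
    cluster: np.ndarray
    X: np.ndarray
    X_time: np.ndarray
    x_names: list[str] = field(default_factory=list)
    x_time_names: list[str] = field(default_factory=list)
    cluster_labels: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.status = np.asarray(self.status).ravel()
        n = self.time.shape[0]
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = np.flatnonzero(~np.isfinite(self.time) | (self.time <= 0))
            raise ValueError(
                f"observed times must be positive and finite; offending rows: "
                f"{bad[:10].tolist()}"
            )
        if not np.isin(self.status, [0, 1]).all():
            raise ValueError("status indicators must be 0 (censored) or 1 (event)")
        self.status = self.status.astype(float)

        labels = np.asarray(self.cluster).ravel()
        if labels.shape[0] != n:
            raise ValueError("cluster labels must match the number of rows")
        uniq, codes = np.unique(labels, return_inverse=True)
        # recode in order of first appearance so cluster 0 is the first seen
        first_pos = np.full(len(uniq), n, dtype=int)
        np.minimum.at(first_pos, codes, np.arange(n))
        order = np.argsort(first_pos, kind="stable")
        remap = np.empty(len(uniq), dtype=int)
        remap[order] = np.arange(len(uniq))
        self.cluster = remap[codes]
        self.cluster_labels = uniq[order]

        self.X = self._as_matrix(self.X, n, "X")
        self.X_time = self._as_matrix(self.X_time, n, "X_time")
        if not self.x_names:
            self.x_names = [f"x{k + 1}" for k in range(self.X.shape[1])]
        if not self.x_time_names:
            self.x_time_names = [f"xt{k + 1}" for k in range(self.X_time.shape[1])]

        self._check_full_rank()

    @staticmethod
    def _as_matrix(M, n, name):
        if M is None:
            return np.empty((n, 0))
        M = np.asarray(M, dtype=float)
        if M.ndim == 1:
            M = M.reshape(-1, 1)
        if M.shape[0] != n:
            raise ValueError(f"{name} must have one row per observation")
        if not np.all(np.isfinite(M)):
            raise ValueError(f"{name} contains non-finite entries")
        return M

    def _check_full_rank(self):
        # collinearity among uncensored rows breaks identifiability of the
        # regression coefficients
        rows = self.status == 1
        for M, name in ((self.X, "X"), (self.X_time, "X_time")):
            if M.shape[1] and rows.sum() >= M.shape[1]:
                if np.linalg.matrix_rank(M[rows]) < M.shape[1]:
                    warnings.warn(
                        f"design matrix {name} restricted to uncensored rows "
                        "is not full column rank; coefficients may not be "
                        "identifiable",
                        stacklevel=3,
                    )

    # -- basic summaries -----------------------------------------------
    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def r(self) -> int:
        """Number of clusters."""
        return int(self.cluster.max()) + 1 if self.n else 0

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster, minlength=self.r)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def censoring_rate(self) -> float:
        return 1.0 - self.status.mean()

    def subset(self, rows) -> "ClusteredDataset":
        rows = np.asarray(rows)
        return ClusteredDataset(
            time=self.time[rows],
            status=self.status[rows],
            cluster=np.asarray(self.cluster_labels)[self.cluster[rows]],
            X=self.X[rows],
            X_time=self.X_time[rows],
            x_names=list(self.x_names),
            x_time_names=list(self.x_time_names),
        )

    def resample_clusters(self, cluster_ids) -> "ClusteredDataset":
        """Concatenate the given clusters (with multiplicity) into a new
        dataset, relabelling repeats as distinct clusters."""
        rows, labels = [], []
        for k, c in enumerate(cluster_ids):
            idx = np.flatnonzero(self.cluster == c)
            rows.append(idx)
            labels.append(np.full(idx.size, k))
        rows = np.concatenate(rows)
        return ClusteredDataset(
            time=self.time[rows],
            status=self.status[rows],
            cluster=np.concatenate(labels),
            X=self.X[rows],
            X_time=self.X_time[rows],
            x_names=list(self.x_names),
            x_time_names=list(self.x_time_names),
        )

    def to_frame(
        self,
        time_col: str = "time",
        status_col: str = "status",
        cluster_col: str = "cluster",
    ) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                time_col: self.time,
                status_col: self.status.astype(int),
                cluster_col: np.asarray(self.cluster_labels)[self.cluster],
            }
        )
        for k, name in enumerate(self.x_names):
            df[name] = self.X[:, k]
        for k, name in enumerate(self.x_time_names):
            if name not in df.columns:
                df[name] = self.X_time[:, k]
        return df
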