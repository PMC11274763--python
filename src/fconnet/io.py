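"""Readers, writers and pipeline configuration.

All on-disk formats are delimited text:

- atlas TSV: label, x, y, z, network
- time-series TSV: T rows x N columns, header = ROI labels
- manifest TSV: subject_id, group, file (paths relative to the manifest)
- connectivity TSV: square matrix with ROI-label header and index
- metric tables: long-format TSV (subject, group, sparsity, metric, node, value)
- node export for glass-brain viewers: label, x, y, z, size, color
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .atlas import AtlasSpec
from .cohort import SubjectTimeSeries
from .connectivity import ConnectivityMatrix
from .metrics import NullConfig


class IOError_(ValueError):
    """Raised on malformed or inconsistent input files."""


def write_atlas(atlas: AtlasSpec, path: str | os.PathLike) -> str:
    df = pd.DataFrame(
        {
            "label": atlas.labels,
            "x": atlas.coords[:, 0],
            "y": atlas.coords[:, 1],
            "z": atlas.coords[:, 2],
            "network": atlas.networks,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return os.fspath(path)


def read_atlas(path: str | os.PathLike) -> AtlasSpec:
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x", "y", "z", "network"}
    missing = required - set(df.columns)
    if missing:
        raise IOError_(f"atlas file {path}: missing column(s) {sorted(missing)}")
    return AtlasSpec(
        tuple(df["label"].astype(str)),
        tuple(df["network"].astype(str)),
        df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def read_timeseries(
    path: str | os.PathLike, subject_id: str, group: str, atlas: AtlasSpec | None = None
) -> SubjectTimeSeries:
    df = pd.read_csv(path, sep="\t")
    if atlas is not None:
        if df.shape[1] != atlas.n_rois:
            raise IOError_(
                f"{path}: {df.shape[1]} ROI columns, atlas has {atlas.n_rois}"
            )
        if list(df.columns) != list(atlas.labels):
            raise IOError_(f"{path}: column header does not match atlas labels")
    data = df.to_numpy(dtype=float)
    if np.isnan(data).any():
        raise IOError_(f"{path}: missing values in time series")
    return SubjectTimeSeries(subject_id, group, data)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "file"}
    missing = required - set(df.columns)
    if missing:
        raise IOError_(f"manifest {path}: missing column(s) {sorted(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise IOError_(f"manifest {path}: duplicate subject id(s) {sorted(set(dup))}")
    return df


def read_cohort(
    manifest_path: str | os.PathLike, atlas: AtlasSpec | None = None
) -> list[SubjectTimeSeries]:
    """Load every subject listed in a manifest (round-trips write_cohort)."""
    manifest = read_manifest(manifest_path)
    base = os.path.dirname(os.fspath(manifest_path))
    return [
        read_timeseries(os.path.join(base, row.file), row.subject_id, row.group, atlas)
        for row in manifest.itertuples()
    ]


def write_matrix(cm: ConnectivityMatrix, path: str | os.PathLike, labels=None) -> str:
    labels = list(labels) if labels is not None else [f"node_{i:03d}" for i in range(cm.n_rois)]
    pd.DataFrame(cm.values, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g"
    )
    return os.fspath(path)


def read_matrix(path: str | os.PathLike, subject_id: str = "", group: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(df.to_numpy(dtype=float), subject_id=subject_id, group=group)


def write_edge_list(graph_adjacency: np.ndarray, labels, path: str | os.PathLike) -> str:
    """Edge list (i-label, j-label) for external viewers."""
    ii, jj = np.nonzero(np.triu(graph_adjacency, k=1))
    pd.DataFrame({"source": [labels[i] for i in ii], "target": [labels[j] for j in jj]}).to_csv(
        path, sep="\t", index=False
    )
    return os.fspath(path)


def write_node_export(comparison: pd.DataFrame, path: str | os.PathLike) -> str:
    """Glass-brain-viewer node file from a nodal comparison table:
    label, x, y, z, size (|t|), color (t)."""
    out = comparison[["label", "x", "y", "z"]].copy()
    out["size"] = comparison["t"].abs()
    out["color"] = comparison["t"]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return os.fspath(path)


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; one seed governs all randomness."""

    manifest: str
    atlas: str
    outdir: str
    sparsity: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.501, 0.05), 2))
    edge_rank: str = "signed"
    null: NullConfig = field(default_factory=NullConfig)
    stats_mode: str = "fdr05"
    stats_metric: str = "clustering"
    louvain_restarts: int = 10
    nca_beta: float | None = None
    nca_kernel_width: float = 1.0
    nca_max_iter: int = 200
    seed: int = 0

    def validate(self) -> None:
        for p in (self.manifest, self.atlas):
            if not os.path.exists(p):
                raise IOError_(f"input file does not exist: {p}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sparsity"] = [float(s) for s in self.sparsity]
        return d

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        null = NullConfig(**raw.pop("null", {}))
        if "sparsity" in raw:
            raw["sparsity"] = tuple(float(s) for s in raw["sparsity"])
        return cls(null=null, **raw)

    def to_yaml(self, path: str | os.PathLike) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return os.fspath(path)
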