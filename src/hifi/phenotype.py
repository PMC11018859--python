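"""Semi-supervised cell phenotyping.

Per-marker MFIs (nuclear or whole-cell, according to the marker's biology)
are clipped at the 99.7th percentile and min-max scaled to [0, 1], clustered
into 100 nodes by a 10x10 self-organizing map, the node codebooks are
metaclustered hierarchically, and a user-supplied node annotation maps every
cell to a phenotype label. Batches are clustered independently and merged at
the point of annotation to avoid batch effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage

from hifi.som import SelfOrganizingMap

__all__ = [
    "MarkerConfig",
    "NodeAnnotation",
    "ScalingParams",
    "scale_markers",
    "train_som",
    "assign_nodes",
    "metacluster_nodes",
    "annotate_cells",
    "phenotype_batch",
]


@dataclass
class MarkerConfig:
    """Which zone's MFI feeds clustering, per classification marker.

    ``zones`` maps marker name -> ``"nucleus"`` or ``"cell"``.
    """

    zones: dict[str, str]

    def __post_init__(self) -> None:
        bad = {m: z for m, z in self.zones.items() if z not in ("nucleus", "cell")}
        if bad:
            raise ValueError(f"zone must be 'nucleus' or 'cell': {bad}")

    @property
    def markers(self) -> list[str]:
        return list(self.zones)

    def columns(self) -> list[str]:
        return [f"mfi__{m}__{z}" for m, z in self.zones.items()]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerConfig":
        return cls(zones=yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.zones))


@dataclass
class NodeAnnotation:
    """Total mapping node id -> (metacluster id, cell-type label)."""

    metacluster: dict[int, int]
    labels: dict[int, str] = field(default_factory=dict)

    @classmethod
    def from_metaclusters(
        cls, node_to_meta: dict[int, int], meta_labels: dict[int, str]
    ) -> "NodeAnnotation":
        labels = {node: meta_labels[mc] for node, mc in node_to_meta.items()}
        return cls(metacluster=dict(node_to_meta), labels=labels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NodeAnnotation":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            metacluster={int(k): int(v) for k, v in data["metacluster"].items()},
            labels={int(k): str(v) for k, v in data["labels"].items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"metacluster": self.metacluster, "labels": self.labels})
        )


@dataclass
class ScalingParams:
    """Per-marker (min, clip value at the quantile) used for 0-1 scaling."""

    lo: np.ndarray
    hi: np.ndarray
    clip_quantile: float
    columns: list[str]

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        span = np.where(span > 0, span, 1.0)
        scaled = (np.minimum(X, self.hi) - self.lo) / span
        return np.clip(scaled, 0.0, 1.0)


def scale_markers(
    table: pd.DataFrame,
    config: MarkerConfig,
    clip_quantile: float = 0.997,
) -> tuple[np.ndarray, ScalingParams]:
    """Clip each classification marker at its 99.7th-percentile value and
    min-max scale to [0, 1].

    Quantiles use linear interpolation between order statistics. Constant
    markers scale to 0 with a warning. Returns the scaled matrix and the
    parameters for reuse on new data.
    """
    cols = config.columns()
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"markers missing from table: {missing}")
    if len(table) < 2:
        raise ValueError("need at least 2 cells")
    X = table[cols].to_numpy(float)
    lo = np.nanmin(X, axis=0)
    hi = np.nanquantile(X, clip_quantile, axis=0, method="linear")
    flat = hi <= lo
    if flat.any():
        warnings.warn(
            f"constant markers scaled to 0: {[cols[i] for i in np.flatnonzero(flat)]}",
            stacklevel=2,
        )
        hi = np.where(flat, lo + 1.0, hi)
        params = ScalingParams(lo, hi, clip_quantile, cols)
        scaled = params.transform(X)
        scaled[:, flat] = 0.0
        return scaled, params
    params = ScalingParams(lo, hi, clip_quantile, cols)
    return params.transform(X), params


def train_som(
    features: np.ndarray,
    grid: tuple[int, int] = (10, 10),
    seed: int = 0,
    epochs: int = 10,
) -> SelfOrganizingMap:
    """Train the 10x10 (by default) self-organizing map on scaled features."""
    som = SelfOrganizingMap(grid=grid, n_epochs=epochs, seed=seed)
    return som.fit(features)


def assign_nodes(model: SelfOrganizingMap, features: np.ndarray) -> np.ndarray:
    """Best-matching-unit node id per cell (Euclidean, ties -> lowest id)."""
    return model.predict(features)


def metacluster_nodes(
    model: SelfOrganizingMap, k: int, method: str = "average"
) -> dict[int, int]:
    """Agglomerative clustering of the node codebooks cut at ``k`` metaclusters.

    Returns node id -> metacluster id (1-based). Deterministic.
    """
    if model.codebook_ is None:
        raise RuntimeError("model is not fitted")
    n = len(model.codebook_)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == n:
        return {i: i + 1 for i in range(n)}
    Z = linkage(model.codebook_, method=method, metric="euclidean")
    flat = fcluster(Z, t=k, criterion="maxclust")
    return {i: int(flat[i]) for i in range(n)}


def annotate_cells(
    table: pd.DataFrame,
    node_ids: np.ndarray,
    annotation: NodeAnnotation,
) -> pd.DataFrame:
    """Attach node, metacluster, and cell-type columns to the cell table."""
    node_ids = np.asarray(node_ids)
    if len(node_ids) != len(table):
        raise ValueError("node_ids length must match table")
    present = set(np.unique(node_ids).tolist())
    missing = sorted(present - set(annotation.labels))
    if missing:
        raise ValueError(f"annotation missing for nodes: {missing}")
    out = table.copy()
    out["node_id"] = node_ids
    out["metacluster"] = [annotation.metacluster[int(n)] for n in node_ids]
    out["cell_type"] = [annotation.labels[int(n)] for n in node_ids]
    return out


def phenotype_batch(
    table: pd.DataFrame,
    config: MarkerConfig,
    meta_labels: dict[int, str],
    k: int,
    grid: tuple[int, int] = (10, 10),
    seed: int = 0,
    epochs: int = 10,
    clip_quantile: float = 0.997,
) -> tuple[pd.DataFrame, SelfOrganizingMap, NodeAnnotation]:
    """Scale -> SOM -> metacluster -> annotate, for one batch.

    Batches of an experiment are phenotyped independently with their own
    models and merged afterwards under a shared label vocabulary
    (``meta_labels``: metacluster id -> cell-type label).
    """
    X, _ = scale_markers(table, config, clip_quantile)
    som = train_som(X, grid=grid, seed=seed, epochs=epochs)
    nodes = assign_nodes(som, X)
    meta = metacluster_nodes(som, k)
    annotation = NodeAnnotation.from_metaclusters(meta, meta_labels)
    return annotate_cells(table, nodes, annotation), som, annotation
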