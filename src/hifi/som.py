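"""A seeded online self-organizing map on a rectangular grid.

The map follows the classic Kohonen update: for each training vector the
best-matching unit (BMU) is found by Euclidean distance and the codebook is
pulled toward the vector with a Gaussian neighborhood kernel whose width and
learning rate decay linearly over the training schedule. With features
scaled to [0, 1] (the phenotyping convention) the codebook stays inside the
unit cube. Fully deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SelfOrganizingMap"]


@dataclass
class SelfOrganizingMap:
    """Kohonen map with a (rows, cols) rectangular grid.

    Parameters
    ----------
    grid : (rows, cols) of the node lattice; 10x10 = 100 nodes by default.
    n_epochs : passes over the shuffled training data.
    sigma : (start, end) Gaussian neighborhood width in grid units.
    learning_rate : (start, end) step size, decayed linearly with sigma.
    seed : RNG seed for codebook init and shuffling.
    """

    grid: tuple[int, int] = (10, 10)
    n_epochs: int = 10
    sigma: tuple[float, float] = (5.0, 0.5)
    learning_rate: tuple[float, float] = (0.5, 0.01)
    seed: int = 0

    codebook_: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    quantization_error_: float = field(default=float("nan"), repr=False)

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    def _grid_coords(self) -> np.ndarray:
        rows, cols = self.grid
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap":
        X = np.asarray(X, np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2D (cells x markers)")
        n, d = X.shape
        if n < self.n_nodes:
            raise ValueError(f"need at least {self.n_nodes} samples, got {n}")
        rng = np.random.default_rng(self.seed)
        W = X[rng.choice(n, self.n_nodes, replace=False)].copy()
        coords = self._grid_coords()
        # pairwise squared grid distances between nodes, precomputed
        gd2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

        total = self.n_epochs * n
        step = 0
        s0, s1 = self.sigma
        l0, l1 = self.learning_rate
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            for i in order:
                frac = step / max(total - 1, 1)
                sig = s0 + (s1 - s0) * frac
                lr = l0 + (l1 - l0) * frac
                x = X[i]
                bmu = int(np.argmin(((W - x) ** 2).sum(1)))
                h = np.exp(-gd2[bmu] / (2.0 * sig * sig))
                W += (lr * h)[:, None] * (x - W)
                step += 1
        self.codebook_ = W
        bmus = self.predict(X)
        self.quantization_error_ = float(
            np.mean(np.linalg.norm(X - W[bmus], axis=1))
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Best-matching node id for each row (Euclidean; ties -> lowest id)."""
        if self.codebook_ is None:
            raise RuntimeError("map is not fitted")
        X = np.asarray(X, np.float64)
        if X.ndim != 2 or X.shape[1] != self.codebook_.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[-1] if X.ndim == 2 else '?'} does not "
                f"match codebook dimension {self.codebook_.shape[1]}"
            )
        d2 = ((X[:, None, :] - self.codebook_[None, :, :]) ** 2).sum(-1)
        return np.argmin(d2, axis=1)

    # persistence ----------------------------------------------------------

    def to_json(self, path: str | Path | None = None, extra: dict | None = None) -> dict:
        payload = {
            "grid": list(self.grid),
            "n_epochs": self.n_epochs,
            "sigma": list(self.sigma),
            "learning_rate": list(self.learning_rate),
            "seed": self.seed,
            "codebook": None if self.codebook_ is None else self.codebook_.tolist(),
            "quantization_error": self.quantization_error_,
        }
        if extra:
            payload.update(extra)
        if path is not None:
            Path(path).write_text(json.dumps(payload))
        return payload

    @classmethod
    def from_json(cls, source: dict | str | Path) -> "SelfOrganizingMap":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        som = cls(
            grid=tuple(source["grid"]),
            n_epochs=source["n_epochs"],
            sigma=tuple(source["sigma"]),
            learning_rate=tuple(source["learning_rate"]),
            seed=source["seed"],
        )
        if source.get("codebook") is not None:
            som.codebook_ = np.asarray(source["codebook"], float)
            som.quantization_error_ = source.get("quantization_error", float("nan"))
        return som
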