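"""Single-cell objects: overlap resolution, probability filtering, cell
expansion with zoned measurement masks, and per-cell measurements.

Nuclear detections (external label maps with per-object probabilities, or
the built-in watershed baseline) are turned into measured cells:

* overlapping detections are resolved by per-object interior distance maps —
  a contested pixel belongs to the object whose own Euclidean distance map
  is strictly greatest there (ties go to background);
* detections with probability < 0.5 are discarded;
* nuclei are expanded by 2.5 µm toward their nearest nucleus frontier,
  capped so that a cell is never larger than 1.5x its nucleus (farthest
  candidate pixels dropped first);
* four measurement zones per object: nucleus, cytoplasm (cell minus
  nucleus), whole cell, and a 1-px membrane ring on the cell boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure, segmentation
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from hifi.stack import ChannelImage, HyperplexStack
from hifi.regions import RegionSet

__all__ = [
    "LabelMap",
    "CellZones",
    "resolve_overlaps",
    "filter_by_probability",
    "expand_cells",
    "measure_cells",
    "baseline_watershed_segment",
]


@dataclass
class LabelMap:
    """Integer label grid (0 = background) with per-object probabilities."""

    labels: np.ndarray
    probabilities: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.probabilities = np.asarray(self.probabilities, float)
        n = int(self.labels.max()) if self.labels.size else 0
        if len(self.probabilities) != n:
            raise ValueError(
                f"{n} objects but {len(self.probabilities)} probabilities"
            )
        present = np.unique(self.labels)
        present = present[present > 0]
        if n and not np.array_equal(present, np.arange(1, n + 1)):
            raise ValueError("object ids must be dense from 1")

    @property
    def n_objects(self) -> int:
        return len(self.probabilities)


@dataclass
class CellZones:
    """Per-object measurement zones, encoded as two label grids.

    ``nuclei`` and ``cells`` share object ids; the zone masks of object k are
    ``nuclei == k`` (nucleus), ``cells == k`` (whole cell), their difference
    (cytoplasm), and a 1-px inner boundary ring of the cell (membrane).
    """

    nuclei: np.ndarray
    cells: np.ndarray
    pixel_size: float = 1.0
    membrane_width: int = 1
    probabilities: np.ndarray | None = None

    @property
    def n_objects(self) -> int:
        return int(max(self.nuclei.max(), self.cells.max()))

    def membrane(self) -> np.ndarray:
        """Label grid of the membrane rings (inner cell boundary pixels)."""
        ring = segmentation.find_boundaries(self.cells, mode="inner")
        for _ in range(self.membrane_width - 1):
            interior = self.cells > 0
            ring |= segmentation.find_boundaries(self.cells * ~ring, mode="inner") & interior
        return np.where(ring, self.cells, 0)


def resolve_overlaps(per_object_masks: list[np.ndarray], pixel_size: float = 1.0) -> LabelMap:
    """Resolve overlapping detections with per-object interior distance maps.

    Each pixel is assigned to the object whose Euclidean distance-to-own-
    background is strictly greatest there; pixels tying for the maximum go
    to background.
    """
    if not per_object_masks:
        raise ValueError("need at least one mask")
    shape = per_object_masks[0].shape
    best = np.zeros(shape, np.float64)
    second = np.zeros(shape, np.float64)
    winner = np.zeros(shape, np.int32)
    for k, m in enumerate(per_object_masks, start=1):
        m = np.asarray(m).astype(bool)
        if m.shape != shape:
            raise ValueError("masks must share shape")
        if not m.any():
            raise ValueError(f"mask {k} is empty")
        d = ndimage.distance_transform_edt(m)
        gt = d > best
        second = np.where(gt, best, np.maximum(second, d))
        best = np.where(gt, d, best)
        winner = np.where(gt, k, winner)
    labels = np.where((best > 0) & (best > second), winner, 0)
    # re-densify in case an object lost everywhere
    return _densify(labels, np.ones(len(per_object_masks)), pixel_size)[0]


def _densify(
    labels: np.ndarray, probabilities: np.ndarray, pixel_size: float
) -> tuple[LabelMap, dict[int, int]]:
    present = np.unique(labels)
    present = present[present > 0]
    mapping = {int(old): new for new, old in enumerate(present, start=1)}
    lut = np.zeros(int(labels.max()) + 1, labels.dtype if labels.size else np.int32)
    for old, new in mapping.items():
        lut[old] = new
    new_labels = lut[labels]
    new_probs = np.asarray([probabilities[old - 1] for old in present], float)
    return LabelMap(new_labels, new_probs, pixel_size), mapping


def filter_by_probability(
    lm: LabelMap, min_p: float = 0.5
) -> tuple[LabelMap, dict[int, int]]:
    """Drop objects with detection probability < ``min_p`` (default 0.5);
    ids are re-densified and the old->new id mapping returned."""
    keep = lm.probabilities >= min_p
    labels = lm.labels.copy()
    drop_ids = np.flatnonzero(~keep) + 1
    if drop_ids.size:
        labels[np.isin(labels, drop_ids)] = 0
    return _densify(labels, lm.probabilities, lm.pixel_size)


def filter_by_area(
    lm: LabelMap, min_nucleus_area_um2: float = 4.0
) -> tuple[LabelMap, dict[int, int]]:
    """Drop fragment nuclei smaller than ``min_nucleus_area_um2``."""
    areas = np.bincount(lm.labels.ravel(), minlength=lm.n_objects + 1)[1:]
    min_px = min_nucleus_area_um2 / lm.pixel_size**2
    labels = lm.labels.copy()
    drop = np.flatnonzero(areas < min_px) + 1
    if drop.size:
        labels[np.isin(labels, drop)] = 0
    return _densify(labels, lm.probabilities, lm.pixel_size)


def expand_cells(
    lm: LabelMap, radius_um: float = 2.5, max_area_ratio: float = 1.5
) -> CellZones:
    """Expand nuclei into cells (default 2.5 µm, capped at 1.5x nucleus area).

    Expansion pixels are assigned to the nearest nucleus (frontiers meet at
    the equidistant line, so cells stay disjoint) and, per object, the
    farthest candidate pixels are dropped first until
    ``area(cell) <= max_area_ratio * area(nucleus)``.
    """
    nuclei = lm.labels.astype(np.int32)
    if radius_um < 0:
        raise ValueError("radius must be >= 0")
    # round-half-up conversion of the radius to pixel units
    radius_px = radius_um / lm.pixel_size
    if radius_px == 0 or lm.n_objects == 0:
        return CellZones(nuclei, nuclei.copy(), lm.pixel_size, probabilities=lm.probabilities)

    dist, (iy, ix) = ndimage.distance_transform_edt(nuclei == 0, return_indices=True)
    cells = nuclei.copy()
    grow = (nuclei == 0) & (dist <= radius_px)
    cells[grow] = nuclei[iy[grow], ix[grow]]

    areas_nuc = np.bincount(nuclei.ravel(), minlength=lm.n_objects + 1)
    areas_cell = np.bincount(cells.ravel(), minlength=lm.n_objects + 1)
    caps = np.floor(max_area_ratio * areas_nuc).astype(np.int64)
    over = np.flatnonzero(areas_cell[1:] > caps[1:]) + 1
    for k in over:
        added = (cells == k) & (nuclei != k)
        idx = np.flatnonzero(added.ravel())
        d = dist.ravel()[idx]
        n_keep = int(caps[k] - areas_nuc[k])
        if n_keep <= 0:
            cells.ravel()[idx] = 0
            continue
        # drop the farthest candidate pixels first; ties broken by raster order
        order = np.lexsort((idx, d))
        cells.ravel()[idx[order[n_keep:]]] = 0
    return CellZones(nuclei, cells, lm.pixel_size, probabilities=lm.probabilities)


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return np.nan
    return min(1.0, 4.0 * np.pi * area / perimeter**2)


def measure_cells(
    stack: HyperplexStack,
    zones: CellZones,
    regions: RegionSet | None = None,
) -> pd.DataFrame:
    """Measure every cell: centroid, morphometrics, zoned MFIs, region distances.

    Returns a tidy table with one row per cell and columns
    ``mfi__<marker>__<zone>`` (zones: nucleus, cytoplasm, cell, membrane),
    ``dist__<region>`` (µm from the nucleus centroid to the nearest region
    boundary pixel) and ``in__<region>`` membership flags. Cells whose
    centroid falls in the ``excluded`` region are dropped. Empty zones (e.g.
    the membrane of a 1-px object) yield missing MFIs, not zeros.
    """
    if stack.shape != zones.nuclei.shape:
        raise ValueError("stack and zones must share frame")
    px = zones.pixel_size
    n = zones.n_objects
    membrane = zones.membrane()
    cytoplasm = np.where(zones.cells * (zones.nuclei == 0) > 0, zones.cells, 0)
    zone_labels = {
        "nucleus": zones.nuclei,
        "cytoplasm": cytoplasm,
        "cell": zones.cells,
        "membrane": membrane,
    }
    zone_counts = {
        z: np.bincount(lab.ravel(), minlength=n + 1)[1:] for z, lab in zone_labels.items()
    }

    rows: dict[str, np.ndarray] = {"cell_id": np.arange(1, n + 1)}
    # morphometrics
    nuc_props = {p.label: p for p in measure.regionprops(zones.nuclei)}
    cell_props = {p.label: p for p in measure.regionprops(zones.cells)}
    cy = np.full(n, np.nan)
    cx = np.full(n, np.nan)
    for name, props, lab in (("nucleus", nuc_props, zones.nuclei), ("cell", cell_props, zones.cells)):
        area = np.full(n, np.nan)
        perim = np.full(n, np.nan)
        circ = np.full(n, np.nan)
        for k in range(1, n + 1):
            p = props.get(k)
            if p is None:
                continue
            area[k - 1] = p.area * px**2
            perim[k - 1] = p.perimeter * px
            circ[k - 1] = _circularity(p.area, p.perimeter)
            if name == "nucleus":
                cy[k - 1], cx[k - 1] = p.centroid
        rows[f"{name}_area_um2"] = area
        rows[f"{name}_perimeter_um"] = perim
        rows[f"{name}_circularity"] = circ
    rows["y_um"] = cy * px
    rows["x_um"] = cx * px
    if zones.probabilities is not None:
        rows["probability"] = np.asarray(zones.probabilities, float)

    # zoned MFIs
    for marker in stack.marker_names:
        chan = stack.channel(marker).pixels.astype(np.float64)
        for zone, lab in zone_labels.items():
            sums = np.bincount(lab.ravel(), weights=chan.ravel(), minlength=n + 1)[1:]
            counts = zone_counts[zone]
            with np.errstate(invalid="ignore"):
                mfi = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            rows[f"mfi__{marker}__{zone}"] = mfi

    df = pd.DataFrame(rows)

    # region distances and membership
    if regions is not None:
        cent_px = np.column_stack([cy, cx])
        ok = np.isfinite(cent_px).all(axis=1)
        for label in regions.labels:
            rm = regions[label]
            dist_col = np.full(n, np.nan)
            member = np.zeros(n, bool)
            boundary = segmentation.find_boundaries(rm.mask, mode="inner")
            if boundary.any():
                bpts = np.column_stack(np.nonzero(boundary)).astype(float)
                tree = cKDTree(bpts)
                d, _ = tree.query(cent_px[ok])
                dist_col[ok] = d * px
            if rm.mask.any():
                ci = np.clip(np.round(cent_px[ok]).astype(int), 0, None)
                ci[:, 0] = np.minimum(ci[:, 0], rm.mask.shape[0] - 1)
                ci[:, 1] = np.minimum(ci[:, 1], rm.mask.shape[1] - 1)
                member[ok] = rm.mask[ci[:, 0], ci[:, 1]]
            df[f"dist__{label}"] = dist_col
            df[f"in__{label}"] = member
        if "excluded" in regions:
            df = df[~df["in__excluded"]].reset_index(drop=True)
    return df


def baseline_watershed_segment(
    dapi: ChannelImage,
    smoothing_sigma: float = 2.0,
    min_area_px: int = 20,
    min_distance_px: int = 5,
) -> LabelMap:
    """Threshold-based watershed nuclear segmentation (baseline detector).

    Otsu threshold on the smoothed DAPI, distance-transform maxima as seeds,
    watershed on the inverted distance map. All probabilities are 1.0.
    """
    img = ndimage.gaussian_filter(dapi.pixels.astype(np.float32), smoothing_sigma)
    if img.max() <= img.min():
        return LabelMap(np.zeros(dapi.shape, np.int32), np.zeros(0), dapi.pixel_size)
    fg = img > threshold_otsu(img)
    if not fg.any():
        return LabelMap(np.zeros(dapi.shape, np.int32), np.zeros(0), dapi.pixel_size)
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=min_distance_px, labels=fg)
    seeds = np.zeros(dapi.shape, np.int32)
    seeds[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-dist, seeds, mask=fg)
    sizes = np.bincount(labels.ravel())
    drop = np.flatnonzero(sizes < min_area_px)
    drop = drop[drop > 0]
    if drop.size:
        labels[np.isin(labels, drop)] = 0
    lm, _ = _densify(labels, np.ones(int(labels.max())), dapi.pixel_size)
    return lm


def write_cell_table(df: pd.DataFrame, path) -> None:
    """Export a cell table as CSV or Parquet (by extension)."""
    path = str(path)
    if path.endswith(".parquet"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".parquet"):
        return pd.read_parquet(path)
    return pd.read_csv(path)
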