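"""Region masks and derived tissue niches.

Base regions (lesion, tumor, brain, vessel, ECM, excluded artifacts) come
from a small supervised pixel classifier or are imported; derived niches are
reproducible morphological functions of the base masks:

* lesion context — lesion expanded 750 µm into the parenchyma,
* perivascular  — vessels expanded 15 µm (core removed),
* tumor border  — tumor–brain interface expanded 70 µm.

Mask clean-up uses per-region pixel thresholds (fragments removed before
holes are filled, which makes the operation idempotent): 20,000 px for the
lesion, 20 px for vessels, 4,000 px for tumor/brain, holes 50 / fragments
300 px for ECM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import measure
from sklearn.linear_model import LogisticRegression

from hifi.stack import HyperplexStack

__all__ = [
    "RegionMask",
    "RegionSet",
    "CLEANUP_THRESHOLDS",
    "classify_pixels",
    "clean_mask",
    "expand_region",
    "derive_border",
]

# per-region (min_hole_px, min_fragment_px) clean-up constants
CLEANUP_THRESHOLDS: dict[str, tuple[int, int]] = {
    "lesion": (20_000, 20_000),
    "vessel": (20, 20),
    "tumor": (4_000, 4_000),
    "brain": (4_000, 4_000),
    "ecm": (50, 300),
}


@dataclass
class RegionMask:
    mask: np.ndarray
    label: str
    pixel_size: float = 1.0
    provenance: str = "derived"  # {classifier, imported, derived}

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.provenance not in ("classifier", "imported", "derived"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class RegionSet:
    """Named region masks sharing one frame; the ``excluded`` mask is
    subtracted from every analysis that consumes the set."""

    masks: dict[str, RegionMask] = field(default_factory=dict)

    def add(self, rm: RegionMask) -> None:
        if rm.label in self.masks:
            raise ValueError(f"duplicate region label {rm.label!r}")
        if self.masks:
            ref = next(iter(self.masks.values()))
            if rm.mask.shape != ref.mask.shape:
                raise ValueError("region masks must share shape")
        self.masks[rm.label] = rm

    def __getitem__(self, label: str) -> RegionMask:
        return self.masks[label]

    def __contains__(self, label: str) -> bool:
        return label in self.masks

    @property
    def labels(self) -> list[str]:
        return list(self.masks)


# ---------------------------------------------------------------------------
# pixel classification


def _pixel_features(stack: HyperplexStack, channel_subset: list[str]) -> np.ndarray:
    """Per-pixel features: raw intensity plus Gaussian-smoothed at 2 scales."""
    feats = []
    for name in channel_subset:
        ch = stack.channel(name).pixels.astype(np.float32)
        feats.append(ch)
        feats.append(ndimage.gaussian_filter(ch, 2.0))
        feats.append(ndimage.gaussian_filter(ch, 8.0))
    return np.stack(feats, axis=-1)


def classify_pixels(
    stack: HyperplexStack,
    channel_subset: list[str],
    training_scribbles: np.ndarray,
    label: str = "region",
    seed: int = 0,
) -> RegionMask:
    """Binary pixel classification from sparse scribble annotations.

    ``training_scribbles`` is an int grid: 0 = unlabeled, 1 = positive,
    2 = negative. A logistic classifier on per-channel intensity features
    (raw + Gaussian-smoothed at two scales) predicts the full-frame mask.
    Deterministic given ``seed``.
    """
    scribbles = np.asarray(training_scribbles)
    if scribbles.shape != stack.shape:
        raise ValueError("scribbles must match the stack frame")
    pos = scribbles == 1
    neg = scribbles == 2
    if not pos.any() or not neg.any():
        raise ValueError("scribbles must cover at least one positive and one negative region")
    missing = [n for n in channel_subset if n not in stack.marker_names]
    if missing:
        raise ValueError(f"channels absent from stack: {missing}")

    feats = _pixel_features(stack, channel_subset)
    X = np.concatenate([feats[pos], feats[neg]])
    y = np.concatenate([np.ones(pos.sum()), np.zeros(neg.sum())])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(max_iter=500, random_state=seed)
    clf.fit((X - mu) / sd, y)
    flat = (feats.reshape(-1, feats.shape[-1]) - mu) / sd
    pred = clf.predict(flat).reshape(stack.shape).astype(bool)
    return RegionMask(pred, label, stack.pixel_size, provenance="classifier")


def import_mask(
    mask: np.ndarray, label: str, pixel_size: float = 1.0
) -> RegionMask:
    """Store an externally produced mask verbatim (provenance ``imported``)."""
    return RegionMask(np.asarray(mask) > 0, label, pixel_size, provenance="imported")


# ---------------------------------------------------------------------------
# morphology


def clean_mask(rm: RegionMask, min_hole_px: int, min_fragment_px: int) -> RegionMask:
    """Remove foreground fragments with area < ``min_fragment_px``, then fill
    enclosed background holes with area < ``min_hole_px``. Idempotent."""
    if min_hole_px < 0 or min_fragment_px < 0:
        raise ValueError("thresholds must be >= 0")
    mask = rm.mask.copy()
    if min_fragment_px > 0:
        lab, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            drop = np.flatnonzero(sizes < min_fragment_px) + 1
            if drop.size:
                mask[np.isin(lab, drop)] = False
    if min_hole_px > 0:
        lab, n = ndimage.label(~mask)
        if n:
            border = set(
                np.unique(
                    np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
                ).tolist()
            )
            sizes = np.bincount(lab.ravel())
            fill = [
                k for k in range(1, n + 1)
                if k not in border and sizes[k] < min_hole_px
            ]
            if fill:
                mask[np.isin(lab, fill)] = True
    return RegionMask(mask, rm.label, rm.pixel_size, provenance="derived")


def expand_region(
    rm: RegionMask, distance_um: float, subtract_core: bool = False, label: str | None = None
) -> RegionMask:
    """Dilate a mask by a Euclidean disk of radius ``distance_um``.

    ``subtract_core=True`` returns only the expansion band (e.g. the
    perivascular niche = 15 µm vessel expansion minus the vessel itself).
    """
    if distance_um < 0:
        raise ValueError("distance must be >= 0")
    radius_px = distance_um / rm.pixel_size
    if radius_px == 0 or not rm.mask.any():
        out = rm.mask.copy() if not subtract_core else np.zeros_like(rm.mask)
        return RegionMask(out, label or rm.label, rm.pixel_size, provenance="derived")
    dist = ndimage.distance_transform_edt(~rm.mask)
    out = dist <= radius_px
    if subtract_core:
        out &= ~rm.mask
    return RegionMask(out, label or rm.label, rm.pixel_size, provenance="derived")


def derive_border(
    tumor: RegionMask, brain: RegionMask, width_um: float = 70.0
) -> RegionMask:
    """Tumor–brain interface dilated by ``width_um`` (default 70 µm).

    The interface is the set of tumor pixels 8-adjacent to brain (a 1-px
    line for touching masks); non-touching masks yield an empty border.
    """
    if tumor.mask.shape != brain.mask.shape:
        raise ValueError("tumor and brain masks must share frame")
    struct = np.ones((3, 3), bool)
    interface = tumor.mask & ndimage.binary_dilation(brain.mask, structure=struct)
    rm = RegionMask(interface, "border", tumor.pixel_size, provenance="derived")
    if not interface.any():
        import warnings

        warnings.warn("tumor and brain masks do not touch; border is empty", stacklevel=2)
        return rm
    return expand_region(rm, width_um, label="border")


def build_region_set(
    base: dict[str, RegionMask],
    lesion_context_um: float = 750.0,
    perivascular_um: float = 15.0,
    border_um: float = 70.0,
    clean: bool = True,
) -> RegionSet:
    """Clean the base masks with the per-region constants and derive the
    compound niches (lesion_context, perivascular, border)."""
    rs = RegionSet()
    for name, rm in base.items():
        if clean and name in CLEANUP_THRESHOLDS:
            hole, frag = CLEANUP_THRESHOLDS[name]
            rm = clean_mask(rm, hole, frag)
            rm.label = name
        rs.add(rm)
    if "lesion" in rs:
        rs.add(expand_region(rs["lesion"], lesion_context_um, label="lesion_context"))
    if "vessel" in rs:
        rs.add(
            expand_region(rs["vessel"], perivascular_um, subtract_core=True, label="perivascular")
        )
    if "tumor" in rs and "brain" in rs:
        rs.add(derive_border(rs["tumor"], rs["brain"], border_um))
    return rs


# ---------------------------------------------------------------------------
# import / export


def write_mask_tiff(rm: RegionMask, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, rm.mask.astype(np.uint8))
    return path


def read_mask_tiff(path: str | Path, label: str, pixel_size: float = 1.0) -> RegionMask:
    return RegionMask(tifffile.imread(path) > 0, label, pixel_size, provenance="imported")


def mask_to_geojson(rm: RegionMask, path: str | Path | None = None) -> dict:
    """Export a mask as a QuPath-compatible GeoJSON FeatureCollection.

    Polygon coordinates are (x, y) in pixel units; holes are not traced
    (exterior contours only).
    """
    padded = np.pad(rm.mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    features = []
    for contour in contours:
        # (row, col) -> (x, y), undo padding
        xy = np.column_stack([contour[:, 1] - 1, contour[:, 0] - 1])
        if len(xy) < 3:
            continue
        coords = xy.tolist()
        if coords[0] != coords[-1]:
            coords.append(coords[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [coords]},
                "properties": {"classification": {"name": rm.label}},
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc


def geojson_to_mask(
    fc: dict | str | Path, shape: tuple[int, int], label: str, pixel_size: float = 1.0
) -> RegionMask:
    """Rasterise a GeoJSON FeatureCollection back into a binary mask."""
    from skimage.draw import polygon as draw_polygon

    if not isinstance(fc, dict):
        fc = json.loads(Path(fc).read_text())
    mask = np.zeros(shape, bool)
    for feat in fc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            continue
        ring = np.asarray(geom["coordinates"][0], float)
        rr, cc = draw_polygon(ring[:, 1], ring[:, 0], shape=shape)
        mask[rr, cc] = True
    return RegionMask(mask, label, pixel_size, provenance="imported")
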