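"""Synthetic fixtures with ground truth for every pipeline stage.

The generators emulate the study conditions end-to-end: multi-round
blob-nuclei images with known rigid/affine inter-round offsets and a smooth
autofluorescence field shared across channels; nuclei images with
ground-truth label maps (non-uniform internal staining, optional touching
pairs); marker tables drawn from latent phenotype mixtures; and marked point
patterns with controlled spatial structure (complete spatial randomness,
Neyman–Scott-style clustering, or segregated half-windows). Everything is
deterministic under a master seed, with per-component streams derived
stably, and ground truth is always emitted alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from hifi.align import PlanarTransform, _warp
from hifi.stack import ChannelImage, RoundStack
from hifi.cells import LabelMap

__all__ = [
    "FixtureSpec",
    "make_cyclic_rounds",
    "make_nuclei_image",
    "make_marker_table",
    "make_point_pattern",
]


@dataclass
class FixtureSpec:
    """Declarative description of a cyclic-imaging fixture."""

    seed: int = 0
    shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.325
    n_rounds: int = 3
    channels_per_round: int = 3
    transforms: list[PlanarTransform] | None = None  # true round->reference maps
    af_amplitude: float = 400.0
    af_scale_px: float = 120.0
    n_nuclei: int = 400
    nucleus_radius_px: tuple[float, float] = (6.0, 11.0)
    noise_photons: float = 30.0
    read_noise: float = 3.0
    marker_amplitude: float = 3000.0


def _smooth_field(shape, scale_px, amplitude, rng) -> np.ndarray:
    """Non-negative smooth random field (band-limited noise, normalized to [0, amplitude])."""
    coarse = rng.standard_normal((max(2, shape[0] // int(scale_px)) + 2,
                                  max(2, shape[1] // int(scale_px)) + 2))
    f = ndimage.zoom(coarse, (shape[0] / coarse.shape[0], shape[1] / coarse.shape[1]), order=3)
    f = f[: shape[0], : shape[1]]
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return amplitude * f


def _render_blobs(shape, centers, radii, amplitude, rng=None, nonuniform=False) -> np.ndarray:
    img = np.zeros(shape, np.float32)
    for i, ((y, x), r) in enumerate(zip(centers, radii)):
        half = int(3 * r)
        yi, xi = int(y), int(x)
        sl = np.s_[max(0, yi - half): yi + half + 1, max(0, xi - half): xi + half + 1]
        py, px = np.mgrid[sl]
        blob = np.exp(-((py - y) ** 2 + (px - x) ** 2) / (2 * (r / 2.0) ** 2))
        if nonuniform and rng is not None:
            # radial+angular modulation emulating non-uniform chromatin staining
            ang = np.arctan2(py - y, px - x)
            phase = rng.uniform(0, 2 * np.pi)
            blob *= 0.7 + 0.3 * np.cos(2 * ang + phase)
            blob = np.abs(blob)
        img[sl] += amplitude * blob
    return img


def make_cyclic_rounds(
    spec: FixtureSpec,
) -> tuple[list[RoundStack], RoundStack, dict]:
    """Simulate a cyclic-IF experiment with known inter-round transforms.

    Returns (rounds, af_round, ground_truth). Round 1 is the reference;
    every later round (and the autofluorescence round) is resampled from the
    reference scene by the inverse of its true transform, using the same
    bilinear interpolator the alignment applies, so that applying the true
    transform recovers the reference exactly up to interpolation. Ground
    truth carries the true transforms, the landmark (nucleus center)
    coordinates in every round's frame, and the autofluorescence field.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    shape = spec.shape
    margin = 40
    n = spec.n_nuclei
    centers = np.column_stack(
        [
            rng.uniform(margin, shape[0] - margin, n),
            rng.uniform(margin, shape[1] - margin, n),
        ]
    )
    radii = rng.uniform(*spec.nucleus_radius_px, n)
    dapi_scene = _render_blobs(shape, centers, radii, spec.marker_amplitude)
    af_field = _smooth_field(shape, spec.af_scale_px, spec.af_amplitude, rng)

    transforms = spec.transforms
    if transforms is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
        transforms = [PlanarTransform.identity()]
        for _ in range(spec.n_rounds - 1):
            transforms.append(
                PlanarTransform.rigid(
                    rng.uniform(-2, 2), tuple(rng.uniform(-25, 25, 2)), center
                )
            )
    if len(transforms) != spec.n_rounds:
        raise ValueError("one transform per round required")

    # marker scenes: each non-DAPI channel lights up a random nucleus subset
    def marker_scene(k_round: int, k_chan: int) -> np.ndarray:
        sub_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 2, k_round, k_chan])
        )
        pick = sub_rng.random(n) < 0.4
        return _render_blobs(shape, centers[pick], radii[pick] * 1.2, spec.marker_amplitude)

    def noisy(img: np.ndarray, sub_rng: np.random.Generator) -> np.ndarray:
        lam = np.clip(img, 0, None) / max(spec.noise_photons, 1e-9)
        shot = sub_rng.poisson(lam + 1.0) * spec.noise_photons - spec.noise_photons
        out = shot + sub_rng.normal(0, spec.read_noise, img.shape)
        return np.clip(out, 0, None).astype(np.float32)

    landmarks = {}
    rounds = []
    for k in range(spec.n_rounds):
        t = transforms[k]
        inv = t.inverse()
        chans = []
        for c in range(spec.channels_per_round):
            if c == 0:
                scene = dapi_scene + af_field * 0.5
                name = "DAPI"
            else:
                scene = marker_scene(k, c) + af_field
                name = f"M{k + 1}_{c}"
            moved = scene if k == 0 else _warp(scene, inv.linear, inv.translation)
            sub_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3, k, c]))
            chans.append(ChannelImage(noisy(moved, sub_rng), spec.pixel_size, name, k))
        rounds.append(RoundStack(chans, dapi_index=0))
        landmarks[k] = inv.apply_points(centers)
        frac_out = np.mean(
            (landmarks[k][:, 0] < 0)
            | (landmarks[k][:, 0] >= shape[0])
            | (landmarks[k][:, 1] < 0)
            | (landmarks[k][:, 1] >= shape[1])
        )
        if frac_out > 0.5:
            raise ValueError(f"transform for round {k + 1} pushes >50% of content out of frame")

    # AF round: unstained tissue imaged before round 1, its own placement
    af_t = PlanarTransform.rigid(
        rng.uniform(-1, 1),
        tuple(rng.uniform(-10, 10, 2)),
        ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0),
    )
    af_inv = af_t.inverse()
    af_chans = []
    for c in range(spec.channels_per_round):
        scene = dapi_scene + af_field * 0.5 if c == 0 else af_field
        moved = _warp(scene, af_inv.linear, af_inv.translation)
        sub_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4, c]))
        name = "DAPI" if c == 0 else f"AF_{c}"
        af_chans.append(ChannelImage(noisy(moved, sub_rng), spec.pixel_size, name, 0))
    af_round = RoundStack(af_chans, dapi_index=0)

    ground_truth = {
        "transforms": transforms,
        "af_transform": af_t,
        "landmarks": landmarks,
        "landmarks_reference": centers,
        "af_field": af_field,
        "nucleus_radii": radii,
    }
    return rounds, af_round, ground_truth


def make_nuclei_image(
    n: int,
    radius_range: tuple[float, float] = (6.0, 12.0),
    irregularity: float = 0.2,
    density: float = 0.05,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.5,
    max_tries: int = 20,
) -> tuple[ChannelImage, LabelMap]:
    """Blob nuclei with non-uniform internal intensity and ground-truth labels.

    ``density`` sets the minimum center spacing (high density permits
    touching nuclei, stressing watershed/overlap code). Raises after bounded
    retries if ``n`` nuclei cannot be packed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    r_hi = radius_range[1]
    # spacing that guarantees disjoint nuclei (incl. boundary wobble) at low
    # density, shrinking toward touching/overlapping contact as density grows
    full_spacing = 2.0 * r_hi * (1.0 + irregularity) + 2.0
    spacing = max(2.0, full_spacing * (1.0 - min(density * 5.0, 0.9)))
    for _ in range(max_tries):
        centers: list[tuple[float, float]] = []
        attempts = 0
        while len(centers) < n and attempts < 50 * n:
            cand = (
                rng.uniform(r_hi + 2, shape[0] - r_hi - 2),
                rng.uniform(r_hi + 2, shape[1] - r_hi - 2),
            )
            if all((cand[0] - y) ** 2 + (cand[1] - x) ** 2 >= spacing**2 for y, x in centers):
                centers.append(cand)
            attempts += 1
        if len(centers) == n:
            break
    else:
        raise RuntimeError(f"could not pack {n} nuclei at density {density}")

    radii = rng.uniform(*radius_range, n)
    labels = np.zeros(shape, np.int32)
    img = np.zeros(shape, np.float32)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for k, ((y, x), r) in enumerate(zip(centers, radii), start=1):
        ang = np.arctan2(yy - y, xx - x)
        wobble = 1.0 + irregularity * np.sin(3 * ang + rng.uniform(0, 2 * np.pi))
        dist = np.sqrt((yy - y) ** 2 + (xx - x) ** 2)
        inside = dist <= r * wobble
        labels[inside & (labels == 0)] = k
        profile = np.clip(1.0 - (dist / (r * 1.2)) ** 2, 0, None)
        phase = rng.uniform(0, 2 * np.pi)
        texture = 0.75 + 0.25 * np.cos(2 * ang + phase)
        img += 3000.0 * profile * texture * inside
    img += rng.normal(60, 5, shape).astype(np.float32)
    img = np.clip(img, 0, None)
    lm = LabelMap(labels, np.ones(n), pixel_size)
    return ChannelImage(img, pixel_size, "DAPI"), lm


def make_marker_table(
    n_cells: int,
    phenotype_centroids: np.ndarray,
    within_sd: float | np.ndarray,
    marker_names: list[str],
    seed: int = 0,
    weights: np.ndarray | None = None,
    zone: str = "cell",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw cells from a Gaussian phenotype mixture; MFIs clamped at 0.

    Returns (cell table fragment with ``mfi__<marker>__<zone>`` columns,
    true phenotype index per cell).
    """
    centroids = np.asarray(phenotype_centroids, float)
    if centroids.shape[1] != len(marker_names):
        raise ValueError("centroid dimension must equal marker count")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    k = len(centroids)
    p = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, float)
    true = rng.choice(k, n_cells, p=p / p.sum())
    X = centroids[true] + rng.normal(0.0, within_sd, (n_cells, centroids.shape[1]))
    X = np.clip(X, 0, None)
    df = pd.DataFrame(X, columns=[f"mfi__{m}__{zone}" for m in marker_names])
    df.insert(0, "cell_id", np.arange(1, n_cells + 1))
    return df, true


def make_point_pattern(
    process: str,
    n: int,
    types: list[str],
    composition: np.ndarray,
    window_um: tuple[float, float] = (1000.0, 1000.0),
    cluster_params: dict | None = None,
    seed: int = 0,
    image_id: str = "img0",
    group: str = "g0",
) -> tuple[pd.DataFrame, dict]:
    """Marked point patterns with controlled spatial structure.

    ``process``:

    * ``"csr"`` — homogeneous uniform placement (complete spatial randomness);
    * ``"clustered"`` — Neyman–Scott parent–offspring clusters;
      ``cluster_params``: ``n_parents`` (default 10), ``sd_um`` (default 30),
      ``shared_parents`` (default True: all types share parents, planting
      attraction; False: separate parents per type, planting segregation);
    * ``"segregated"`` — types confined to disjoint vertical strips separated
      by ``cluster_params['gap_um']`` (default 0).

    Returns (cell table fragment with x_um/y_um/cell_type, ground truth).
    """
    comp = np.asarray(composition, float)
    if len(comp) != len(types):
        raise ValueError("composition length must equal number of types")
    if not np.isclose(comp.sum(), 1.0):
        raise ValueError("composition must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    W, H = window_um
    counts = rng.multinomial(n, comp)
    truth: dict = {"process": process, "counts": dict(zip(types, counts.tolist()))}

    xs, ys, labels = [], [], []
    if process == "csr":
        for t, c in zip(types, counts):
            xs.append(rng.uniform(0, W, c))
            ys.append(rng.uniform(0, H, c))
            labels += [t] * c
    elif process == "clustered":
        cp = {"n_parents": 10, "sd_um": 30.0, "shared_parents": True, **(cluster_params or {})}
        shared = np.column_stack(
            [rng.uniform(0, W, cp["n_parents"]), rng.uniform(0, H, cp["n_parents"])]
        )
        truth["parents"] = {}
        for t, c in zip(types, counts):
            parents = (
                shared
                if cp["shared_parents"]
                else np.column_stack(
                    [rng.uniform(0, W, cp["n_parents"]), rng.uniform(0, H, cp["n_parents"])]
                )
            )
            truth["parents"][t] = parents
            assign = rng.integers(0, len(parents), c)
            pts = parents[assign] + rng.normal(0, cp["sd_um"], (c, 2))
            pts[:, 0] = np.clip(pts[:, 0], 0, W)
            pts[:, 1] = np.clip(pts[:, 1], 0, H)
            xs.append(pts[:, 0])
            ys.append(pts[:, 1])
            labels += [t] * c
    elif process == "segregated":
        gap = (cluster_params or {}).get("gap_um", 0.0)
        k = len(types)
        strip_w = (W - gap * (k - 1)) / k
        truth["strips"] = {}
        for i, (t, c) in enumerate(zip(types, counts)):
            x0 = i * (strip_w + gap)
            truth["strips"][t] = (x0, x0 + strip_w)
            xs.append(rng.uniform(x0, x0 + strip_w, c))
            ys.append(rng.uniform(0, H, c))
            labels += [t] * c
    else:
        raise ValueError(f"unknown process {process!r}")

    df = pd.DataFrame(
        {
            "image_id": image_id,
            "group": group,
            "x_um": np.concatenate(xs) if xs else np.zeros(0),
            "y_um": np.concatenate(ys) if ys else np.zeros(0),
            "cell_type": labels,
        }
    )
    return df, truth
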