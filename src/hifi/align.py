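"""Background subtraction, rigid/affine registration, and stack assembly.

Each imaging round of a cyclic-IF experiment is registered to the DAPI
channel of round 1 by minimising the squared intensity difference between
the reference and the transformed moving DAPI, over a coarse-to-fine image
pyramid with sub-pixel refinement. The estimated planar transform is then
applied to every channel of that round, one channel at a time, so the peak
working set never exceeds one full-resolution channel plus the reference.
Tissue autofluorescence, imaged before antibody labeling, is removed
pixel-by-pixel from each aligned channel (clamped at zero), except for
channels carrying endogenous signal (e.g. GFP) which are exempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation
from skimage.restoration import rolling_ball as _sk_rolling_ball
from skimage.transform import resize

from hifi.stack import ChannelImage, HyperplexStack, RoundStack

__all__ = [
    "PlanarTransform",
    "rolling_ball_subtract",
    "estimate_transform",
    "apply_transform",
    "subtract_autofluorescence",
    "align_experiment",
]


@dataclass
class PlanarTransform:
    """A rigid-body or affine mapping of moving coordinates into reference coordinates.

    ``matrix`` is 2x3 in homogeneous (row, col) convention:
    ``x_ref = A @ x_mov + t`` with ``A = matrix[:, :2]`` and ``t = matrix[:, 2]``.
    ``residual`` is the final mean squared intensity difference over the
    overlap region at full resolution.
    """

    mode: str
    matrix: np.ndarray
    residual: float = float("nan")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("matrix must be 2x3")
        if self.mode not in ("rigid", "affine"):
            raise ValueError("mode must be 'rigid' or 'affine'")
        if self.mode == "rigid":
            A = self.matrix[:, :2]
            if abs(np.linalg.det(A) - 1.0) > 1e-6:
                raise ValueError("rigid linear part must have det = +1")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("transform is singular")

    @classmethod
    def identity(cls, mode: str = "rigid") -> "PlanarTransform":
        return cls(mode, np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), 0.0)

    @classmethod
    def rigid(
        cls, angle_deg: float, shift: tuple[float, float], center: tuple[float, float] = (0.0, 0.0)
    ) -> "PlanarTransform":
        """Rotation by ``angle_deg`` about ``center`` followed by ``shift`` (row, col)."""
        th = math.radians(angle_deg)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        c = np.asarray(center, float)
        t = c + np.asarray(shift, float) - R @ c
        return cls("rigid", np.column_stack([R, t]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def inverse(self) -> "PlanarTransform":
        Ai = np.linalg.inv(self.linear)
        return PlanarTransform(self.mode, np.column_stack([Ai, -Ai @ self.translation]))

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """self after other: x -> self(other(x))."""
        A = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        mode = "rigid" if self.mode == other.mode == "rigid" else "affine"
        return PlanarTransform(mode, np.column_stack([A, t]))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (row, col) points into the reference frame."""
        pts = np.asarray(pts, float)
        return pts @ self.linear.T + self.translation

    def to_dict(self) -> dict:
        return {"mode": self.mode, "matrix": self.matrix.tolist(), "residual": self.residual}


# ---------------------------------------------------------------------------
# rolling-ball background subtraction


def rolling_ball_subtract(
    img: ChannelImage, ball_diameter_um: float = 75.0
) -> ChannelImage:
    """Subtract a rolling-ball background estimate (default ball diameter 75 µm).

    The diameter is converted to pixels via the image's pixel size. For
    large balls the background is estimated on a block-shrunk copy and
    interpolated back to full resolution (the standard acceleration for
    rolling-ball filters), which changes the estimate by far less than the
    photon noise floor. Output is clamped at zero.
    """
    if ball_diameter_um <= 0:
        raise ValueError("ball diameter must be positive")
    radius_px = 0.5 * ball_diameter_um / img.pixel_size
    if 2 * radius_px < 2:
        raise ValueError(
            f"ball diameter {ball_diameter_um} µm is below 2 px at "
            f"{img.pixel_size} µm/px"
        )
    data = img.pixels.astype(np.float64)
    shrink = max(1, int(radius_px // 16))
    if shrink > 1:
        small = data[::shrink, ::shrink]
        bg_small = _sk_rolling_ball(small, radius=radius_px / shrink)
        bg = resize(bg_small, data.shape, order=1, mode="edge", anti_aliasing=False)
        # interpolation may slightly overshoot; a background estimate must
        # never exceed the image or the subtraction would clip real signal
        bg = np.minimum(bg, data)
    else:
        bg = _sk_rolling_ball(data, radius=radius_px)
    out = np.clip(data - bg, 0, None)
    return img.with_pixels(out)


# ---------------------------------------------------------------------------
# transform estimation


def _warp(moving: np.ndarray, A: np.ndarray, t: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample ``moving`` into the reference frame of transform (A, t).

    ``output[x_ref] = moving(A^-1 (x_ref - t))`` with bilinear interpolation.
    """
    Ai = np.linalg.inv(A)
    return ndimage.affine_transform(
        moving, Ai, offset=-Ai @ t, order=order, cval=cval, mode="constant",
        output=np.float32 if moving.dtype != np.float64 else np.float64,
    )


def _params_to_At(params: np.ndarray, mode: str, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if mode == "rigid":
        th, tr, tc = params
        A = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        t = center + np.array([tr, tc]) - A @ center
    else:
        a11, a12, a21, a22, tr, tc = params
        A = np.array([[1.0 + a11, a12], [a21, 1.0 + a22]])
        t = center + np.array([tr, tc]) - A @ center
    return A, t


def _ssd_residuals(
    params: np.ndarray,
    mode: str,
    ref: np.ndarray,
    mov: np.ndarray,
    mask: np.ndarray,
    center: np.ndarray,
) -> np.ndarray:
    A, t = _params_to_At(params, mode, center)
    warped = _warp(mov, A, t)
    return ((warped - ref) * mask).ravel()


def _pyramid(img: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Gaussian pyramid, levels[0] = full resolution."""
    levels = [img.astype(np.float32)]
    for _ in range(n_levels - 1):
        sm = ndimage.gaussian_filter(levels[-1], 1.0)
        levels.append(sm[::2, ::2].copy())
    return levels


def estimate_transform(
    reference_dapi: ChannelImage,
    moving_dapi: ChannelImage,
    mode: str = "rigid",
    max_iter: int = 100,
    tol: float = 1e-4,
    refine_max_dim: int = 1024,
) -> PlanarTransform:
    """Estimate the planar transform aligning ``moving_dapi`` onto ``reference_dapi``.

    Minimises the squared intensity difference between the reference and the
    transformed moving channel over a coarse-to-fine pyramid (depth
    ``ceil(log2(min_dim / 64))``), with a phase-correlation translation
    initialiser at the coarsest level and Levenberg–Marquardt-style
    refinement at each level. Convergence when the parameter update falls
    below ``tol`` pixel-equivalents or after ``max_iter`` function
    evaluations per level.

    Pyramid levels whose smaller dimension exceeds ``refine_max_dim`` carry
    the coarser level's solution upward (translations doubled) without a
    further optimisation pass: the sub-pixel solution converges well below
    resampling accuracy by then, and a full-resolution pass would dominate
    runtime on whole-slide images for no measurable gain. Set
    ``refine_max_dim`` to the image size to force refinement at every level.
    """
    if mode not in ("rigid", "affine"):
        raise ValueError("mode must be 'rigid' or 'affine'")
    if reference_dapi.shape != moving_dapi.shape:
        raise ValueError("reference and moving images must share shape")
    if not np.isclose(reference_dapi.pixel_size, moving_dapi.pixel_size):
        raise ValueError("reference and moving images must share pixel size")

    ref = reference_dapi.pixels.astype(np.float32)
    mov = moving_dapi.pixels.astype(np.float32)
    if ref.std() == 0 or mov.std() == 0:
        raise ValueError("constant image: no gradient signal to register on")

    min_dim = min(ref.shape)
    n_levels = max(1, math.ceil(math.log2(min_dim / 64))) + 1
    ref_pyr = _pyramid(ref, n_levels)
    mov_pyr = _pyramid(mov, n_levels)

    # coarsest-level translation initialiser
    shift, _, _ = phase_cross_correlation(
        ref_pyr[-1], mov_pyr[-1], upsample_factor=10, normalization=None
    )
    if mode == "rigid":
        params = np.array([0.0, shift[0], shift[1]])
        x_scale = np.array([0.01, 1.0, 1.0])
    else:
        params = np.array([0.0, 0.0, 0.0, 0.0, shift[0], shift[1]])
        x_scale = np.array([0.01, 0.01, 0.01, 0.01, 1.0, 1.0])

    for lvl in range(n_levels - 1, -1, -1):
        r, m = ref_pyr[lvl], mov_pyr[lvl]
        if min(r.shape) > refine_max_dim:
            if lvl > 0:
                params = params * (
                    np.array([1.0, 2.0, 2.0])
                    if mode == "rigid"
                    else np.array([1.0, 1.0, 1.0, 1.0, 2.0, 2.0])
                )
            continue
        center = (np.array(r.shape, float) - 1) / 2.0
        # weight by the warped footprint at the incoming parameters and drop a
        # border margin, so out-of-frame fill does not bias the fit; the mask
        # stays fixed during refinement (updates are sub-pixel by then)
        A0, t0 = _params_to_At(params, mode, center)
        mask = (_warp(np.ones_like(m), A0, t0) > 0.999).astype(np.float32)
        b = max(1, min(r.shape) // 32)
        mask[:b], mask[-b:], mask[:, :b], mask[:, -b:] = 0, 0, 0, 0
        scale = r.std() or 1.0
        max_nfev = max_iter if lvl > 1 else (25 if lvl == 1 else 8)
        res = optimize.least_squares(
            _ssd_residuals,
            params,
            args=(mode, r / scale, m / scale, mask, center),
            method="trf",
            x_scale=x_scale,
            xtol=tol,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=max_nfev,
            diff_step=1e-3,
        )
        params = res.x
        if lvl > 0:  # translations double when moving to the finer level
            if mode == "rigid":
                params = params * np.array([1.0, 2.0, 2.0])
            else:
                params = params * np.array([1.0, 1.0, 1.0, 1.0, 2.0, 2.0])

    center = (np.array(ref.shape, float) - 1) / 2.0
    A, t = _params_to_At(params, mode, center)
    warped = _warp(mov, A, t)
    wmask = _warp(np.ones_like(mov), A, t)
    overlap = wmask > 0.999
    residual = float(np.mean((warped[overlap] - ref[overlap]) ** 2)) if overlap.any() else float("nan")
    if mode == "rigid":
        # renormalise against floating-point drift in the rotation block
        th = math.atan2(A[1, 0], A[0, 0])
        A = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return PlanarTransform(mode, np.column_stack([A, t]), residual)


def apply_transform(
    channel: ChannelImage, t: PlanarTransform, fill: float = 0.0
) -> ChannelImage:
    """Resample one channel into the reference frame (bilinear, one channel at a time)."""
    warped = _warp(channel.pixels.astype(np.float32), t.linear, t.translation, cval=fill)
    return channel.with_pixels(np.clip(warped, 0, None))


def subtract_autofluorescence(
    channel: ChannelImage, af_channel_aligned: ChannelImage, scale: float = 1.0
) -> ChannelImage:
    """Pixel-by-pixel autofluorescence removal: ``max(channel - scale*af, 0)``."""
    if channel.shape != af_channel_aligned.shape:
        raise ValueError("channel and autofluorescence image differ in shape")
    out = np.clip(
        channel.pixels.astype(np.float64) - scale * af_channel_aligned.pixels, 0, None
    )
    return channel.with_pixels(out)


@dataclass
class AlignmentResult:
    stack: HyperplexStack
    transforms: list[PlanarTransform] = field(default_factory=list)
    af_transform: PlanarTransform | None = None


def align_experiment(
    rounds: list[RoundStack],
    af_round: RoundStack | None = None,
    af_map: dict[str, str] | None = None,
    skip_af_channels: set[str] | None = None,
    mode: str = "rigid",
    keep_dapi: str = "first",
    af_scale: float = 1.0,
    force: bool = False,
) -> AlignmentResult:
    """Register all rounds to round-1 DAPI, warp every channel, remove autofluorescence.

    Round 1 is the reference. For every later round the DAPI channel
    estimates the transform, which is then applied to each channel of that
    round in turn (one resident channel at a time). When an
    autofluorescence round is supplied it is aligned like any other round
    and subtracted channel-by-channel according to ``af_map``
    (channel name -> AF channel name); channels listed in
    ``skip_af_channels`` (e.g. endogenous GFP) are warped but never
    subtracted.

    ``keep_dapi``: ``"first"`` keeps only the round-1 DAPI in the output;
    ``"all"`` keeps every round's DAPI (disambiguated).
    """
    if not rounds:
        raise ValueError("need at least one round")
    shapes = {r.shape for r in rounds}
    if len(shapes) != 1:
        raise ValueError("all rounds must share shape")
    skip = set(skip_af_channels or ())
    reference = rounds[0].dapi

    if af_round is not None:
        if af_map is None:
            raise ValueError("af_map required when af_round is given")
        missing = {
            c.channel_name
            for r in rounds
            for c in r.channels
            if c.channel_name not in af_map
            and c.channel_name not in skip
            and c is not r.dapi
        }
        if missing:
            raise ValueError(f"af_map does not cover channels: {sorted(missing)}")

    # align the AF round first (round 0 in acquisition order)
    af_aligned: dict[str, np.ndarray] = {}
    af_transform: PlanarTransform | None = None
    if af_round is not None:
        af_transform = estimate_transform(reference, af_round.dapi, mode=mode)
        for ch in af_round.channels:
            af_aligned[ch.channel_name] = apply_transform(ch, af_transform).pixels

    out_channels: list[ChannelImage] = []
    names: list[str] = []
    transforms: list[PlanarTransform] = []
    errors: list[str] = []
    for k, rnd in enumerate(rounds):
        if k == 0:
            t = PlanarTransform.identity(mode)
        else:
            try:
                t = estimate_transform(reference, rnd.dapi, mode=mode)
            except Exception as exc:  # noqa: BLE001 - reported per round
                errors.append(f"round {k + 1}: {exc}")
                if not force:
                    raise RuntimeError(
                        f"registration failed for round {k + 1}: {exc}"
                    ) from exc
                t = PlanarTransform.identity(mode)
        transforms.append(t)
        for i, ch in enumerate(rnd.channels):
            is_dapi = i == rnd.dapi_index
            if is_dapi and keep_dapi == "first" and k > 0:
                continue
            warped = ch if k == 0 else apply_transform(ch, t)
            if (
                af_round is not None
                and not is_dapi
                and ch.channel_name not in skip
            ):
                af_name = af_map[ch.channel_name]  # type: ignore[index]
                af_img = warped.with_pixels(af_aligned[af_name])
                warped = subtract_autofluorescence(warped, af_img, scale=af_scale)
            warped.round_index = k
            out_channels.append(warped)
            names.append(ch.channel_name)

    stack = HyperplexStack(channels=out_channels)
    return AlignmentResult(stack=stack, transforms=transforms, af_transform=af_transform)
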