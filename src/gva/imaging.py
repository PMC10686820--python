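"""Synthetic tip images and recovery of colony positions from images.

This module closes the loop *image → positions → estimate*.  A renderer
draws a gel-filled tip as seen by a calibrated camera — cone silhouette,
dark colony discs, optional tilt and sensor noise — and emits the ground
truth alongside, so the whole pipeline can be validated without laboratory
images.  The recovery side finds the tip outline and apex, then detects
colonies by multi-scale blob detection and converts their centres to axial
millimetres from the apex.

Colony size in real tips shrinks as density grows (self-limiting growth,
which conveniently prevents overlap); the renderer reproduces this with the
stated rule ``r = r0 · (1 + density/d0)^(-1/3)`` without claiming a
mechanism.  When the smallest rendered colony spans fewer than 2 px the
image carries a resolution warning — the same physics that costs a
low-resolution camera its upper dynamic range.

Optics profiles: ``canon`` (6.6 µm/px, mirrorless + macro) and ``iphone12``
(13.7 µm/px, phone + clip-on macro).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw as skdraw
from skimage import feature, filters, measure
from skimage.util import img_as_float

from .estimator import CfuEstimate, ColonySet, estimate_cfu
from .geometry import ConeGeometry

__all__ = [
    "OpticsProfile",
    "OPTICS_PROFILES",
    "SyntheticTipImage",
    "TipSegmentation",
    "SegmentationResult",
    "SegmentationError",
    "colony_radius_um",
    "generate_tip_image",
    "segment_tip",
    "detect_colonies",
    "image_to_estimate",
]

# rendered intensity levels (fraction of full scale)
BACKGROUND_LEVEL = 0.85
CONE_LEVEL = 0.60
COLONY_LEVEL = 0.15

#: axial window analysed by each segmentation routine level, as a fraction
#: of the tip length from the apex; level 5 additionally caps at 30 colonies
WINDOW_FRACTIONS = {1: 1.0, 2: 0.5, 3: 0.2, 4: 0.1, 5: 0.05}
LEVEL5_MAX_COLONIES = 30


class SegmentationError(RuntimeError):
    """No usable tip silhouette was found in the image."""


@dataclass(frozen=True)
class OpticsProfile:
    """Camera calibration and noise model for rendering/recovery.

    ``pixel_size_um`` is the physical size of one pixel at the object plane;
    ``noise_sd`` is additive Gaussian intensity noise (fraction of full
    scale); ``rotation_jitter_deg`` bounds the random tip tilt drawn at
    render time.
    """

    pixel_size_um: float
    noise_sd: float = 0.0
    background_level: float = BACKGROUND_LEVEL
    rotation_jitter_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0


OPTICS_PROFILES: dict[str, OpticsProfile] = {
    "canon": OpticsProfile(pixel_size_um=6.6),
    "iphone12": OpticsProfile(pixel_size_um=13.7),
}


@dataclass(frozen=True)
class SyntheticTipImage:
    """A rendered tip plus the ground truth needed to score recovery."""

    pixels: np.ndarray  # 2-D uint16, row 0 at top, apex near the top
    optics: OpticsProfile
    geom: ConeGeometry
    truth_positions_mm: np.ndarray  # axial, sorted ascending
    truth_radii_px: np.ndarray
    apex_px: tuple[float, float]  # (row, col), subpixel
    axis_angle_deg: float  # tilt of the axis from vertical, +ve toward +col
    resolution_warning: bool = False

    @property
    def pixel_size_um(self) -> float:
        return self.optics.pixel_size_um


@dataclass(frozen=True)
class TipSegmentation:
    """Recovered tip frame: apex, tilt, and the two boundary lines.

    Boundary lines are (slope, intercept) of col = slope·row + intercept.
    """

    apex_px: tuple[float, float]
    axis_angle_deg: float
    left_line: tuple[float, float]
    right_line: tuple[float, float]


@dataclass(frozen=True)
class SegmentationResult:
    """Detected colonies of one tip, in pixels and in axial millimetres."""

    apex_px: tuple[float, float]
    axis_angle_deg: float
    centers_px: np.ndarray  # (n, 2) rows, cols — sorted by axial position
    radii_px: np.ndarray
    positions_mm: np.ndarray  # sorted ascending
    routine_level: int = 1

    @property
    def n_colonies(self) -> int:
        return int(self.positions_mm.size)


def colony_radius_um(
    density_cfu_per_ml: float, r0_um: float = 66.0, d0_cfu_per_ml: float = 1e5
) -> float:
    """Self-limiting colony radius rule ``r0·(1 + density/d0)^(−1/3)`` (µm).

    ``r0_um=66`` makes an isolated colony 10 px across a 6.6 µm/px sensor.
    """
    return r0_um * (1.0 + density_cfu_per_ml / d0_cfu_per_ml) ** (-1.0 / 3.0)


def _axis_vectors(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit axis (apex→base, ~downward) and normal, in (row, col) mm frame."""
    th = np.deg2rad(angle_deg)
    d = np.array([np.cos(th), np.sin(th)])
    n = np.array([-np.sin(th), np.cos(th)])
    return d, n


def generate_tip_image(
    colonies: ColonySet,
    optics: OpticsProfile,
    rng: np.random.Generator | None = None,
    tilt_deg: float | None = None,
    base_radius_mm: float | None = None,
    margin_mm: float = 2.0,
) -> SyntheticTipImage:
    """Render a gel-filled tip with its colonies as a greyscale image.

    The apex is near the top of the frame, axis pointing down, tilted by
    ``tilt_deg`` (drawn uniformly within ±rotation_jitter_deg when None).
    Colonies are dark discs at their (axial, radial) positions, radius from
    :func:`colony_radius_um` evaluated at the set's own gel density.
    Deterministic given ``rng``.
    """
    rng = rng or np.random.default_rng(0)
    geom = colonies.geom
    h = geom.axial_length_mm
    if base_radius_mm is None:
        base_radius_mm = float(np.sqrt(3.0 * geom.volume_uL / (np.pi * h)))
    if tilt_deg is None:
        j = optics.rotation_jitter_deg
        tilt_deg = float(rng.uniform(-j, j)) if j else 0.0
    d, nrm = _axis_vectors(tilt_deg)
    px_mm = optics.pixel_size_mm

    # bounding box of the cone (apex + base corners) plus margin
    corners = np.array([[0.0, 0.0], h * d + base_radius_mm * nrm, h * d - base_radius_mm * nrm])
    lo = corners.min(axis=0) - margin_mm
    hi = corners.max(axis=0) + margin_mm
    apex_mm = -lo  # apex position relative to the image origin
    n_rows = int(np.ceil((hi[0] - lo[0]) / px_mm))
    n_cols = int(np.ceil((hi[1] - lo[1]) / px_mm))

    rows_mm = (np.arange(n_rows) + 0.5) * px_mm - apex_mm[0]
    cols_mm = (np.arange(n_cols) + 0.5) * px_mm - apex_mm[1]
    rr, cc = np.meshgrid(rows_mm, cols_mm, indexing="ij")
    a = rr * d[0] + cc * d[1]  # axial coordinate of each pixel
    r = rr * nrm[0] + cc * nrm[1]  # signed radial coordinate
    inside = (a >= 0.0) & (a <= h) & (np.abs(r) <= base_radius_mm * np.clip(a, 0, None) / h)

    img = np.full((n_rows, n_cols), optics.background_level, dtype=float)
    img[inside] = CONE_LEVEL

    # colony discs
    pos = colonies.positions_mm
    density = pos.size / colonies.volume_mL if pos.size else 0.0
    r_um = colony_radius_um(density) if pos.size else 0.0
    r_px = r_um / optics.pixel_size_um
    radial = colonies.y_mm if colonies.y_mm is not None else np.zeros(pos.size)
    if pos.size:
        lim = base_radius_mm * pos / h
        y_c = np.clip(radial, -lim, lim)
        centers_mm = apex_mm + pos[:, None] * d + y_c[:, None] * nrm
        centers_px = np.round(centers_mm / px_mm - 0.5).astype(int)
        # all colonies share one radius; paint every disc from one offset template
        off_r, off_c = skdraw.disk((0, 0), max(r_px, 1.0))
        rr_all = (centers_px[:, 0, None] + off_r).ravel()
        cc_all = (centers_px[:, 1, None] + off_c).ravel()
        ok = (rr_all >= 0) & (rr_all < n_rows) & (cc_all >= 0) & (cc_all < n_cols)
        rr_all, cc_all = rr_all[ok], cc_all[ok]
        keep = inside[rr_all, cc_all]  # clip discs to the gel silhouette
        img[rr_all[keep], cc_all[keep]] = COLONY_LEVEL

    if optics.noise_sd:
        img += rng.normal(0.0, optics.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    apex_px = (apex_mm[0] / px_mm - 0.5, apex_mm[1] / px_mm - 0.5)
    return SyntheticTipImage(
        pixels=np.round(img * 65535).astype(np.uint16),
        optics=optics,
        geom=geom,
        truth_positions_mm=pos.copy(),
        truth_radii_px=np.full(pos.size, r_px),
        apex_px=apex_px,
        axis_angle_deg=tilt_deg,
        resolution_warning=bool(pos.size and r_px < 2.0),
    )


def _silhouette_mask(img: np.ndarray) -> np.ndarray:
    """Binary tip silhouette: largest connected component darker than background.

    The background level is estimated from the image border (the tip never
    touches it), which keeps the threshold stable whether the gel is mostly
    empty or mostly covered by dark colonies — plain Otsu can split
    colony-vs-gel instead of tip-vs-background on dense tips.
    """
    if img.ndim == 3:  # colour input: luminance
        from skimage.color import rgb2gray

        img = rgb2gray(img)
    f = img_as_float(img)
    if f.max() - f.min() < 0.05:
        raise SegmentationError("no tip silhouette found (flat image)")
    border = np.concatenate([f[0], f[-1], f[:, 0], f[:, -1]])
    bg = float(np.median(border))
    interior_floor = float(f.min())
    if bg - interior_floor < 0.05:
        raise SegmentationError("no tip silhouette found (no contrast to background)")
    mask = f < bg - 0.3 * (bg - interior_floor)
    labels = measure.label(mask)
    if labels.max() == 0:
        raise SegmentationError("no tip silhouette found")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    if mask.sum() < 200:
        raise SegmentationError("candidate silhouette too small to be a tip")
    return mask


def segment_tip(image) -> TipSegmentation:
    """Locate the tip's apex, tilt and left/right boundary lines.

    The silhouette is thresholded (Otsu), each row's leftmost/rightmost
    silhouette column is extracted over the central portion of the tip, and
    two least-squares lines are fitted; their intersection is the apex and
    the angle of their bisector from vertical is the tilt.  Averaging edge
    pixels over thousands of rows gives subpixel apex accuracy on clean
    images (≤2 px, ≤0.5°).
    """
    pixels = image.pixels if isinstance(image, SyntheticTipImage) else np.asarray(image)
    mask = _silhouette_mask(pixels)
    rows = np.flatnonzero(mask.any(axis=1))
    extent = rows[-1] - rows[0]
    if extent < 20:
        raise SegmentationError("silhouette too short to fit boundary lines")
    # central band: clear of the rounded apex and of base-end artefacts
    band = rows[(rows >= rows[0] + 0.15 * extent) & (rows <= rows[0] + 0.9 * extent)]
    # subpixel edges: the true boundary lies half a pixel outside the first/last
    # silhouette pixel centre; without this the lines intersect ~1px/(edge
    # slope difference) short of the true apex
    left = np.array([np.flatnonzero(mask[r])[0] for r in band], dtype=float) - 0.5
    right = np.array([np.flatnonzero(mask[r])[-1] for r in band], dtype=float) + 0.5
    ml, bl = np.polyfit(band, left, 1)
    mr, br = np.polyfit(band, right, 1)
    if abs(ml - mr) < 1e-9:
        raise SegmentationError("boundary lines are parallel; not a conical tip")
    apex_row = (br - bl) / (ml - mr)
    apex_col = ml * apex_row + bl
    axis_slope = 0.5 * (ml + mr)  # d(col)/d(row) of the bisector
    angle = float(np.degrees(np.arctan(axis_slope)))
    return TipSegmentation(
        apex_px=(float(apex_row), float(apex_col)),
        axis_angle_deg=angle,
        left_line=(float(ml), float(bl)),
        right_line=(float(mr), float(br)),
    )


def detect_colonies(
    image,
    segmentation: TipSegmentation | None = None,
    routine_level: int = 1,
    pixel_size_um: float | None = None,
    geom: ConeGeometry | None = None,
    min_sigma: float = 1.0,
    max_sigma: float = 8.0,
    threshold: float = 0.08,
    add_px: list[tuple[float, float]] | None = None,
    remove_px: list[tuple[float, float]] | None = None,
) -> SegmentationResult:
    """Detect colonies and convert their centres to axial mm from the apex.

    ``routine_level`` (1..5) selects the axial window analysed, from the
    whole tip down to the apex-most 1/20 (level 5, additionally capped at
    the first 30 colonies) — the small windows are for dense tips whose
    colonies are tiny.  Detection is multi-scale Laplacian-of-Gaussian blob
    search on the colony contrast (pixels darker than the gel).

    ``add_px``/``remove_px`` are the curation hook: (row, col) detections to
    force in, or existing detections to delete (nearest within 5 px).
    """
    if routine_level not in WINDOW_FRACTIONS:
        raise ValueError(f"routine_level must be in {sorted(WINDOW_FRACTIONS)}")
    if isinstance(image, SyntheticTipImage):
        pixels = image.pixels
        pixel_size_um = pixel_size_um or image.optics.pixel_size_um
        geom = geom or image.geom
    else:
        pixels = np.asarray(image)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um is required for plain-array input")
    if geom is None:
        geom = ConeGeometry()
    seg = segmentation or segment_tip(pixels)

    f = img_as_float(pixels)
    mask = _silhouette_mask(pixels)
    # bright end of the silhouette = clean gel; the median would land on the
    # colony level once projected colonies cover most of a dense tip
    gel_level = float(np.percentile(f[mask], 98))
    signal = np.where(mask, np.clip(gel_level - f, 0.0, None), 0.0)

    # restrict the blob search to rows that can reach the axial window
    window_mm = geom.axial_length_mm * WINDOW_FRACTIONS[routine_level]
    px_mm_local = pixel_size_um / 1000.0
    pad = int(2 * max_sigma) + 2
    row_lo = max(int(seg.apex_px[0]) - pad, 0)
    row_hi = min(
        int(seg.apex_px[0] + window_mm / px_mm_local / max(np.cos(np.deg2rad(seg.axis_angle_deg)), 0.5))
        + pad,
        signal.shape[0],
    )
    blobs = feature.blob_log(
        signal[row_lo:row_hi],
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=10,
        threshold=threshold,
        overlap=0.3,
    )
    if blobs.size:
        blobs[:, 0] += row_lo
    centers = blobs[:, :2] if blobs.size else np.empty((0, 2))
    radii = blobs[:, 2] * np.sqrt(2.0) if blobs.size else np.empty(0)

    if remove_px:
        keep = np.ones(len(centers), dtype=bool)
        for r0, c0 in remove_px:
            if not keep.any():
                break
            dist = np.hypot(centers[:, 0] - r0, centers[:, 1] - c0)
            dist[~keep] = np.inf
            if dist.min() <= 5.0:
                keep[int(np.argmin(dist))] = False
        centers, radii = centers[keep], radii[keep]
    if add_px:
        extra = np.asarray(add_px, dtype=float).reshape(-1, 2)
        med_r = float(np.median(radii)) if radii.size else min_sigma * np.sqrt(2.0)
        centers = np.vstack([centers, extra])
        radii = np.concatenate([radii, np.full(len(extra), med_r)])

    # axial positions via the recovered frame
    d, _ = _axis_vectors(seg.axis_angle_deg)
    rel = centers - np.asarray(seg.apex_px)
    a_mm = (rel @ d) * (pixel_size_um / 1000.0)
    in_win = (a_mm >= 0.0) & (a_mm <= min(window_mm, geom.axial_length_mm))
    centers, radii, a_mm = centers[in_win], radii[in_win], a_mm[in_win]

    order = np.argsort(a_mm, kind="stable")
    centers, radii, a_mm = centers[order], radii[order], a_mm[order]
    if routine_level == 5 and a_mm.size > LEVEL5_MAX_COLONIES:
        centers = centers[:LEVEL5_MAX_COLONIES]
        radii = radii[:LEVEL5_MAX_COLONIES]
        a_mm = a_mm[:LEVEL5_MAX_COLONIES]
    return SegmentationResult(
        apex_px=seg.apex_px,
        axis_angle_deg=seg.axis_angle_deg,
        centers_px=centers,
        radii_px=radii,
        positions_mm=a_mm,
        routine_level=routine_level,
    )


def image_to_estimate(
    image,
    geom: ConeGeometry | None = None,
    dilution_factor: float = 100.0,
    k: int | str = 10,
    mode: str = "interval",
    routine_level: int = 1,
    pixel_size_um: float | None = None,
    tip_id: str = "image",
) -> CfuEstimate:
    """End-to-end: segment a tip image and estimate its sample CFU/mL."""
    if isinstance(image, SyntheticTipImage):
        geom = geom or image.geom
    elif geom is None:
        geom = ConeGeometry()
    res = detect_colonies(
        image, routine_level=routine_level, pixel_size_um=pixel_size_um, geom=geom
    )
    colonies = ColonySet(
        tip_id=tip_id,
        positions_mm=np.clip(res.positions_mm, 0.0, geom.axial_length_mm),
        geom=geom,
        dilution_factor=dilution_factor,
    )
    return estimate_cfu(colonies, k=k, mode=mode)
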