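"""Synthetic multi-channel fluorescence scenes with known ground truth.

Real receptor-clustering experiments image a surface stain whose texture
changes with stimulation time: fine puncta before ligand addition, connected
linear clusters a few minutes after, and coarse dense aggregates at late
times.  Super-resolution imaging of the late aggregates additionally shows
"double-walled" profiles: two parallel ridges of surface stain with ligand
and phospho-receptor signal filling the central gap.

This module renders those four texture classes onto a random cell-shaped
mask, together with the confounds an analysis pipeline has to survive —
smooth uneven illumination, bright membrane ruffles near the cell edge, and
Poisson + Gaussian camera noise — and records complete ground truth
(centrelines, characteristic length, ruffle and illumination fields,
noiseless intensities) so that every downstream stage can be tested without
microscope data.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter
from skimage.draw import polygon as draw_polygon

from .image import ImagePlane

__all__ = [
    "TEXTURE_CLASSES",
    "SceneConfig",
    "SceneTruth",
    "Scene",
    "generate_cell_shape",
    "render_texture",
    "corrupt",
    "generate_scene",
    "generate_timecourse",
    "timecourse_config",
]

TEXTURE_CLASSES = ("punctate", "linear_cidc", "aggregate", "double_wall")

# FWHM = 2*sqrt(2 ln 2) * sigma for a Gaussian profile
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    ``char_length_um`` is the characteristic structure scale: the FWHM of
    puncta/ridge cross-sections for the single-ridge classes, and the
    wall-to-wall gap for the ``double_wall`` class.  ``density`` counts
    structures (spots or polylines) per μm² of cell area.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.1
    texture_class: str = "punctate"
    char_length_um: float = 0.2
    density: float = 8.0
    amplitude: float = 100.0
    baseline_frac: float = 0.15
    noise_gaussian_sd: float = 2.0
    noise_poisson: bool = True
    gain: float = 1.0
    illumination_amplitude: float = 0.2
    ruffle_count: int = 0
    py_amplitude: float = 0.0
    collagen_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.texture_class not in TEXTURE_CLASSES:
            raise ValueError(
                f"texture_class must be one of {TEXTURE_CLASSES}, got {self.texture_class!r}"
            )
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if self.char_length_um < 2.0 * self.pixel_size_um:
            raise ValueError(
                "char_length_um must be at least 2x pixel_size_um so structures are resolvable "
                f"(got {self.char_length_um} um at {self.pixel_size_um} um/px)"
            )
        if not (self.amplitude > 0):
            raise ValueError("amplitude must be > 0")
        if self.noise_gaussian_sd < 0 or self.density < 0:
            raise ValueError("noise and density parameters must be non-negative")
        if self.illumination_amplitude < 0:
            raise ValueError("illumination_amplitude must be >= 0")
        if self.ruffle_count < 0:
            raise ValueError("ruffle_count must be >= 0")

    def replace(self, **kwargs) -> "SceneConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SceneTruth:
    """Generator ground truth for one scene."""

    cell_mask: np.ndarray
    structure_centrelines: list[np.ndarray]  # each (n, 2) float array of (row, col)
    char_length_um: float
    ruffle_mask: np.ndarray
    illumination_field: np.ndarray
    per_channel_truth: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Scene:
    """A multi-channel synthetic image plus its ground truth and config."""

    channels: dict[str, ImagePlane]
    truth: SceneTruth
    config: SceneConfig

    def __post_init__(self) -> None:
        shapes = {p.data.shape for p in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels of a Scene must share one shape")


def generate_cell_shape(shape: tuple[int, int], seed: int) -> np.ndarray:
    """Generate one simply-connected cell-shaped blob.

    The blob is a star-convex polygon: a base radius chosen so that the area
    occupies roughly 25–50 % of the frame, perturbed by a few low-order
    Fourier modes of the boundary.  Star-convexity guarantees simple
    connectivity; the bounded perturbation keeps the area fraction within
    the contract [0.2, 0.6].
    """
    h, w = int(shape[0]), int(shape[1])
    if h < 64 or w < 64:
        raise ValueError(f"frame too small for a cell shape: need >= 64x64, got {h}x{w}")
    rng = np.random.default_rng(seed)
    frac = rng.uniform(0.27, 0.45)
    r0 = np.sqrt(frac * h * w / np.pi)
    r0 = min(r0, 0.46 * min(h, w))
    theta = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    r = np.full_like(theta, r0)
    for k in range(2, 6):
        amp = rng.uniform(0.0, 0.22 / k)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        r = r + r0 * amp * np.cos(k * theta + phase)
    r = np.clip(r, 4.0, 0.48 * min(h, w))
    cr = h / 2.0 + rng.uniform(-0.04, 0.04) * h
    cc = w / 2.0 + rng.uniform(-0.04, 0.04) * w
    rows = cr + r * np.sin(theta)
    cols = cc + r * np.cos(theta)
    mask = np.zeros((h, w), dtype=bool)
    rr, ccs = draw_polygon(rows, cols, shape=(h, w))
    mask[rr, ccs] = True
    return mask


def _uniform_points_in_mask(mask: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) float (row, col) points uniform over the mask, sub-pixel jittered."""
    pix = np.argwhere(mask)
    idx = rng.integers(0, len(pix), size=n)
    return pix[idx].astype(np.float64) + rng.uniform(-0.5, 0.5, size=(n, 2))


def _deposit_points(grid: np.ndarray, pts: np.ndarray, weights=1.0) -> None:
    """Accumulate point weights into the nearest pixels of ``grid`` in place."""
    r = np.clip(np.rint(pts[:, 0]).astype(int), 0, grid.shape[0] - 1)
    c = np.clip(np.rint(pts[:, 1]).astype(int), 0, grid.shape[1] - 1)
    np.add.at(grid, (r, c), weights)


def _random_walk_polyline(
    mask: np.ndarray,
    rng: np.random.Generator,
    step_px: float,
    n_steps: int,
    angle_jitter: float,
) -> np.ndarray:
    """A persistent random walk clipped to the mask; (n, 2) row/col vertices."""
    start = _uniform_points_in_mask(mask, 1, rng)[0]
    ang = rng.uniform(0.0, 2.0 * np.pi)
    pts = [start]
    p = start.copy()
    for _ in range(n_steps):
        ang += rng.normal(0.0, angle_jitter)
        q = p + step_px * np.array([np.sin(ang), np.cos(ang)])
        ri, ci = int(round(q[0])), int(round(q[1]))
        if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]) or not mask[ri, ci]:
            break
        pts.append(q)
        p = q
    return np.array(pts)


def _densify(polyline: np.ndarray, spacing: float = 0.3) -> np.ndarray:
    """Resample a polyline at roughly ``spacing``-pixel intervals."""
    if len(polyline) < 2:
        return polyline
    segs = []
    for a, b in zip(polyline[:-1], polyline[1:]):
        d = float(np.hypot(*(b - a)))
        n = max(2, int(np.ceil(d / spacing)) + 1)
        t = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
        segs.append(a[None, :] + t * (b - a)[None, :])
    segs.append(polyline[-1:])
    return np.concatenate(segs, axis=0)


def _polyline_normals(dense: np.ndarray) -> np.ndarray:
    """Unit normals at each vertex of a densified polyline."""
    tang = np.gradient(dense, axis=0)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tang = tang / norm
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def render_texture(
    config: SceneConfig,
    mask: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], list[np.ndarray]]:
    """Render noiseless texture channels for one scene.

    Returns ``(channels, centrelines)`` where ``channels`` maps channel names
    to noiseless float grids (zero outside the cell mask) and ``centrelines``
    lists the ground-truth structure centrelines in pixel coordinates.

    All classes share a Gaussian cross-section of σ = char_length / 2.355
    (so the FWHM of a structure equals the characteristic length), except
    ``double_wall``, where char_length is the wall-to-wall gap ``g``: the
    receptor channel carries two parallel ridges offset ±g/2 from the
    centreline (σ = g/4) while the collagen and phospho channels carry a
    single centred ridge — the filler-in-the-gap geometry.

    Rendering is linear in ``config.amplitude`` by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cell mask is empty; nothing to render onto")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    px = config.pixel_size_um
    area_um2 = mask.sum() * px * px
    sigma_px = (config.char_length_um / _FWHM_PER_SIGMA) / px
    shape = mask.shape
    centrelines: list[np.ndarray] = []
    channels: dict[str, np.ndarray] = {}

    if config.texture_class in ("punctate", "aggregate"):
        # spot centres form a spatial Poisson process for the fine punctate
        # class; the coarse-aggregate count is fixed to its expectation so
        # late-time scenes vary less in total coverage
        if config.texture_class == "punctate":
            n = int(rng.poisson(config.density * area_um2))
        else:
            n = int(round(config.density * area_um2))
        grid = np.zeros(shape, dtype=np.float64)
        if n > 0:
            pts = _uniform_points_in_mask(mask, n, rng)
            _deposit_points(grid, pts)
            centrelines.extend(p[None, :] for p in pts)
            grid = gaussian_filter(grid, sigma_px)
            # unit-impulse response peak is ~1/(2 pi sigma^2); rescale so an
            # isolated spot peaks at `amplitude`
            grid *= config.amplitude * (2.0 * np.pi * sigma_px**2)
        grid *= mask
        if grid.sum() > 0 and (grid > 0.5 * config.amplitude).sum() > 0.95 * mask.sum():
            import warnings

            warnings.warn("structure density covers >95% of the cell mask", stacklevel=2)
        channels["ddr1"] = grid

    elif config.texture_class == "linear_cidc":
        n = max(1, int(round(config.density * area_um2)))
        grid = np.zeros(shape, dtype=np.float64)
        step_px = max(2.0, 2.0 * config.char_length_um / px)
        spacing = 0.3
        placed = 0
        for _ in range(10 * n):
            if placed >= n:
                break
            poly = _random_walk_polyline(mask, rng, step_px, n_steps=12, angle_jitter=0.45)
            if len(poly) < 2:
                continue
            dense = _densify(poly, spacing)
            _deposit_points(grid, dense, spacing)
            centrelines.append(poly)
            placed += 1
        grid = gaussian_filter(grid, sigma_px)
        # a line of unit linear density filtered in 2-D peaks at 1/(sqrt(2 pi) sigma)
        grid *= config.amplitude * np.sqrt(2.0 * np.pi) * sigma_px
        grid *= mask
        channels["ddr1"] = grid

    elif config.texture_class == "double_wall":
        n = max(1, int(rng.poisson(config.density * area_um2)))
        gap_px = config.char_length_um / px
        ridge_sigma = max(0.8, gap_px / 4.0)
        wall = np.zeros(shape, dtype=np.float64)
        filler = np.zeros(shape, dtype=np.float64)
        spacing = 0.3
        step_px = max(3.0, 1.5 * gap_px)
        # keep walks far enough inside the cell that neither wall is clipped
        # by the mask edge
        margin = int(np.ceil(0.5 * gap_px + 2.0 * ridge_sigma))
        inner = binary_erosion(mask, iterations=margin) if margin > 0 else mask
        if not inner.any():
            inner = mask
        placed = 0
        for _ in range(10 * n):
            if placed >= n:
                break
            poly = _random_walk_polyline(inner, rng, step_px, n_steps=10, angle_jitter=0.15)
            dense = _densify(poly, spacing)
            if len(dense) < 4:
                continue
            placed += 1
            normals = _polyline_normals(dense)
            # re-densify each offset polyline so wall brightness stays uniform
            # along curves (offsetting stretches the outer wall's spacing)
            _deposit_points(wall, _densify(dense + 0.5 * gap_px * normals, spacing), spacing)
            _deposit_points(wall, _densify(dense - 0.5 * gap_px * normals, spacing), spacing)
            _deposit_points(filler, dense, spacing)
            centrelines.append(poly)
        wall = gaussian_filter(wall, ridge_sigma) * np.sqrt(2.0 * np.pi) * ridge_sigma
        filler = gaussian_filter(filler, ridge_sigma) * np.sqrt(2.0 * np.pi) * ridge_sigma
        wall *= config.amplitude * mask
        coll_amp = config.collagen_amplitude if config.collagen_amplitude > 0 else config.amplitude
        py_amp = config.py_amplitude if config.py_amplitude > 0 else config.amplitude
        channels["ddr1"] = wall
        channels["collagen"] = coll_amp * filler * mask
        channels["py"] = py_amp * filler * mask

    if "py" not in channels:
        channels["py"] = (config.py_amplitude / config.amplitude) * channels["ddr1"]
    if "collagen" not in channels and config.collagen_amplitude > 0:
        channels["collagen"] = (config.collagen_amplitude / config.amplitude) * channels["ddr1"]
    # diffuse unclustered-stain baseline inside the cell, proportional to each
    # channel's peak amplitude so rendering stays exactly linear in amplitude
    if config.baseline_frac > 0:
        per_channel_amp = {
            "ddr1": config.amplitude,
            "py": config.py_amplitude,
            "collagen": config.collagen_amplitude or config.amplitude,
        }
        if config.texture_class == "double_wall":
            per_channel_amp["collagen"] = (
                config.collagen_amplitude if config.collagen_amplitude > 0 else config.amplitude
            )
            per_channel_amp["py"] = (
                config.py_amplitude if config.py_amplitude > 0 else config.amplitude
            )
        for name in channels:
            channels[name] = channels[name] + config.baseline_frac * per_channel_amp.get(
                name, config.amplitude
            ) * mask
    return channels, centrelines


def _illumination_field(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative illumination: 1 + a low-order 2-D polynomial.

    The polynomial is rescaled so its peak-to-trough range equals
    ``amplitude`` (fraction of the mean level).  amplitude = 0 gives an
    exact field of ones.
    """
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    yn = 2.0 * y / max(h - 1, 1) - 1.0
    xn = 2.0 * x / max(w - 1, 1) - 1.0
    coeffs = rng.normal(0.0, 1.0, size=5)
    f = (
        coeffs[0] * xn
        + coeffs[1] * yn
        + coeffs[2] * xn * yn
        + coeffs[3] * xn**2
        + coeffs[4] * yn**2
    )
    if amplitude == 0:
        return np.ones(shape, dtype=np.float64)
    rng_span = f.max() - f.min()
    if rng_span == 0:
        return np.ones(shape, dtype=np.float64)
    f = (f - f.min()) / rng_span - 0.5  # in [-0.5, 0.5]
    return 1.0 + amplitude * f


def _ruffle_field(
    mask: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator,
    sigma_um: float = 0.4,
) -> np.ndarray:
    """Bright blobs (3–5x texture amplitude) within ~1 μm of the mask edge."""
    px = config.pixel_size_um
    boundary = mask & ~binary_erosion(mask, np.ones((3, 3), dtype=bool))
    bpix = np.argwhere(boundary)
    fieldgrid = np.zeros(mask.shape, dtype=np.float64)
    sigma_px = sigma_um / px
    jitter_px = 1.0 / px
    for _ in range(config.ruffle_count):
        centre = bpix[rng.integers(0, len(bpix))].astype(np.float64)
        centre += rng.uniform(-jitter_px, jitter_px, size=2)
        amp = rng.uniform(3.0, 5.0) * config.amplitude
        blob = np.zeros(mask.shape, dtype=np.float64)
        _deposit_points(blob, centre[None, :])
        blob = gaussian_filter(blob, sigma_px) * (2.0 * np.pi * sigma_px**2)
        fieldgrid += amp * blob
    return fieldgrid


def corrupt(
    noiseless: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
    cell_mask: np.ndarray | None = None,
) -> tuple[ImagePlane, np.ndarray, np.ndarray]:
    """Apply illumination, ruffle confounds and camera noise to a clean grid.

    Order of corruption: multiplicative smooth illumination, additive bright
    membrane-ruffle blobs near the cell boundary, Poisson shot noise
    (intensities read as expected photon counts times ``config.gain``), then
    additive Gaussian read noise.

    Returns ``(plane, illumination_field, ruffle_mask)``.  With illumination
    amplitude 0, no ruffles and noise off, the output equals the input.
    """
    noiseless = np.asarray(noiseless, dtype=np.float64)
    if (noiseless < 0).any():
        raise ValueError("noiseless input must be non-negative")
    if config.noise_gaussian_sd < 0:
        raise ValueError("noise_gaussian_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    img = noiseless.copy()

    illum = _illumination_field(img.shape, config.illumination_amplitude, rng)
    img = img * illum

    ruffle_mask = np.zeros(img.shape, dtype=bool)
    if config.ruffle_count > 0:
        if cell_mask is None:
            raise ValueError("cell_mask is required to place membrane ruffles")
        ruffles = _ruffle_field(cell_mask, config, rng)
        img = img + ruffles
        ruffle_mask = ruffles > 0.5 * config.amplitude

    if config.noise_poisson:
        img = rng.poisson(np.maximum(img, 0.0) * config.gain).astype(np.float64) / config.gain
    if config.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, config.noise_gaussian_sd, size=img.shape)
    return ImagePlane(img, config.pixel_size_um), illum, ruffle_mask


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a complete scene: shape, texture, confounds and ground truth.

    Fully deterministic given ``config`` (one seed drives independent child
    streams for shape, texture and per-channel corruption).
    """
    root = np.random.default_rng(config.seed)
    shape_seed = int(root.integers(0, 2**31 - 1))
    mask = generate_cell_shape(config.image_shape, shape_seed)
    texture_rng = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
    clean, centrelines = render_texture(config, mask, texture_rng)

    # one illumination field / ruffle layout shared by all channels: draw them
    # once and reuse by corrupting each channel with the same confound rng but
    # an independent noise stream
    channels: dict[str, ImagePlane] = {}
    illum_ref: np.ndarray | None = None
    ruffle_ref: np.ndarray | None = None
    confound_seed = int(root.integers(0, 2**31 - 1))
    for name in sorted(clean):
        chan_rng = np.random.default_rng([confound_seed, zlib.crc32(name.encode()) % (2**31)])
        plane, illum, ruffle = corrupt(clean[name], config, chan_rng, cell_mask=mask)
        plane.channel = name
        channels[name] = plane
        if illum_ref is None:
            illum_ref, ruffle_ref = illum, ruffle

    truth = SceneTruth(
        cell_mask=mask,
        structure_centrelines=centrelines,
        char_length_um=config.char_length_um,
        ruffle_mask=ruffle_ref if ruffle_ref is not None else np.zeros(mask.shape, bool),
        illumination_field=illum_ref if illum_ref is not None else np.ones(mask.shape),
        per_channel_truth=clean,
    )
    return Scene(channels=channels, truth=truth, config=config)


def timecourse_config(time_min: float, seed: int = 0, **overrides) -> SceneConfig:
    """Scene configuration for one stimulation time point.

    0 min maps to fine puncta, 5–30 min to linear connected clusters at an
    intermediate scale, and ≥45 min to coarse aggregates; the characteristic
    length strictly increases along that ordering.  Aggregate density is
    scaled down with scale² so late scenes show fewer, larger structures of
    comparable total mass.  The phospho-channel amplitude follows the slow
    activation kinetics: absent before stimulation, weak at early/middle
    times, strong only in the late aggregated state.
    """
    if time_min <= 0:
        base = dict(texture_class="punctate", char_length_um=0.2, density=8.0, py_amplitude=0.0)
    elif time_min < 45:
        base = dict(texture_class="linear_cidc", char_length_um=0.3, density=0.5, py_amplitude=15.0)
    else:
        # structure count scales down with the square of the scale so the late
        # scenes show fewer, larger aggregates of comparable total coverage
        base = dict(
            texture_class="aggregate",
            char_length_um=0.8,
            density=8.0 * (0.2 / 0.8) ** 2,
            py_amplitude=100.0,
        )
    base.update(overrides)
    return SceneConfig(seed=seed, **base)


def generate_timecourse(times: list[float], seed: int = 0, **overrides) -> list[Scene]:
    """One scene per stimulation time, emulating a stimulation time course."""
    if not times:
        raise ValueError("times must be non-empty")
    scenes = []
    for i, t in enumerate(times):
        cfg = timecourse_config(t, seed=seed * 100003 + i, **overrides)
        scenes.append(generate_scene(cfg))
    return scenes
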