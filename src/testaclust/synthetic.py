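"""Synthetic seed-testa texture generator.

Seed-coat (testa) sculpture is a standard taxonomic character: the
*anticlinal* walls (boundaries between neighbouring epidermal cells) show a
characteristic undulation type — straight, S-shaped, U-shaped, U-to-Ω,
Ω-shaped, or irregular — while the *periclinal* (outward-facing) walls carry
granules or verrucae (wart-like protuberances) of varying size and placement.

This module renders labelled 250 × 250 grayscale patches that emulate those
morphologies so that the downstream preprocessing, clustering and consensus
stages can be exercised and validated with known ground truth:

* a jittered-grid (blue-noise) point set seeds a Voronoi tessellation whose
  ridges play the role of anticlinal walls;
* each wall is drawn as a sinusoidally displaced polyline whose amplitude,
  frequency and lobe re-entrance encode the anticlinal class;
* bright blobs placed uniformly, marginally (along walls) or densely encode
  the periclinal class;
* Gaussian blur plus additive Gaussian noise give an SEM-like finish.

Generation is fully deterministic for a fixed (wall class, parameters, seed).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.spatial import Voronoi

from ._seeds import derive_seed
from .errors import InvalidInputError

PATCH_SIDE = 250

__all__ = [
    "PATCH_SIDE",
    "Anticlinal",
    "Periclinal",
    "WallClass",
    "TextureParams",
    "SeedImage",
    "default_params",
    "generate_image",
    "generate_dataset",
    "trace_walls",
    "render_layers",
    "boundary_tortuosity",
    "well_separated_triple",
    "write_dataset",
    "load_dataset",
]


class Anticlinal(str, enum.Enum):
    """The seven anticlinal-wall undulation types."""

    IRREGULAR_CURVED = "irregular_curved"
    IRREGULAR_TO_STRAIGHT = "irregular_to_straight"
    STRAIGHT = "straight"
    S = "S"
    U = "U"
    U_TO_OMEGA = "U_to_omega"
    OMEGA = "omega"


class Periclinal(str, enum.Enum):
    """The five periclinal-wall sculpture types."""

    GRANULE = "granule"
    SMALL_VERRUCAE = "small_verrucae"
    LARGE_VERRUCAE = "large_verrucae"
    MARGINAL_VERRUCAE = "marginal_verrucae"
    VERRUCATE_VERRUCAE = "verrucate_verrucae"


def _coerce(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError as exc:
        valid = ", ".join(m.value for m in enum_cls)
        raise InvalidInputError(
            f"{value!r} is not a valid {enum_cls.__name__}; expected one of: {valid}"
        ) from exc


@dataclasses.dataclass(frozen=True)
class WallClass:
    """A ground-truth morphology label: one anticlinal and one periclinal type."""

    anticlinal: Anticlinal
    periclinal: Periclinal

    def __post_init__(self):
        object.__setattr__(self, "anticlinal", _coerce(self.anticlinal, Anticlinal))
        object.__setattr__(self, "periclinal", _coerce(self.periclinal, Periclinal))

    @property
    def label(self) -> str:
        return f"{self.anticlinal.value}|{self.periclinal.value}"


@dataclasses.dataclass(frozen=True)
class TextureParams:
    """Rendering parameters for one synthetic patch.

    ``cell_count`` is the requested number of Voronoi seeds (realized as the
    nearest jittered grid); ``undulation_amplitude`` (px) and
    ``undulation_frequency`` (cycles per wall) shape the anticlinal walls;
    ``lobe_reentrance`` in [0, 1] moves a wall from U-like (0) toward Ω-like
    re-entrant lobes (→1); the verruca fields control the periclinal blobs;
    ``mesh_jitter`` is the grid jitter as a fraction of cell spacing;
    ``noise_sd`` (gray levels) and ``blur_sigma`` (px) give the SEM finish.
    """

    cell_count: int = 12
    undulation_amplitude: float = 0.0
    undulation_frequency: float = 0.0
    lobe_reentrance: float = 0.0
    verruca_count: int = 0
    verruca_radius: float = 3.0
    verruca_placement: str = "uniform"
    interior_level: float = 0.78
    mesh_jitter: float = 0.15
    wall_halfwidth: float = 1.5
    noise_sd: float = 0.03
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.cell_count < 1:
            raise InvalidInputError("cell_count must be >= 1")
        if self.verruca_count < 0:
            raise InvalidInputError("verruca_count must be >= 0")
        for name in ("undulation_amplitude", "undulation_frequency",
                     "verruca_radius", "noise_sd", "blur_sigma", "wall_halfwidth"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if not 0.0 <= self.lobe_reentrance <= 1.0:
            raise InvalidInputError("lobe_reentrance must be in [0, 1]")
        if self.verruca_placement not in ("uniform", "marginal", "dense"):
            raise InvalidInputError(
                "verruca_placement must be 'uniform', 'marginal' or 'dense'"
            )
        if not 0.0 < self.interior_level <= 1.0:
            raise InvalidInputError("interior_level must be in (0, 1]")
        spacing = PATCH_SIDE / math.sqrt(self.cell_count)
        if self.undulation_amplitude >= spacing / 2:
            raise InvalidInputError(
                "undulation_amplitude must be smaller than half the cell spacing "
                f"({spacing / 2:.1f} px for cell_count={self.cell_count})"
            )


@dataclasses.dataclass
class SeedImage:
    """One 250 × 250 gray-level patch with optional ground-truth labels."""

    id: str
    raster: np.ndarray
    truth: WallClass | None = None
    provenance: str = "synthetic"

    def __post_init__(self):
        self.raster = np.asarray(self.raster, dtype=float)
        if self.raster.shape != (PATCH_SIDE, PATCH_SIDE):
            raise InvalidInputError(
                f"raster must be {PATCH_SIDE} x {PATCH_SIDE}, got {self.raster.shape}"
            )
        if self.raster.min() < 0 or self.raster.max() > 1:
            raise InvalidInputError("raster values must lie in [0, 1]")
        if self.provenance not in ("synthetic", "external"):
            raise InvalidInputError("provenance must be 'synthetic' or 'external'")


# ---------------------------------------------------------------------------
# Default per-class parameter table.  The anticlinal entries are ordered so
# that mean wall tortuosity increases straight < S < U < U-to-Ω < Ω; the
# periclinal entries follow the field's qualitative descriptions (granules:
# many tiny bumps; verrucae: fewer, larger; marginal: along walls).  Tests
# pin this table — change it deliberately.
# ---------------------------------------------------------------------------

ANTICLINAL_PARAMS: dict[Anticlinal, dict] = {
    Anticlinal.STRAIGHT: dict(undulation_amplitude=0.0, undulation_frequency=0.0,
                              lobe_reentrance=0.0),
    Anticlinal.S: dict(undulation_amplitude=4.0, undulation_frequency=1.0,
                       lobe_reentrance=0.0),
    Anticlinal.U: dict(undulation_amplitude=6.5, undulation_frequency=1.5,
                       lobe_reentrance=0.0),
    Anticlinal.U_TO_OMEGA: dict(undulation_amplitude=8.5, undulation_frequency=1.8,
                                lobe_reentrance=0.4),
    Anticlinal.OMEGA: dict(undulation_amplitude=10.5, undulation_frequency=2.0,
                           lobe_reentrance=0.8),
    Anticlinal.IRREGULAR_CURVED: dict(undulation_amplitude=6.0,
                                      undulation_frequency=1.5,
                                      lobe_reentrance=0.0),
    Anticlinal.IRREGULAR_TO_STRAIGHT: dict(undulation_amplitude=3.0,
                                           undulation_frequency=1.0,
                                           lobe_reentrance=0.0),
}

#: Irregular classes additionally jitter amplitude and frequency per wall.
_IRREGULAR = {Anticlinal.IRREGULAR_CURVED, Anticlinal.IRREGULAR_TO_STRAIGHT}

# ``interior_level`` models the mean secondary-electron brightness of the
# periclinal surface: heavier sculpture (large or dense verrucae) scatters
# more and images darker, finely granular surfaces image brighter.  All
# levels stay above the downstream 0.6 threshold so cells remain the
# foreground components.
PERICLINAL_PARAMS: dict[Periclinal, dict] = {
    Periclinal.GRANULE: dict(verruca_count=90, verruca_radius=2.0,
                             verruca_placement="dense", interior_level=0.88),
    Periclinal.SMALL_VERRUCAE: dict(verruca_count=50, verruca_radius=3.0,
                                    verruca_placement="uniform",
                                    interior_level=0.78),
    Periclinal.LARGE_VERRUCAE: dict(verruca_count=12, verruca_radius=8.0,
                                    verruca_placement="uniform",
                                    interior_level=0.66),
    Periclinal.MARGINAL_VERRUCAE: dict(verruca_count=40, verruca_radius=3.0,
                                       verruca_placement="marginal",
                                       interior_level=0.82),
    Periclinal.VERRUCATE_VERRUCAE: dict(verruca_count=70, verruca_radius=5.0,
                                        verruca_placement="dense",
                                        interior_level=0.70),
}

# Gray levels of the clean composite, before blur/noise.  Walls sit well
# below the downstream 0.6 threshold.
_WALL_LEVEL = 0.15
_BUMP_GAIN = 0.14


def default_params(wall_class: WallClass, seed: int = 0, **overrides) -> TextureParams:
    """Build the default :class:`TextureParams` for a wall class.

    Morphology fields come from the per-class table; any keyword override
    wins over the table.
    """
    wall_class = _as_wall_class(wall_class)
    fields: dict = {}
    fields.update(ANTICLINAL_PARAMS[wall_class.anticlinal])
    fields.update(PERICLINAL_PARAMS[wall_class.periclinal])
    fields["seed"] = seed
    fields.update(overrides)
    return TextureParams(**fields)


def _as_wall_class(wall_class) -> WallClass:
    if isinstance(wall_class, WallClass):
        return wall_class
    if isinstance(wall_class, (tuple, list)) and len(wall_class) == 2:
        return WallClass(*wall_class)
    raise InvalidInputError(f"cannot interpret {wall_class!r} as a WallClass")


# ---------------------------------------------------------------------------
# Mesh and wall geometry
# ---------------------------------------------------------------------------

def _mesh_sites(params: TextureParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid blue-noise sites covering the patch."""
    nx = max(1, round(math.sqrt(params.cell_count)))
    ny = max(1, round(params.cell_count / nx))
    sx = PATCH_SIDE / nx
    sy = PATCH_SIDE / ny
    gx, gy = np.meshgrid((np.arange(nx) + 0.5) * sx, (np.arange(ny) + 0.5) * sy)
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    jitter = params.mesh_jitter * min(sx, sy)
    sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)
    return np.clip(sites, 1.0, PATCH_SIDE - 1.0)


def _voronoi_edges(sites: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Finite Voronoi ridge segments touching the patch.

    Sites are mirrored across the four patch borders so that every ridge
    adjacent to an original site has finite vertices.
    """
    mirrored = [sites]
    for axis, bound in ((0, 0.0), (0, PATCH_SIDE), (1, 0.0), (1, PATCH_SIDE)):
        m = sites.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    allpts = np.vstack(mirrored)
    n_orig = len(sites)
    vor = Voronoi(allpts)
    edges = []
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n_orig and q >= n_orig:
            continue
        if -1 in verts:
            continue
        v0, v1 = vor.vertices[verts[0]], vor.vertices[verts[1]]
        # Keep ridges that intersect the (slightly padded) patch.
        lo, hi = -2.0, PATCH_SIDE + 2.0
        if max(v0[0], v1[0]) < lo or min(v0[0], v1[0]) > hi:
            continue
        if max(v0[1], v1[1]) < lo or min(v0[1], v1[1]) > hi:
            continue
        edges.append((v0, v1))
    return edges


def _undulated_polyline(v0, v1, amplitude, frequency, reentrance, phase) -> np.ndarray:
    """Displace the straight segment v0→v1 into an undulating wall.

    The normal displacement is a sine with a half-sine envelope (so the
    endpoints stay pinned to the Voronoi vertices); the tangential term,
    scaled by ``reentrance``, makes lobes double back on themselves,
    producing Ω-like necks.
    """
    v0 = np.asarray(v0, float)
    v1 = np.asarray(v1, float)
    chord = v1 - v0
    length = float(np.hypot(*chord))
    if length < 1e-9:
        return np.vstack([v0, v1])
    tangent = chord / length
    normal = np.array([-tangent[1], tangent[0]])
    n_samples = max(8, int(2 * length))
    t = np.linspace(0.0, 1.0, n_samples)
    envelope = np.sin(np.pi * t)
    normal_disp = amplitude * np.sin(2 * np.pi * frequency * t + phase) * envelope
    tangential_disp = (
        0.6 * reentrance * amplitude
        * np.sin(4 * np.pi * frequency * t + phase) * envelope
    )
    pts = (
        v0[None, :]
        + (t * length + tangential_disp)[:, None] * tangent[None, :]
        + normal_disp[:, None] * normal[None, :]
    )
    return pts


def trace_walls(wall_class: WallClass, params: TextureParams) -> list[np.ndarray]:
    """Vector anticlinal walls of the patch, as ordered (x, y) polylines.

    This is the generator's own boundary geometry, prior to rasterization;
    it is what :func:`boundary_tortuosity` validates undulation classes on.
    """
    wall_class = _as_wall_class(wall_class)
    rng = np.random.default_rng(params.seed)
    sites = _mesh_sites(params, rng)
    edges = _voronoi_edges(sites)
    irregular = wall_class.anticlinal in _IRREGULAR
    polylines = []
    for v0, v1 in edges:
        amp = params.undulation_amplitude
        freq = params.undulation_frequency
        # Regular undulation types lobe coherently along a wall; only the
        # irregular classes draw per-edge phase/amplitude/frequency jitter.
        phase = 0.0
        if irregular:
            phase = rng.uniform(0, 2 * np.pi)
            amp = amp * rng.uniform(0.2, 1.6)
            freq = freq * rng.uniform(0.5, 2.0)
        length = float(np.hypot(*(np.asarray(v1) - np.asarray(v0))))
        # Short ridges cannot carry full-amplitude lobes without colliding
        # with neighbouring walls.
        amp = min(amp, 0.35 * length)
        polylines.append(
            _undulated_polyline(v0, v1, amp, freq, params.lobe_reentrance, phase)
        )
    return polylines


def boundary_tortuosity(polyline: Sequence) -> float:
    """Arc length of a polyline divided by its endpoint chord length (>= 1)."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise InvalidInputError("polyline needs at least 2 points")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord < 1e-12:
        raise InvalidInputError("polyline endpoints coincide; chord undefined")
    arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return arc / chord


def mean_wall_tortuosity(wall_class: WallClass, params: TextureParams) -> float:
    """Mean tortuosity over the patch's walls (chord length >= 2 px only)."""
    ts = []
    for poly in trace_walls(wall_class, params):
        if np.linalg.norm(poly[-1] - poly[0]) >= 2.0:
            ts.append(boundary_tortuosity(poly))
    return float(np.mean(ts)) if ts else 1.0


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _paint_polylines(polylines: Iterable[np.ndarray], halfwidth: float) -> np.ndarray:
    """Boolean wall mask: pixels within ``halfwidth`` of any polyline sample."""
    mask = np.zeros((PATCH_SIDE, PATCH_SIDE), dtype=bool)
    r = max(0.5, halfwidth)
    offs = []
    ir = int(math.ceil(r))
    for dy in range(-ir, ir + 1):
        for dx in range(-ir, ir + 1):
            if dx * dx + dy * dy <= r * r:
                offs.append((dy, dx))
    offs = np.array(offs)
    for poly in polylines:
        seg = np.diff(poly, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        n_dense = max(2, int(np.ceil(2 * seglen.sum())))
        t = np.linspace(0, 1, n_dense)
        # arc-length resampling of the polyline
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        total = cum[-1]
        if total < 1e-9:
            continue
        xs = np.interp(t * total, cum, poly[:, 0])
        ys = np.interp(t * total, cum, poly[:, 1])
        cols = np.round(xs).astype(int)
        rows = np.round(ys).astype(int)
        pts = np.column_stack([rows, cols])
        all_pts = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
        keep = (
            (all_pts[:, 0] >= 0) & (all_pts[:, 0] < PATCH_SIDE)
            & (all_pts[:, 1] >= 0) & (all_pts[:, 1] < PATCH_SIDE)
        )
        all_pts = all_pts[keep]
        mask[all_pts[:, 0], all_pts[:, 1]] = True
    return mask


def _place_verrucae(params: TextureParams, polylines: list[np.ndarray],
                    rng: np.random.Generator) -> np.ndarray:
    """Verruca centres via dart throwing with a minimum-separation rule.

    Separation keeps blobs disjoint so the rendered blob count tracks
    ``verruca_count``; 'dense' packs them with the minimal 1-px gap.
    """
    count = params.verruca_count
    if count == 0:
        return np.empty((0, 2))
    r = params.verruca_radius
    gap = 1.0 if params.verruca_placement == "dense" else 3.0
    min_d = 2 * r + gap
    centres: list[np.ndarray] = []

    if params.verruca_placement == "marginal" and polylines:
        lengths = np.array([
            float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
            for p in polylines
        ])
        weights = lengths / lengths.sum() if lengths.sum() > 0 else None

        def propose():
            i = rng.choice(len(polylines), p=weights)
            poly = polylines[i]
            j = rng.integers(0, len(poly) - 1)
            p0, p1 = poly[j], poly[j + 1]
            seg = p1 - p0
            norm = np.linalg.norm(seg)
            if norm < 1e-9:
                return None
            tangent = seg / norm
            normal = np.array([-tangent[1], tangent[0]])
            side = rng.choice([-1.0, 1.0])
            offset = r + params.wall_halfwidth + 2.0
            return p0 + rng.uniform() * seg + side * offset * normal
    else:
        lo, hi = r + 1.0, PATCH_SIDE - r - 1.0

        def propose():
            return rng.uniform(lo, hi, size=2)

    attempts = 0
    max_attempts = 400 * count
    while len(centres) < count and attempts < max_attempts:
        attempts += 1
        c = propose()
        if c is None:
            continue
        if c[0] < r or c[0] > PATCH_SIDE - r or c[1] < r or c[1] > PATCH_SIDE - r:
            continue
        if centres and np.min(np.linalg.norm(np.array(centres) - c, axis=1)) < min_d:
            continue
        centres.append(np.asarray(c, float))
    return np.array(centres) if centres else np.empty((0, 2))


def _bump_mask(centres: np.ndarray, radius: float) -> np.ndarray:
    mask = np.zeros((PATCH_SIDE, PATCH_SIDE), dtype=bool)
    ir = int(math.ceil(radius))
    yy, xx = np.mgrid[-ir:ir + 1, -ir:ir + 1]
    disk = (yy * yy + xx * xx) <= radius * radius
    for cx, cy in centres:
        row, col = int(round(cy)), int(round(cx))
        r0, r1 = row - ir, row + ir + 1
        c0, c1 = col - ir, col + ir + 1
        rr0, rr1 = max(r0, 0), min(r1, PATCH_SIDE)
        cc0, cc1 = max(c0, 0), min(c1, PATCH_SIDE)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        mask[rr0:rr1, cc0:cc1] |= disk[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0]
    return mask


@dataclasses.dataclass
class RenderLayers:
    """Intermediate render products, exposed for validation."""

    walls: list[np.ndarray]
    wall_mask: np.ndarray
    bump_mask: np.ndarray
    clean: np.ndarray
    raster: np.ndarray


def render_layers(wall_class: WallClass, params: TextureParams) -> RenderLayers:
    """Render a patch and return all intermediate layers.

    The random stream is consumed in a fixed order (mesh → wall phases →
    verruca placement → noise), so the output is a pure function of
    (wall_class, params).
    """
    wall_class = _as_wall_class(wall_class)
    polylines = trace_walls(wall_class, params)

    # trace_walls consumed the mesh/phase part of the stream; reproduce the
    # same state for the placement/noise part by re-deriving a child seed.
    rng = np.random.default_rng(derive_seed(params.seed, "placement"))

    wall_mask = _paint_polylines(polylines, params.wall_halfwidth)
    centres = _place_verrucae(params, polylines, rng)
    bump_mask = _bump_mask(centres, params.verruca_radius)

    clean = np.full((PATCH_SIDE, PATCH_SIDE), params.interior_level)
    clean[bump_mask] += _BUMP_GAIN
    clean[wall_mask] = _WALL_LEVEL
    clean = np.clip(clean, 0.0, 1.0)

    raster = clean
    if params.blur_sigma > 0:
        raster = ndimage.gaussian_filter(raster, params.blur_sigma)
    if params.noise_sd > 0:
        noise_rng = np.random.default_rng(derive_seed(params.seed, "noise"))
        raster = raster + noise_rng.normal(0.0, params.noise_sd, raster.shape)
    raster = np.clip(raster, 0.0, 1.0)
    return RenderLayers(polylines, wall_mask, bump_mask, clean, raster)


def generate_image(wall_class: WallClass, params: TextureParams,
                   image_id: str | None = None) -> SeedImage:
    """Generate one labelled synthetic testa patch."""
    wall_class = _as_wall_class(wall_class)
    layers = render_layers(wall_class, params)
    if image_id is None:
        image_id = f"{wall_class.label}#{params.seed}"
    return SeedImage(id=image_id, raster=layers.raster, truth=wall_class,
                     provenance="synthetic")


def _normalize_class_spec(class_spec) -> list[tuple[WallClass, int, dict]]:
    entries = []
    for entry in class_spec:
        if len(entry) == 2:
            wc, count = entry
            overrides: dict = {}
        elif len(entry) == 3:
            wc, count, overrides = entry
            overrides = dict(overrides or {})
        else:
            raise InvalidInputError(
                "class_spec entries must be (WallClass, count[, overrides])"
            )
        wc = _as_wall_class(wc)
        if int(count) < 1:
            raise InvalidInputError("per-class counts must be >= 1")
        entries.append((wc, int(count), overrides))
    if not entries:
        raise InvalidInputError("class_spec must not be empty")
    return entries


def generate_dataset(class_spec, base_params: TextureParams | None = None,
                     seed: int = 0) -> list[SeedImage]:
    """Generate a labelled dataset from a per-class specification.

    ``class_spec`` is a list of ``(WallClass, count)`` or
    ``(WallClass, count, overrides)`` entries.  Per-class morphology fields
    come from the default table; ``base_params``, if given, supplies the
    scene fields (cell_count, jitter, noise, blur); per-entry overrides win
    over both.  Per-image seeds are derived deterministically from ``seed``.
    """
    entries = _normalize_class_spec(class_spec)
    base_overrides: dict = {}
    if base_params is not None:
        for name in ("cell_count", "mesh_jitter", "wall_halfwidth",
                     "noise_sd", "blur_sigma"):
            base_overrides[name] = getattr(base_params, name)
    images = []
    index = 0
    for wc, count, overrides in entries:
        for rep in range(count):
            img_seed = derive_seed(seed, "image", index)
            merged = dict(base_overrides)
            merged.update(overrides)
            params = default_params(wc, seed=img_seed, **merged)
            images.append(generate_image(wc, params, image_id=f"img{index:04d}"))
            index += 1
    return images


def well_separated_triple() -> list[tuple[WallClass, int, dict]]:
    """Three morphologically well-separated classes (template, count = 1 each).

    The classes differ simultaneously in cell size and wall thickness,
    anticlinal undulation and periclinal sculpture, so all three downstream
    representations carry a class signal.  Scale counts as needed, e.g.
    ``[(wc, 20, ov) for wc, _, ov in well_separated_triple()]``.
    """
    return [
        (WallClass(Anticlinal.STRAIGHT, Periclinal.GRANULE), 1,
         dict(cell_count=6, wall_halfwidth=1.0)),
        (WallClass(Anticlinal.U, Periclinal.SMALL_VERRUCAE), 1,
         dict(cell_count=20, wall_halfwidth=1.8)),
        (WallClass(Anticlinal.OMEGA, Periclinal.LARGE_VERRUCAE), 1,
         dict(cell_count=42, wall_halfwidth=2.6)),
    ]


# ---------------------------------------------------------------------------
# Disk I/O: 8-bit grayscale PNG + labels CSV
# ---------------------------------------------------------------------------

def write_dataset(images: Sequence[SeedImage], out_dir) -> Path:
    """Write images as 8-bit grayscale PNGs plus a labels CSV; returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        arr = np.clip(np.round(img.raster * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / f"{img.id}.png")
        rows.append({
            "id": img.id,
            "anticlinal": img.truth.anticlinal.value if img.truth else "",
            "periclinal": img.truth.periclinal.value if img.truth else "",
            "provenance": img.provenance,
        })
    csv_path = out / "labels.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path


def load_dataset(in_dir) -> list[SeedImage]:
    """Load a PNG directory written by :func:`write_dataset` (labels CSV optional)."""
    in_dir = Path(in_dir)
    truth_map: dict[str, WallClass] = {}
    csv_path = in_dir / "labels.csv"
    if csv_path.exists():
        df = pd.read_csv(csv_path).fillna("")
        for _, row in df.iterrows():
            if row.get("anticlinal") and row.get("periclinal"):
                truth_map[str(row["id"])] = WallClass(row["anticlinal"],
                                                      row["periclinal"])
    images = []
    for png in sorted(in_dir.glob("*.png")):
        arr = np.asarray(Image.open(png).convert("L"), dtype=float) / 255.0
        images.append(SeedImage(id=png.stem, raster=arr,
                                truth=truth_map.get(png.stem),
                                provenance="external"))
    if not images:
        raise InvalidInputError(f"no PNG images found in {in_dir}")
    return images
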