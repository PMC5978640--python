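"""Dimensioned phantom geometry for the tomosynthesis QA phantom.

Coordinate frame (fixed here, used everywhere else in the package):

* ``x`` — lateral, mm, zero at the phantom mid-line;
* ``y`` — depth from the chest wall, mm, the chest-wall plane is ``y = 0``;
* ``z`` — through-plane (slice) direction, mm, zero at the bottom of the
  42 mm assembly;
* right-handed, all lengths in mm.

The module holds no image processing: it only describes where every test
object sits and serialises that description to/from JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "StepGauge",
    "BeadRamp",
    "PhantomGeometry",
    "default_geometry",
    "bead_positions",
]

GEOMETRY_SCHEMA_VERSION = 1

#: z of the central test-object plane for the default 42 mm assembly.
CENTRAL_PLANE_Z = 21.0


@dataclass(frozen=True)
class StepGauge:
    """A stair-step chest-wall gauge.

    Twelve steps in 0.5 mm increments rise into the phantom from the chest
    wall, so the full gauge extent is 6 mm; counting the visible steps
    measures missing tissue at the chest wall.
    """

    gauge_id: str
    lateral_position: float  # x of the gauge centreline, mm
    n_steps: int = 12
    step_increment: float = 0.5  # mm of depth per step
    width: float = 2.0  # lateral extent of each step, mm
    thickness: float = 2.0  # through-plane extent, mm
    z_center: float = CENTRAL_PLANE_Z
    contrast: float = 0.6  # fraction of background level

    def __post_init__(self) -> None:
        if self.n_steps <= 0 or self.step_increment <= 0:
            raise ValueError("n_steps and step_increment must be positive")

    @property
    def full_extent(self) -> float:
        """Full gauge depth: n_steps x step_increment (default 6.0 mm)."""
        return self.n_steps * self.step_increment

    def step_y_interval(self, index: int) -> tuple[float, float]:
        """Depth interval [y0, y1) covered by step ``index`` (0 at the wall)."""
        if not 0 <= index < self.n_steps:
            raise IndexError(f"step index {index} out of range")
        y0 = index * self.step_increment
        return (y0, y0 + self.step_increment)


@dataclass(frozen=True)
class BeadRamp:
    """A folded (reversing) bead ramp set.

    Each set holds two laterally offset limbs of 0.18 mm beads spaced
    0.25 mm vertically; the pair rises ``total_rise`` (10 mm) in z.  The
    top bead of the lower limb sits one vertical spacing below the bottom
    bead of the upper limb.  Ramps on the right side of the phantom run
    opposite to those on the left.
    """

    ramp_id: str
    side: str  # "left" | "right"
    lateral_position: float  # x midway between the two limbs, mm
    y_start: float  # chest-wall-ward end of the ramp run, mm
    bead_diameter: float = 0.18
    vertical_spacing: float = 0.25  # z spacing between consecutive beads
    total_rise: float = 10.0  # z span of the folded set
    bead_pitch: float = 2.0  # in-plane spacing between consecutive beads, mm
    limb_offset: float = 1.0  # lateral offset between the two limbs, mm
    z_center: float = CENTRAL_PLANE_Z
    contrast: float = 25.0

    def __post_init__(self) -> None:
        if self.vertical_spacing <= 0:
            raise ValueError("vertical_spacing must be positive")
        if self.total_rise < 0:
            raise ValueError("total_rise must be non-negative")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def n_beads_lower(self) -> int:
        """Beads on the lower limb: floor(rise / (2 spacing)) + 1."""
        return int(np.floor(self.total_rise / (2 * self.vertical_spacing))) + 1

    @property
    def n_beads_upper(self) -> int:
        """Beads on the upper limb; fills the remaining rise exactly.

        The upper limb starts one vertical spacing above the lower limb's
        top bead and its top bead closes the full ``total_rise``, so the
        folded set spans exactly 10 mm by default (41 beads: 21 + 20).
        """
        if self.total_rise == 0:
            return 0
        lower_top = (self.n_beads_lower - 1) * self.vertical_spacing
        remaining = self.total_rise - lower_top - self.vertical_spacing
        if remaining < 0:
            return 0
        return int(np.floor(remaining / self.vertical_spacing + 1e-9)) + 1


def bead_positions(ramp: BeadRamp) -> np.ndarray:
    """Return the (n, 3) xyz positions (mm) of every bead in a folded set.

    Beads are ordered by increasing z.  Within each limb the z step between
    consecutive beads equals ``vertical_spacing``; the fold reverses the
    in-plane run direction and applies the lateral limb offset.
    """
    if ramp.vertical_spacing <= 0:
        raise ValueError("vertical_spacing must be positive")
    sgn = 1.0 if ramp.side == "left" else -1.0
    z0 = ramp.z_center - ramp.total_rise / 2.0
    x_lower = ramp.lateral_position - ramp.limb_offset / 2.0
    x_upper = ramp.lateral_position + ramp.limb_offset / 2.0

    pts = []
    n1 = ramp.n_beads_lower
    for j in range(n1):
        y = ramp.y_start + sgn * j * ramp.bead_pitch
        pts.append((x_lower, y, z0 + j * ramp.vertical_spacing))
    lower_top = z0 + (n1 - 1) * ramp.vertical_spacing
    n2 = ramp.n_beads_upper
    for m in range(n2):
        # fold: the upper limb runs back toward the chest wall
        y = ramp.y_start + sgn * (n1 - 1 - m) * ramp.bead_pitch
        pts.append((x_upper, y, lower_top + (m + 1) * ramp.vertical_spacing))
    return np.asarray(pts, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class Sphere:
    """A spherical insert (low-contrast sphere, z-geometry bead or marker)."""

    center: tuple[float, float, float]  # xyz mm
    diameter: float  # mm
    contrast: float  # fraction of background level


@dataclass(frozen=True)
class Box:
    """An axis-aligned rectangular insert (aluminium square)."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]  # full extents along x, y, z (mm)
    contrast: float


@dataclass(frozen=True)
class PhantomGeometry:
    """Complete dimensioned description of the phantom's test objects."""

    overall_thickness: float = 42.0  # z extent of the assembly, mm
    x_range: tuple[float, float] = (-32.0, 32.0)
    y_range: tuple[float, float] = (0.0, 96.0)
    gauges: tuple[StepGauge, ...] = ()
    ramps: tuple[BeadRamp, ...] = ()
    z_beads: tuple[Sphere, ...] = ()
    low_contrast_spheres: tuple[Sphere, ...] = ()
    al_square: Box | None = None
    alignment_markers: tuple[Sphere, ...] = ()
    background_attenuation: float = 1.0  # relative scale of the slab body
    schema_version: int = GEOMETRY_SCHEMA_VERSION

    # chest-wall plane is y = 0 by construction of the frame

    def __post_init__(self) -> None:
        if self.overall_thickness <= 0:
            raise ValueError("overall_thickness must be positive")
        lo, hi = self.bounding_box()
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("geometry bounds must be finite")
        for s in (*self.z_beads, *self.low_contrast_spheres,
                  *self.alignment_markers):
            self._check_inside(np.asarray(s.center), s.diameter / 2.0)
        if self.al_square is not None:
            self._check_inside(np.asarray(self.al_square.center),
                               max(self.al_square.size) / 2.0)

    def _check_inside(self, center: np.ndarray, radius: float) -> None:
        x0, x1 = self.x_range
        y0, y1 = self.y_range
        ok = (x0 - 1e-9 <= center[0] - radius and center[0] + radius <= x1 + 1e-9
              and y0 - 1e-9 <= center[1] - radius
              and center[1] + radius <= y1 + 1e-9
              and -1e-9 <= center[2] - radius
              and center[2] + radius <= self.overall_thickness + 1e-9)
        if not ok:
            raise ValueError(
                f"object at {tuple(center)} (radius {radius}) lies outside "
                f"the phantom bounding box")

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the phantom volume, xyz mm."""
        lo = np.array([self.x_range[0], self.y_range[0], 0.0])
        hi = np.array([self.x_range[1], self.y_range[1],
                       self.overall_thickness])
        return lo, hi

    @property
    def center(self) -> np.ndarray:
        lo, hi = self.bounding_box()
        return (lo + hi) / 2.0

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = self.schema_version
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomGeometry":
        d = dict(d)
        version = d.pop("schema_version", GEOMETRY_SCHEMA_VERSION)
        if version != GEOMETRY_SCHEMA_VERSION:
            raise ValueError(f"unsupported geometry schema version {version}")

        def _tup(x):
            return tuple(x)

        gauges = tuple(StepGauge(**g) for g in d.pop("gauges", []))
        ramps = tuple(BeadRamp(**r) for r in d.pop("ramps", []))

        def _spheres(key):
            return tuple(
                Sphere(center=_tup(s["center"]), diameter=s["diameter"],
                       contrast=s["contrast"]) for s in d.pop(key, []))

        z_beads = _spheres("z_beads")
        lcs = _spheres("low_contrast_spheres")
        markers = _spheres("alignment_markers")
        sq = d.pop("al_square", None)
        al = (Box(center=_tup(sq["center"]), size=_tup(sq["size"]),
                  contrast=sq["contrast"]) if sq else None)
        return cls(gauges=gauges, ramps=ramps, z_beads=z_beads,
                   low_contrast_spheres=lcs, al_square=al,
                   alignment_markers=markers,
                   x_range=_tup(d.pop("x_range")),
                   y_range=_tup(d.pop("y_range")),
                   schema_version=version, **d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- default layout -------------------------------------------------------

#: Diameters of the nine low-contrast spheres, mm.
LOW_CONTRAST_DIAMETERS = (0.8, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)

#: Order in which sphere diameters are placed around the circle; chosen so
#: that large spheres are never adjacent (the circle could not hold two
#: 10 mm-class neighbours) and a small sphere sits nearest the CNR
#: background ROI.  x/y placements are not fully dimensioned in the
#: published drawings; this layout preserves the topology (spheres on a
#: circle, aluminium square just inside it, ramps left and right of
#: centre, gauges along the chest wall) and is configurable.
_SPHERE_ORDER = (1.0, 1.5, 0.8, 10.0, 2.0, 8.0, 3.0, 6.0, 4.0)

SPHERE_CIRCLE_CENTER = (0.0, 30.0)  # xy, mm
SPHERE_CIRCLE_RADIUS = 14.0  # mm


def default_geometry(
    *,
    sphere_contrast: float = 0.02,
    al_square_contrast: float = 0.20,
) -> PhantomGeometry:
    """Build the default phantom geometry.

    Printed dimensions: four 12-step gauges at 0.5 mm increments; two
    folded bead ramps of 0.18 mm beads at 0.25 mm vertical spacing rising
    10 mm; three 5 mm aluminium z-geometry beads spaced 10 mm in z; nine
    low-contrast spheres of 0.8-10 mm on a circle; an aluminium square
    just inside the circle.  Contrast fractions are effective-contrast
    modelling defaults (spheres +2 %, aluminium square +20 % of
    background), not printed values.
    """
    zc = CENTRAL_PLANE_Z
    gauges = tuple(
        StepGauge(gauge_id=f"gauge_{i}", lateral_position=x)
        for i, x in enumerate((-24.0, -8.0, 8.0, 24.0)))
    ramps = (
        BeadRamp(ramp_id="ramp_left", side="left", lateral_position=-24.0,
                 y_start=10.0),
        BeadRamp(ramp_id="ramp_right", side="right", lateral_position=24.0,
                 y_start=50.0),
    )
    z_beads = tuple(
        Sphere(center=(20.0, 64.0, z), diameter=5.0, contrast=3.0)
        for z in (zc - 10.0, zc, zc + 10.0))

    cx, cy = SPHERE_CIRCLE_CENTER
    r = SPHERE_CIRCLE_RADIUS
    spheres = []
    for k, d in enumerate(_SPHERE_ORDER):
        ang = np.deg2rad(90.0 + 40.0 * k)
        spheres.append(Sphere(center=(cx + r * np.cos(ang),
                                      cy + r * np.sin(ang), zc),
                              diameter=d, contrast=sphere_contrast))
    al_square = Box(center=(cx, cy, zc), size=(10.0, 10.0, 2.0),
                    contrast=al_square_contrast)
    markers = (
        Sphere(center=(-29.0, 8.0, zc - 3.0), diameter=3.0, contrast=1.0),
        Sphere(center=(29.0, 8.0, zc + 3.0), diameter=3.0, contrast=1.0),
        Sphere(center=(-29.0, 91.0, zc + 3.0), diameter=3.0, contrast=1.0),
        Sphere(center=(29.0, 91.0, zc - 3.0), diameter=3.0, contrast=1.0),
    )
    return PhantomGeometry(gauges=gauges, ramps=ramps, z_beads=z_beads,
                           low_contrast_spheres=tuple(spheres),
                           al_square=al_square, alignment_markers=markers)


def bundled_geometry_path() -> Path:
    """Path of the bundled default-geometry JSON document."""
    return Path(__file__).parent / "data" / "default_geometry.json"


def object_footprints(geometry: PhantomGeometry) -> list[tuple[str, str, np.ndarray, tuple]]:
    """In-plane footprints of every test object.

    Each entry is (name, kind, xy centre, params): kind ``circle`` with
    params (radius,), or kind ``rect`` with params (half_x, half_y).
    Used to keep uniformity / noise ROIs clear of test objects.
    """
    out: list[tuple[str, str, np.ndarray, tuple]] = []
    for s in geometry.low_contrast_spheres:
        out.append(("sphere", "circle", np.asarray(s.center[:2]),
                    (s.diameter / 2.0,)))
    for s in geometry.z_beads:
        out.append(("z_bead", "circle", np.asarray(s.center[:2]),
                    (s.diameter / 2.0,)))
    for s in geometry.alignment_markers:
        out.append(("marker", "circle", np.asarray(s.center[:2]),
                    (s.diameter / 2.0,)))
    if geometry.al_square is not None:
        b = geometry.al_square
        out.append(("al_square", "rect", np.asarray(b.center[:2]),
                    (b.size[0] / 2.0, b.size[1] / 2.0)))
    for g in geometry.gauges:
        out.append((g.gauge_id, "rect",
                    np.array([g.lateral_position, g.full_extent / 2.0]),
                    (g.width / 2.0, g.full_extent / 2.0)))
    for ramp in geometry.ramps:
        for p in bead_positions(ramp):
            out.append((ramp.ramp_id, "circle", p[:2],
                        (ramp.bead_diameter / 2.0 + 0.5,)))
    return out


def footprint_distance(point_xy, kind: str, center: np.ndarray,
                       params: tuple) -> float:
    """Distance from a point to a footprint boundary (0 if inside)."""
    p = np.asarray(point_xy, dtype=float)
    if kind == "circle":
        return max(float(np.linalg.norm(p - center)) - params[0], 0.0)
    d = np.maximum(np.abs(p - center) - np.asarray(params), 0.0)
    return float(np.linalg.norm(d))
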