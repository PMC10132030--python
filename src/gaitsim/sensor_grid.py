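"""Systematic sensor placement grids on cylindrical limb surrogates and shoes.

Leg segments are approximated by cylinders whose long axis is the local y
(limb) axis with the segment origin at the proximal joint; the limb extends
towards negative y.  Each leg grid has ``n_rings`` rings equally spaced along
the axis and ``n_slots`` slots equally spaced in azimuth.  Slot S1 sits at
the ventral (anterior, +x) azimuth 0; slot numbering increases towards the
lateral side (+z first).

The shoe is a non-deformable elliptical outline in the local x-z plane with
three rings stacked along y.  The printed default ring sizes (36, 36, 25)
sum to 97 and contradict the twice-stated totals of 96 per shoe and 960
overall; the default profile here is **(36, 35, 25)** so that the totals
hold.  Override ``ring_sizes`` to explore other profiles (must sum to 96).

Sensor mount frames: sensor x = outward surface normal, sensor y = limb
axis, sensor z = x cross y.  For a ventral leg sensor the mount rotation is
the identity, so sensor y reads the vertical acceleration and sensor z the
medio-lateral angular velocity during upright sagittal gait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, GeometryError, UnsupportedGridError

LEG_SEGMENT_TYPES = ("upper_leg", "lower_leg")

#: default cylinder geometry (length, radius) in metres per segment type,
#: anthropometric proportions for a ~1.8 m body
DEFAULT_LEG_GEOMETRY = {
    "upper_leg": (0.44, 0.075),
    "lower_leg": (0.44, 0.055),
}

DEFAULT_SHOE_RING_SIZES = (36, 35, 25)

#: shoe outline semi-axes (x longitudinal, z transversal) and ring heights [m]
_SHOE_A, _SHOE_B = 0.14, 0.05
_SHOE_RING_HEIGHTS = (0.03, 0.06, 0.09)


def _is_leg_segment(segment_id: str) -> bool:
    return segment_id.rsplit("_", 1)[0] in LEG_SEGMENT_TYPES or any(
        segment_id.startswith(st) for st in LEG_SEGMENT_TYPES)


@dataclass(eq=False)
class SensorPlacement:
    """One virtual sensor bound to a segment.

    ``ring``/``slot`` are 1-based indices; ``offset_local`` is the vector
    from the segment origin in the segment-local frame [m];
    ``mount_rotation`` maps segment-local vectors into the sensor frame.
    """

    segment_id: str
    ring: int
    slot: int
    offset_local: np.ndarray
    mount_rotation: np.ndarray
    region: str | None = None

    @property
    def key(self) -> tuple:
        return (self.segment_id, self.ring, self.slot)


@dataclass
class SensorGrid:
    """A collection of placements plus the surrogate geometry that bred them."""

    placements: list[SensorPlacement]
    geometry: dict = field(default_factory=dict)
    kind: str = "leg"  # "leg" | "shoe" | "mixed"

    def __len__(self) -> int:
        return len(self.placements)

    @property
    def spacing(self) -> float:
        """Maximum nearest-neighbour distance between placements [m]."""
        pts = np.array([p.offset_local for p in self.placements])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return float(np.max(np.min(d, axis=1)))

    def find(self, segment_id: str, ring: int, slot: int) -> SensorPlacement:
        for p in self.placements:
            if p.key == (segment_id, ring, slot):
                return p
        raise KeyError((segment_id, ring, slot))


def _ring_frame(azimuth: float) -> np.ndarray:
    """Mount rotation (local -> sensor) for a cylinder surface point.

    The sensor x axis is aligned with the surface-normal line: facing
    outward on the ventral half of the ring and inward on the dorsal half
    (the minimal rotation from the segment frame).  No sensor is mounted
    upside down: sensor y stays the limb axis and sensor z keeps a
    non-negative medio-lateral component, degenerating to the
    anterior-posterior axis only at the exactly medial/lateral slots.
    """
    az = np.mod(azimuth + np.pi, 2.0 * np.pi) - np.pi  # wrap to (-pi, pi]
    if abs(az) > np.pi / 2:
        az -= np.sign(az) * np.pi  # dorsal half: face inward
    c, s = np.cos(az), np.sin(az)
    x_s = np.array([c, 0.0, s])        # surface-normal line
    y_s = np.array([0.0, 1.0, 0.0])    # limb axis
    z_s = np.cross(x_s, y_s)
    return np.vstack([x_s, y_s, z_s])  # rows = sensor axes in local coords


def build_leg_grid(segment_id: str, length: float | None = None,
                   radius: float | None = None, n_rings: int = 12,
                   n_slots: int = 16) -> SensorGrid:
    """Build the default 12x16 cylindrical grid for one leg segment."""
    seg_type = segment_id.rsplit("_", 1)[0]
    if length is None or radius is None:
        default = DEFAULT_LEG_GEOMETRY.get(seg_type, DEFAULT_LEG_GEOMETRY["lower_leg"])
        length = default[0] if length is None else length
        radius = default[1] if radius is None else radius
    if length <= 0 or radius <= 0 or n_rings < 1 or n_slots < 1:
        raise GeometryError("length, radius, n_rings, n_slots must be positive")
    placements = []
    for r in range(1, n_rings + 1):
        # ring centres equally spaced along the limb axis, R1 proximal
        y = -length * (r - 0.5) / n_rings
        for s in range(1, n_slots + 1):
            az = 2.0 * np.pi * (s - 1) / n_slots
            offset = np.array([radius * np.cos(az), y, radius * np.sin(az)])
            placements.append(SensorPlacement(
                segment_id=segment_id, ring=r, slot=s,
                offset_local=offset, mount_rotation=_ring_frame(az)))
    return SensorGrid(placements=placements, kind="leg",
                      geometry={"segment_id": segment_id, "length": length,
                                "radius": radius, "n_rings": n_rings,
                                "n_slots": n_slots})


def _shoe_frame(a: float, b: float, theta: float) -> np.ndarray:
    """Mount rotation for a point on the elliptical shoe outline."""
    n = np.array([np.cos(theta) / a, 0.0, np.sin(theta) / b])
    x_s = n / np.linalg.norm(n)
    y_s = np.array([0.0, 1.0, 0.0])
    z_s = np.cross(x_s, y_s)
    return np.vstack([x_s, y_s, z_s])


def _shoe_region(ring: int, n_rings: int, theta: float) -> str | None:
    """Label instep (top ring, anterior) and heel (posterior) regions."""
    th = np.mod(theta + np.pi, 2 * np.pi) - np.pi  # wrap to (-pi, pi]
    if abs(th) > 5 * np.pi / 6:
        return "heel"
    if ring == n_rings and abs(th) < np.pi / 4:
        return "instep"
    return None


def build_shoe_grid(segment_id: str = "shoe_left",
                    ring_sizes: tuple[int, ...] = DEFAULT_SHOE_RING_SIZES) -> SensorGrid:
    """Build the 96-sensor shoe grid (three rings on a closed outline)."""
    if sum(ring_sizes) != 96:
        raise ConfigError(f"shoe ring sizes {ring_sizes} must sum to 96")
    placements = []
    n_rings = len(ring_sizes)
    for r, n in enumerate(ring_sizes, start=1):
        y = _SHOE_RING_HEIGHTS[(r - 1) % len(_SHOE_RING_HEIGHTS)]
        for s in range(1, n + 1):
            theta = 2.0 * np.pi * (s - 1) / n
            offset = np.array([_SHOE_A * np.cos(theta), y,
                               _SHOE_B * np.sin(theta)])
            placements.append(SensorPlacement(
                segment_id=segment_id, ring=r, slot=s, offset_local=offset,
                mount_rotation=_shoe_frame(_SHOE_A, _SHOE_B, theta),
                region=_shoe_region(r, n_rings, theta)))
    return SensorGrid(placements=placements, kind="shoe",
                      geometry={"segment_id": segment_id,
                                "ring_sizes": tuple(ring_sizes),
                                "a": _SHOE_A, "b": _SHOE_B})


def build_default_grid() -> SensorGrid:
    """Full default grid: 192 sensors on each of the four leg segments plus
    96 on each shoe, 960 placements in total."""
    placements: list[SensorPlacement] = []
    geometry: dict = {}
    for side in ("left", "right"):
        for seg_type in LEG_SEGMENT_TYPES:
            g = build_leg_grid(f"{seg_type}_{side}")
            placements += g.placements
            geometry[f"{seg_type}_{side}"] = g.geometry
        g = build_shoe_grid(f"shoe_{side}")
        placements += g.placements
        geometry[f"shoe_{side}"] = g.geometry
    return SensorGrid(placements=placements, kind="mixed", geometry=geometry)


def _require_leg(grid: SensorGrid) -> None:
    if grid.kind != "leg" or not all(_is_leg_segment(p.segment_id)
                                     for p in grid.placements):
        raise UnsupportedGridError(
            "rotatory/translatory selection is defined for leg grids only "
            "(shoe grids are excluded: asymmetric distribution)")


def select_rotatory(grid: SensorGrid, ring: int = 1) -> list[SensorPlacement]:
    """All slots of one ring: a uniaxial sensor rotation around the limb."""
    _require_leg(grid)
    return [p for p in grid.placements if p.ring == ring]


def select_translatory(grid: SensorGrid, slot: int = 1) -> list[SensorPlacement]:
    """One slot across all rings: a uniaxial translation along the limb."""
    _require_leg(grid)
    return [p for p in grid.placements if p.slot == slot]
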