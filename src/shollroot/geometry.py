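"""Vector root-system geometry and analytic Sholl profiling.

A root system is modelled as a primary axis polyline rooted at the origin
plus first-order lateral polylines attached at arclength positions along the
primary.  Coordinates are in cm with y positive downward (image row
convention), the origin being the hypocotyl/root junction the concentric
Sholl circles are centred on.

The central primitive is an exact count of transversal crossings between a
polyline and a circle of radius ``r`` centred at the origin.  A crossing is
a strict sign change of ``distance - r`` along the path.  Points lying
exactly on a circle are classified as *outside* (``distance >= r``), which
makes counts well defined when a branch point or root tip falls exactly on a
circle; tangential touches (a local distance extremum exactly at ``r``)
therefore contribute no crossing.  Because the distance to the origin is
convex along a straight segment, a single segment can cross a circle at most
twice, and sampling each segment at its endpoints plus its interior distance
minimum captures every sign change exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidParameterError",
    "InvalidInputError",
    "Polyline",
    "RootSystem",
    "RootTraits",
    "ShollGrid",
    "ShollProfile",
    "circle_crossings",
    "circle_crossings_multi",
    "circle_crossing_points",
    "analytic_sholl",
    "extract_traits",
    "auto_end_radius",
]


class InvalidParameterError(ValueError):
    """A scalar parameter (radius, step, distribution moment) is out of range."""


class InvalidInputError(ValueError):
    """A structured input (polyline, root system, image) violates an invariant."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("polyline points must be an (n, 2) array")
    return pts


@dataclass(frozen=True)
class Polyline:
    """An ordered open polygonal chain in the (x, y-down) plane, cm units.

    Invariants: at least two points, all finite, consecutive points distinct
    (hence positive arclength).
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = _as_points(self.points)
        if len(pts) < 2:
            raise InvalidInputError("polyline needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("polyline coordinates must be finite")
        steps = np.diff(pts, axis=0)
        if np.any(np.all(steps == 0.0, axis=1)):
            raise InvalidInputError("consecutive polyline points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def segment_lengths(self) -> np.ndarray:
        d = np.diff(self.points, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def arclength(self) -> float:
        return float(np.sum(self.segment_lengths))

    @property
    def vertex_distances(self) -> np.ndarray:
        """Distance of every vertex from the origin."""
        return np.hypot(self.points[:, 0], self.points[:, 1])

    def point_at_arclength(self, s: float) -> np.ndarray:
        """Linear interpolation of the point at arclength ``s`` from the start."""
        cum = np.concatenate([[0.0], np.cumsum(self.segment_lengths)])
        if s < -1e-12 or s > cum[-1] + 1e-12:
            raise InvalidParameterError(
                f"arclength {s} outside [0, {cum[-1]}]"
            )
        s = min(max(s, 0.0), cum[-1])
        i = int(np.searchsorted(cum, s, side="right")) - 1
        i = min(i, len(cum) - 2)
        seg = cum[i + 1] - cum[i]
        t = 0.0 if seg == 0 else (s - cum[i]) / seg
        return self.points[i] + t * (self.points[i + 1] - self.points[i])

    def transformed(self, rotation: float = 0.0, about: tuple[float, float] = (0.0, 0.0)) -> "Polyline":
        """Rigid rotation by ``rotation`` radians about the point ``about``."""
        c, s = np.cos(rotation), np.sin(rotation)
        rot = np.array([[c, -s], [s, c]])
        centre = np.asarray(about, dtype=float)
        return Polyline((self.points - centre) @ rot.T + centre)


@dataclass(frozen=True)
class RootSystem:
    """Primary axis plus first-order laterals attached along it.

    The primary starts at the origin; each lateral's first point coincides
    (within 1e-9 cm) with the primary point at its branch arclength.
    """

    primary: Polyline
    laterals: tuple = ()

    def __post_init__(self) -> None:
        lats = tuple((float(s), axis) for s, axis in self.laterals)
        object.__setattr__(self, "laterals", lats)
        if np.hypot(*self.primary.points[0]) > 1e-9:
            raise InvalidInputError("primary axis must start at the origin")
        prl = self.primary.arclength
        for s, axis in lats:
            if not (-1e-12 <= s <= prl + 1e-12):
                raise InvalidInputError(
                    f"branch arclength {s} outside primary [0, {prl}]"
                )
            attach = self.primary.point_at_arclength(min(max(s, 0.0), prl))
            if np.hypot(*(axis.points[0] - attach)) > 1e-9:
                raise InvalidInputError(
                    "lateral start does not coincide with its branch point"
                )

    @property
    def axes(self) -> list[Polyline]:
        return [self.primary] + [axis for _, axis in self.laterals]

    @property
    def extent(self) -> float:
        """Maximum distance of any root point from the origin (attained at a vertex)."""
        return float(max(ax.vertex_distances.max() for ax in self.axes))

    def to_dict(self) -> dict:
        return {
            "primary": self.primary.points.tolist(),
            "laterals": [
                {"branch_arclength": s, "points": axis.points.tolist()}
                for s, axis in self.laterals
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RootSystem":
        return cls(
            primary=Polyline(d["primary"]),
            laterals=tuple(
                (lat["branch_arclength"], Polyline(lat["points"]))
                for lat in d["laterals"]
            ),
        )


@dataclass(frozen=True)
class RootTraits:
    """Per-plant root architecture traits (cm).

    RL = PRL + LRL; MLRL = LRL / NLR (0 when there are no laterals);
    ``extent`` is the largest origin distance of any root point.
    """

    RL: float
    PRL: float
    LRL: float
    MLRL: float
    NLR: int
    extent: float

    def as_dict(self) -> dict:
        return {
            "RL": self.RL, "PRL": self.PRL, "LRL": self.LRL,
            "MLRL": self.MLRL, "NLR": self.NLR, "extent": self.extent,
        }


@dataclass(frozen=True)
class ShollGrid:
    """Linear concentric-circle grid: radii start, start+step, ... <= end."""

    end_radius: float
    start_radius: float = 0.5
    step: float = 0.5

    def __post_init__(self) -> None:
        if self.start_radius <= 0 or self.step <= 0:
            raise InvalidParameterError("start_radius and step must be positive")
        if self.end_radius < self.start_radius - 1e-12:
            raise InvalidParameterError("end_radius must be >= start_radius")

    @property
    def radii(self) -> np.ndarray:
        n = int(np.floor((self.end_radius - self.start_radius) / self.step + 1e-9)) + 1
        return self.start_radius + self.step * np.arange(n)


@dataclass(frozen=True)
class ShollProfile:
    """Per-radius intersection counts I_k aligned to grid radii."""

    radii: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        if radii.shape != counts.shape or radii.ndim != 1:
            raise InvalidInputError("radii and counts must be 1-d of equal length")
        if np.any(counts < 0):
            raise InvalidInputError("intersection counts must be non-negative")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        """I_T: the sum of intersections over all circles."""
        return int(self.counts.sum())


def _sample_distances(points: np.ndarray) -> np.ndarray:
    """Origin distances at vertices interleaved with interior segment minima.

    Distance is convex along each straight segment, so this sequence captures
    every strict sign change of (distance - r) for any radius r.
    """
    d = np.hypot(points[:, 0], points[:, 1])
    a = points[:-1]
    ab = np.diff(points, axis=0)
    denom = np.einsum("ij,ij->i", ab, ab)
    tstar = -np.einsum("ij,ij->i", a, ab) / denom
    interior = (tstar > 0.0) & (tstar < 1.0)
    if not interior.any():
        return d
    mins = a[interior] + tstar[interior, None] * ab[interior]
    mdist = np.hypot(mins[:, 0], mins[:, 1])
    # interleave: vertex i sits after all interior minima of earlier segments
    n = len(d)
    offsets = np.concatenate([[0], np.cumsum(interior)])
    pos = np.arange(n) + offsets
    out = np.empty(n + int(interior.sum()))
    out[pos] = d
    out[pos[:-1][interior] + 1] = mdist
    return out


def circle_crossings_multi(axis: Polyline, radii) -> np.ndarray:
    """Crossing counts of one polyline against many origin-centred circles."""
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii <= 0):
        raise InvalidParameterError("circle radii must be positive")
    samples = _sample_distances(axis.points)
    sgn = np.sign(samples[None, :] - radii[:, None]).astype(np.int8)
    # endpoints exactly on a circle classify as outside
    sgn[sgn[:, 0] == 0, 0] = 1
    sgn[sgn[:, -1] == 0, -1] = 1
    # interior on-circle samples carry the preceding sign (no strict change)
    if np.any(sgn == 0):
        idx = np.where(sgn != 0, np.arange(sgn.shape[1])[None, :], 0)
        idx = np.maximum.accumulate(idx, axis=1)
        sgn = np.take_along_axis(sgn, idx, axis=1)
    return (sgn[:, 1:] != sgn[:, :-1]).sum(axis=1)


def circle_crossing_points(axis: Polyline, radii) -> list[list[tuple[float, float]]]:
    """Exact crossing locations of a polyline with origin-centred circles.

    For every radius, returns a list of ``(angle, radial_speed)`` pairs: the
    polar angle (atan2(y, x)) of each crossing point and the magnitude of
    the radial component of the unit direction there (1 = perfectly radial
    crossing, 0 = tangential).  Crossings are found by solving the
    per-segment quadratic |A + t (B - A)|^2 = r^2 on t in [0, 1).
    """
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii <= 0):
        raise InvalidParameterError("circle radii must be positive")
    pts = axis.points
    a = pts[:-1]
    ab = np.diff(pts, axis=0)
    aa = np.einsum("ij,ij->i", ab, ab)
    bb = 2.0 * np.einsum("ij,ij->i", a, ab)
    d0sq = np.einsum("ij,ij->i", a, a)
    out: list[list[tuple[float, float]]] = []
    for r in radii:
        cc = d0sq - r * r
        disc = bb * bb - 4.0 * aa * cc
        hits: list[tuple[float, float]] = []
        seg_idx = np.nonzero(disc > 0)[0]
        for i in seg_idx:
            sq = np.sqrt(disc[i])
            for t in ((-bb[i] - sq) / (2 * aa[i]), (-bb[i] + sq) / (2 * aa[i])):
                if 0.0 <= t < 1.0:
                    p = a[i] + t * ab[i]
                    speed = abs(np.dot(p, ab[i])) / (np.hypot(*p) * np.sqrt(aa[i]))
                    hits.append((float(np.arctan2(p[1], p[0])), float(speed)))
        out.append(sorted(hits))
    return out


def circle_crossings(axis: Polyline, radius: float) -> int:
    """Number of strict crossings of ``axis`` through the circle of ``radius``.

    A curved axis may cross the same circle more than once; each geometric
    crossing counts once.  Vertices exactly on the circle are outside.
    """
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    return int(circle_crossings_multi(axis, [radius])[0])


def analytic_sholl(system: RootSystem, grid: ShollGrid) -> ShollProfile:
    """Exact Sholl profile of a vector root system: I_k summed over all axes."""
    radii = grid.radii
    counts = np.zeros(len(radii), dtype=int)
    for axis in system.axes:
        counts += circle_crossings_multi(axis, radii)
    return ShollProfile(radii=radii, counts=counts)


def extract_traits(system: RootSystem) -> RootTraits:
    """Architecture traits of a vector root system (exact arclengths)."""
    prl = system.primary.arclength
    lat_lengths = [axis.arclength for _, axis in system.laterals]
    nlr = len(lat_lengths)
    lrl = float(np.sum(lat_lengths)) if nlr else 0.0
    return RootTraits(
        RL=prl + lrl,
        PRL=prl,
        LRL=lrl,
        MLRL=lrl / nlr if nlr else 0.0,
        NLR=nlr,
        extent=system.extent,
    )


def grid_end_beyond(extent: float, start_radius: float = 0.5, step: float = 0.5) -> float:
    """Smallest grid radius strictly greater than ``extent``."""
    if start_radius <= 0 or step <= 0:
        raise InvalidParameterError("start_radius and step must be positive")
    if extent < start_radius:
        return start_radius
    m = int(np.floor((extent - start_radius) / step)) + 1
    return start_radius + m * step


def auto_end_radius(system: RootSystem, start_radius: float = 0.5, step: float = 0.5) -> float:
    """Smallest grid radius strictly beyond the outermost root tip.

    Guarantees the profile ends with at least one zero-count circle, matching
    the convention of drawing the outer circle beyond the outermost tip.
    """
    return grid_end_beyond(system.extent, start_radius, step)
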