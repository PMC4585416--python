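"""Stochastic generator of seedling root systems and their raster images.

Emulates hydroponically grown *Brassica napus* seedling roots at the stage
where they are scanned flat on a glass plate: a single gravitropic primary
axis bearing first-order laterals.  Axes are heading random walks with a
fixed 0.05 cm growth step — well below the 0.5 cm circle spacing of the
Sholl grid, so path discretisation cannot create or destroy circle
crossings at grid radii.  The heading angle (measured from the downward
vertical) follows an AR(1) process: each step it is pulled a fraction
``gravitropism`` back toward vertical and perturbed by Gaussian noise of
scale ``tortuosity_sd``.

Lateral count is Poisson, branch positions are uniform over the apical
branching zone, and lateral lengths are log-normal — the simplest
non-negative families matching a count and a right-skewed length when only
group means are known.  Lateral geometry emulates a *disentangled* root:
before scanning, the washed root is spread on the plate so individual
laterals fan out instead of overlapping.  Each lateral leaves the primary
at an emergence angle drawn from a wide fan
(``branch_angle_mean`` +/- ``branch_angle_sd`` off the primary, random
side) and its heading then relaxes toward the local radial (away from the
origin) direction step by step, the way combing the root outward orients
it; radially oriented roots are also what makes circle crossings
transversal and countable.

Ground-truth traits are recorded from the freshly built polylines with the
same arclength measure `extract_traits` uses, so the recorded truth is
exactly the emitted geometry's measure.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .geometry import (
    InvalidInputError,
    InvalidParameterError,
    Polyline,
    RootSystem,
    RootTraits,
    extract_traits,
)
from .image import CalibratedImage

__all__ = [
    "STEP_CM",
    "GenotypeParams",
    "CohortSpec",
    "RasterParams",
    "CalibratedImage",
    "sample_root_system",
    "sample_resolvable_system",
    "validation_params",
    "default_params",
    "default_cohort_spec",
    "simulate_cohort",
    "rasterize",
    "respread",
    "derive_seed",
]

#: fixed growth step of the heading random walk, cm
STEP_CM = 0.05

#: per-step relaxation of a lateral's heading toward the local radial
#: direction (plate-spreading emulation)
COMB_STRENGTH = 0.03


@dataclass(frozen=True)
class GenotypeParams:
    """Distribution parameters of one genotype x treatment phenotype.

    ``lateral_length_log_mean``/``log_sd`` parameterise a log-normal in
    log-cm; the expected single-lateral length is
    ``exp(log_mean + log_sd**2 / 2)``.
    """

    primary_length_mean: float
    primary_length_sd: float
    lateral_count_mean: float
    lateral_length_log_mean: float
    lateral_length_log_sd: float
    branch_zone_fraction: float = 0.6
    branch_angle_mean: float = 0.7
    branch_angle_sd: float = 0.35
    tortuosity_sd: float = 0.08
    gravitropism: float = 0.15

    def __post_init__(self) -> None:
        if self.primary_length_mean <= 0 or self.primary_length_sd < 0:
            raise InvalidParameterError("primary length moments out of range")
        if self.lateral_count_mean < 0 or self.lateral_length_log_sd < 0:
            raise InvalidParameterError("lateral distribution parameters out of range")
        if not 0 < self.branch_zone_fraction <= 1:
            raise InvalidParameterError("branch_zone_fraction must be in (0, 1]")
        if not 0 <= self.gravitropism <= 1:
            raise InvalidParameterError("gravitropism must be in [0, 1]")
        if self.branch_angle_mean < 0 or self.branch_angle_sd < 0 or self.tortuosity_sd < 0:
            raise InvalidParameterError("angle scales must be non-negative")

    @property
    def expected_mlrl(self) -> float:
        return float(np.exp(self.lateral_length_log_mean + self.lateral_length_log_sd**2 / 2))


@dataclass(frozen=True)
class CohortSpec:
    """Replicated groups of a simulation experiment."""

    groups: tuple  # of (genotype_label, treatment_label, GenotypeParams)
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        labels = [(g, t) for g, t, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise InvalidParameterError("group labels must be unique")
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass(frozen=True)
class RasterParams:
    """Scanner emulation: 200 dpi office-scanner default, 1 px stroke."""

    dpi: float = 200.0
    thickness_px: int = 1
    margin_px: int = 8

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise InvalidParameterError("dpi must be positive")
        if self.thickness_px < 1:
            raise InvalidParameterError("thickness_px must be >= 1")

    @property
    def pixel_size(self) -> float:
        """cm per pixel (2.54 cm/inch divided by dpi)."""
        return 2.54 / self.dpi


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministic, order-independent per-replicate seed below 2**31."""
    key = "|".join([str(master_seed), *map(str, tokens)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def _walk(start: np.ndarray, n_steps: int, heading0: float, tortuosity_sd: float,
          gravitropism: float, rng: np.random.Generator) -> np.ndarray:
    """Heading random walk: AR(1) pull of the heading angle toward vertical."""
    noise = rng.normal(0.0, tortuosity_sd, n_steps) if tortuosity_sd > 0 else np.zeros(n_steps)
    phi = (1.0 - gravitropism)
    # theta_t = phi * theta_{t-1} + noise_t, theta_0 pre-step = heading0
    theta = lfilter([1.0], [1.0, -phi], noise + np.concatenate([[phi * heading0], np.zeros(n_steps - 1)]))
    dx = STEP_CM * np.sin(theta)
    dy = STEP_CM * np.cos(theta)  # y positive downward
    pts = np.empty((n_steps + 1, 2))
    pts[0] = start
    pts[1:, 0] = start[0] + np.cumsum(dx)
    pts[1:, 1] = start[1] + np.cumsum(dy)
    return pts


def _combed_walk(start: np.ndarray, n_steps: int, heading0: float,
                 tortuosity_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Lateral walk whose heading relaxes toward the local radial direction.

    ``heading0`` is measured from the radial (away-from-origin) direction at
    the start point.  Each step the heading angle relative to the current
    radial direction shrinks by ``COMB_STRENGTH`` and receives Gaussian
    noise, emulating a root combed outward on the scanner plate.
    """
    pts = np.empty((n_steps + 1, 2))
    pts[0] = start
    pos = np.array(start, dtype=float)
    r = np.hypot(*pos)
    radial = pos / r if r > 1e-12 else np.array([0.0, 1.0])
    heading = np.arctan2(radial[0], radial[1]) + heading0  # absolute, from +y (down)
    noise = rng.normal(0.0, tortuosity_sd, n_steps) if tortuosity_sd > 0 else np.zeros(n_steps)
    for i in range(n_steps):
        pos = pos + STEP_CM * np.array([np.sin(heading), np.cos(heading)])
        pts[i + 1] = pos
        radial_ang = np.arctan2(pos[0], pos[1])
        rel = (heading - radial_ang + np.pi) % (2 * np.pi) - np.pi
        heading = radial_ang + (1.0 - COMB_STRENGTH) * rel + noise[i]
    return pts


def sample_root_system(params: GenotypeParams, seed: int) -> tuple[RootSystem, RootTraits]:
    """Draw one root system; returns the system and its recorded ground truth."""
    rng = np.random.default_rng(seed)
    primary_len = max(rng.normal(params.primary_length_mean, params.primary_length_sd), 4 * STEP_CM)
    n_steps = max(int(round(primary_len / STEP_CM)), 2)
    primary = Polyline(_walk(np.zeros(2), n_steps, 0.0,
                             params.tortuosity_sd, params.gravitropism, rng))
    prl = primary.arclength

    nlr = int(rng.poisson(params.lateral_count_mean))
    # a disentangled root is feather-like: laterals on one side fan out
    # roughly parallel, so emergence angles share a per-plant, per-side base
    # (between-plant spread branch_angle_sd) with small per-lateral jitter
    base_angle = {
        side: rng.normal(params.branch_angle_mean, params.branch_angle_sd)
        for side in (-1.0, 1.0)
    }
    laterals = []
    for _ in range(nlr):
        s = float(rng.uniform(0.0, params.branch_zone_fraction * prl))
        attach = primary.point_at_arclength(s)
        side = 1.0 if rng.random() < 0.5 else -1.0
        heading0 = side * (base_angle[side] + rng.normal(0.0, 0.1))
        length = float(rng.lognormal(params.lateral_length_log_mean,
                                     params.lateral_length_log_sd))
        lat_steps = max(int(round(length / STEP_CM)), 1)
        # spreading on the plate straightens laterals: reduced heading noise
        axis = Polyline(_combed_walk(attach, lat_steps, heading0,
                                     0.25 * params.tortuosity_sd, rng))
        laterals.append((s, axis))

    system = RootSystem(primary=primary, laterals=tuple(laterals))
    return system, extract_traits(system)


# Synthetic phenotype calibration for the two genotypes (drought resistant
# 'DR' and drought sensitive 'DS') under control and osmotic (PEG 6000)
# stress.  Expected MLRL is 1.48 cm (DR control) and 6.19 cm (DR stress);
# expected NLR under stress is 50% (DR) / 60% (DS) of its control value;
# primary lengths are set so expected outermost-tip distances are near
# 26 / 21 / 22 / 18 cm for DR-control / DS-control / DR-stress / DS-stress.
# Absolute control NLR (40) is a synthetic calibration choice, not a
# measured value.  DS-stress MLRL (2.6 cm) encodes a sub-significant upward
# trend that leaves the expected total intersection count roughly unchanged.
_LOG_SD = 0.45


def _log_mean(mlrl: float) -> float:
    return float(np.log(mlrl) - _LOG_SD**2 / 2)


_DEFAULTS = {
    ("DR", "control"): GenotypeParams(
        primary_length_mean=26.0, primary_length_sd=2.0,
        lateral_count_mean=40.0,
        lateral_length_log_mean=_log_mean(1.48), lateral_length_log_sd=_LOG_SD),
    ("DR", "stress"): GenotypeParams(
        primary_length_mean=22.0, primary_length_sd=2.0,
        lateral_count_mean=20.0,
        lateral_length_log_mean=_log_mean(6.19), lateral_length_log_sd=_LOG_SD),
    ("DS", "control"): GenotypeParams(
        primary_length_mean=21.0, primary_length_sd=2.0,
        lateral_count_mean=40.0,
        lateral_length_log_mean=_log_mean(1.50), lateral_length_log_sd=_LOG_SD),
    ("DS", "stress"): GenotypeParams(
        primary_length_mean=18.0, primary_length_sd=2.0,
        lateral_count_mean=24.0,
        lateral_length_log_mean=_log_mean(2.60), lateral_length_log_sd=_LOG_SD),
}


def default_params(genotype: str, treatment: str) -> GenotypeParams:
    """Calibrated parameter set for genotype in {DR, DS}, treatment in
    {control, stress}."""
    try:
        return _DEFAULTS[(genotype, treatment)]
    except KeyError:
        raise InvalidParameterError(
            f"unknown group ({genotype!r}, {treatment!r}); "
            "genotype must be DR or DS, treatment control or stress"
        ) from None


def default_cohort_spec(n_replicates: int = 5, seed: int = 0) -> CohortSpec:
    """The four-group experiment layout with default phenotype parameters."""
    groups = tuple(
        (g, t, default_params(g, t))
        for g in ("DR", "DS") for t in ("control", "stress")
    )
    return CohortSpec(groups=groups, n_replicates=n_replicates, seed=seed)


def simulate_cohort(spec: CohortSpec) -> list[dict]:
    """Simulate every replicate of every group.

    Returns a list of row dicts with keys genotype, treatment, replicate,
    system, traits.  Replicate seeds are derived by hashing (master seed,
    group labels, replicate index), so rows are reproducible independently
    of generation order.
    """
    rows = []
    for genotype, treatment, params in spec.groups:
        for rep in range(spec.n_replicates):
            sub = derive_seed(spec.seed, genotype, treatment, rep)
            system, traits = sample_root_system(params, sub)
            rows.append({
                "genotype": genotype, "treatment": treatment, "replicate": rep,
                "system": system, "traits": traits,
            })
    return rows


def validation_params() -> GenotypeParams:
    """Fixture phenotype for the oracle-equivalence validation suite.

    A sparser root system than the cohort phenotypes (shorter primary,
    about a dozen laterals): measurement equivalence between the exact
    vector counts and the image-based counts is a property of the counting
    machinery, and it is well defined only where distinct crossings are
    resolvable at the scanner resolution.
    """
    return GenotypeParams(
        primary_length_mean=12.0, primary_length_sd=1.5,
        lateral_count_mean=12.0,
        lateral_length_log_mean=float(np.log(1.8) - 0.45**2 / 2),
        lateral_length_log_sd=0.45,
    )


def sample_resolvable_system(seed: int, params: GenotypeParams | None = None,
                             start_radius: float = 0.5, step: float = 0.5,
                             pixel_size: float = 2.54 / 200.0,
                             min_gap_px: float = 3.5, tip_margin_px: float = 1.5,
                             min_radial_speed: float = 0.25,
                             max_tries: int = 2000) -> tuple[RootSystem, RootTraits]:
    """Draw a root system whose circle crossings are all scanner-resolvable.

    Rejection-samples `sample_root_system` until, on the system's own Sholl
    grid, (i) every pair of crossings on a circle is at least ``min_gap_px``
    apart in arc length, (ii) every crossing is transversal (radial speed at
    least ``min_radial_speed``), and (iii) no axis tip lies within
    ``tip_margin_px`` of a circle.  These are the tangency-free fixtures on
    which image counts and exact vector counts can be expected to agree
    circle by circle; sub-pixel coincidences are physically uncountable by
    any image-based (or manual) method and are excluded by construction.
    """
    from .geometry import ShollGrid, circle_crossing_points, grid_end_beyond

    params = params or validation_params()
    for trial in range(max_tries):
        sub = derive_seed(seed, "resolvable", trial)
        system, traits = sample_root_system(params, sub)
        radii = ShollGrid(
            end_radius=grid_end_beyond(system.extent, start_radius, step),
            start_radius=start_radius, step=step,
        ).radii
        ok = True
        for ax in system.axes:
            tip = float(np.hypot(*ax.points[-1]))
            if np.min(np.abs(radii - tip)) < tip_margin_px * pixel_size:
                ok = False
                break
        if ok:
            per_axis = [circle_crossing_points(ax, radii) for ax in system.axes]
            for k, r in enumerate(radii):
                hits = sorted(h for ax_hits in per_axis for h in ax_hits[k])
                if any(speed < min_radial_speed for _, speed in hits):
                    ok = False
                    break
                if len(hits) > 1:
                    angs = np.array([a for a, _ in hits])
                    gaps = np.diff(angs)
                    wrap = angs[0] + 2 * np.pi - angs[-1]
                    if min(gaps.min(), wrap) * r < min_gap_px * pixel_size:
                        ok = False
                        break
        if ok:
            return system, traits
    raise InvalidInputError(
        f"no resolvable system found in {max_tries} draws; relax the margins"
    )


def rasterize(system: RootSystem, raster: RasterParams = RasterParams()) -> CalibratedImage:
    """Draw a root system as a binary scanner image.

    Every polyline is drawn as an 8-connected stroke (scikit-image Bresenham
    lines between consecutive vertices) and optionally thickened by
    morphological dilation.  The root origin pixel is recorded.
    """
    from skimage.draw import line as _line
    from skimage.morphology import dilation, disk

    px = raster.pixel_size
    all_pts = np.vstack([ax.points for ax in system.axes])
    rows = np.round(all_pts[:, 1] / px).astype(int)
    cols = np.round(all_pts[:, 0] / px).astype(int)
    pad = raster.margin_px + raster.thickness_px
    origin = (pad - rows.min(), pad - cols.min())
    h = rows.max() - rows.min() + 1 + 2 * pad
    w = cols.max() - cols.min() + 1 + 2 * pad
    if max(h, w) > 20_000:
        raise InvalidInputError(
            f"rasterized image would be {h} x {w} px (> 20000 on a side)"
        )
    mask = np.zeros((h, w), dtype=bool)
    for ax in system.axes:
        r = np.round(ax.points[:, 1] / px).astype(int) + origin[0]
        c = np.round(ax.points[:, 0] / px).astype(int) + origin[1]
        for i in range(len(r) - 1):
            rr, cc = _line(r[i], c[i], r[i + 1], c[i + 1])
            mask[rr, cc] = True
    if raster.thickness_px > 1:
        mask = dilation(mask, disk(raster.thickness_px // 2))
    return CalibratedImage(mask=mask, pixel_size=px, origin=origin)


def respread(system: RootSystem, seed: int, angle_sd: float = 0.15) -> RootSystem:
    """Re-spread a washed root on the scanner plate (positional perturbation).

    Each lateral is rigidly rotated about its branch point by an independent
    N(0, angle_sd) draw, then the whole system is rigidly rotated about the
    origin by one further draw.  Rigid motions preserve every arclength and
    the lateral count, so all traits are invariant.
    """
    if angle_sd < 0:
        raise InvalidParameterError("angle_sd must be non-negative")
    rng = np.random.default_rng(seed)
    new_laterals = []
    for s, axis in system.laterals:
        ang = rng.normal(0.0, angle_sd) if angle_sd > 0 else 0.0
        new_laterals.append((s, axis.transformed(rotation=ang, about=tuple(axis.points[0]))))
    global_ang = rng.normal(0.0, angle_sd) if angle_sd > 0 else 0.0
    primary = system.primary.transformed(rotation=global_ang)
    laterals = tuple(
        (s, axis.transformed(rotation=global_ang)) for s, axis in new_laterals
    )
    return RootSystem(primary=primary, laterals=laterals)
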