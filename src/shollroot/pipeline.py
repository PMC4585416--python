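"""End-to-end drivers and file I/O for the phenotyping workflow.

Binds the simulator, the rasterizer, the image-domain Sholl counter, the
analytic oracle, and the cohort statistics into three reproducible runs:

``run_simulate``
    cohort simulation to disk (root-system JSON, ground-truth traits CSV,
    optional PNG scans) with a checksum manifest.
``run_validate``
    the automated-vs-reference validation design: per-replicate Pearson
    correlation between image-based and exact per-circle counts, pooled
    over replicates by Fisher's z-transform.
``run_full_pipeline``
    simulate -> rasterize -> image Sholl -> statistics, producing the
    per-trait and per-circle group-comparison tables, the profile PCA with
    trait correlations, and the trait correlation matrix as CSV files.

All tabular outputs are CSV with a header row; root systems serialize to
JSON with points in cm.  Every run records its master seed and parameters
in the manifest, making outputs reproducible from the logged config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    RootSystem,
    ShollGrid,
    ShollProfile,
    analytic_sholl,
    auto_end_radius,
    grid_end_beyond,
)
from .image import CalibratedImage, image_sholl
from .stats import (
    align_profiles,
    compare_groups,
    correlate_traits,
    fisher_z_pool,
    per_circle_tests,
    profile_pca,
)
from .synth import (
    CohortSpec,
    RasterParams,
    default_cohort_spec,
    derive_seed,
    rasterize,
    sample_resolvable_system,
    simulate_cohort,
)

logger = logging.getLogger("shollroot")

__all__ = [
    "RunConfig",
    "save_system_json",
    "load_system_json",
    "save_profile_csv",
    "load_profile_csv",
    "save_image_png",
    "load_image_png",
    "cohort_traits_frame",
    "cohort_profiles",
    "run_simulate",
    "run_validate",
    "run_full_pipeline",
]


@dataclass
class RunConfig:
    """Parameters of one reproducible run; defaults follow the scan protocol
    (0.5 cm circle start and step, 200 dpi)."""

    outdir: Path | str = "shollroot_out"
    seed: int = 0
    n_replicates: int = 5
    start_radius: float = 0.5
    step: float = 0.5
    dpi: float = 200.0
    thickness_px: int = 1
    write_images: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def raster(self) -> RasterParams:
        return RasterParams(dpi=self.dpi, thickness_px=self.thickness_px)


# ---------------------------------------------------------------------------
# serialization

def save_system_json(system: RootSystem, path: Path | str) -> None:
    Path(path).write_text(json.dumps(system.to_dict()))


def load_system_json(path: Path | str) -> RootSystem:
    return RootSystem.from_dict(json.loads(Path(path).read_text()))


def save_profile_csv(profile: ShollProfile, path: Path | str) -> None:
    pd.DataFrame(
        {"radius_cm": profile.radii, "intersections": profile.counts}
    ).to_csv(path, index=False)


def load_profile_csv(path: Path | str) -> ShollProfile:
    df = pd.read_csv(path, comment="#")
    return ShollProfile(
        radii=df["radius_cm"].to_numpy(), counts=df["intersections"].to_numpy()
    )


def save_image_png(image: CalibratedImage, path: Path | str) -> None:
    """Write the mask as an 8-bit greyscale scan: dark root, light background."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.where(image.mask, 0, 255).astype(np.uint8))


def load_image_png(path: Path | str, pixel_size: float, origin: tuple) -> CalibratedImage:
    """Read a greyscale PNG/TIFF scan and binarise it (dark foreground, Otsu)."""
    import imageio.v3 as iio

    from .image import threshold_image

    gray = np.asarray(iio.imread(Path(path)))
    if gray.ndim == 3:  # collapse an RGB(A) scan to luminance
        gray = gray[..., :3].mean(axis=2)
    return CalibratedImage(
        mask=threshold_image(gray), pixel_size=pixel_size, origin=origin
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, files: list[Path]) -> Path:
    manifest = {
        "config": {**asdict(config), "outdir": str(config.outdir)},
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# cohort assembly

def cohort_traits_frame(rows: list[dict]) -> pd.DataFrame:
    """Replicate-level trait table: genotype, treatment, replicate, traits."""
    return pd.DataFrame(
        [
            {
                "genotype": r["genotype"],
                "treatment": r["treatment"],
                "replicate": r["replicate"],
                **r["traits"].as_dict(),
            }
            for r in rows
        ]
    )


def cohort_profiles(rows: list[dict], config: RunConfig, method: str = "image"
                    ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-replicate Sholl profiles on a zero-padded common grid.

    ``method='image'`` rasterizes each system and counts on the mask;
    ``method='analytic'`` uses the exact vector counts.  Each replicate's own
    grid ends one step beyond its outermost tip before padding.  Returns
    (common radii, replicates x radii matrix, key frame aligned to rows).
    """
    profiles = []
    for r in rows:
        system = r["system"]
        grid = ShollGrid(
            end_radius=auto_end_radius(system, config.start_radius, config.step),
            start_radius=config.start_radius,
            step=config.step,
        )
        if method == "analytic":
            profiles.append(analytic_sholl(system, grid))
        elif method == "image":
            profiles.append(image_sholl(rasterize(system, config.raster), grid))
        else:
            raise ValueError(f"unknown profile method {method!r}")
    radii, mat = align_profiles(profiles)
    keys = pd.DataFrame(
        [(r["genotype"], r["treatment"], r["replicate"]) for r in rows],
        columns=["genotype", "treatment", "replicate"],
    )
    return radii, mat, keys


def _cohort_spec(config: RunConfig) -> CohortSpec:
    return default_cohort_spec(n_replicates=config.n_replicates, seed=config.seed)


# ---------------------------------------------------------------------------
# runs

def run_simulate(config: RunConfig, spec: CohortSpec | None = None) -> dict:
    """Simulate a cohort to disk; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or _cohort_spec(config)
    logger.info("simulate: seed=%s groups=%d n_replicates=%d",
                spec.seed, len(spec.groups), spec.n_replicates)
    rows = simulate_cohort(spec)
    files = []
    for r in rows:
        stem = f"{r['genotype']}_{r['treatment']}_rep{r['replicate']}"
        sys_path = outdir / f"{stem}.json"
        save_system_json(r["system"], sys_path)
        files.append(sys_path)
        if config.write_images:
            png_path = outdir / f"{stem}.png"
            save_image_png(rasterize(r["system"], config.raster), png_path)
            files.append(png_path)
    traits_path = outdir / "traits.csv"
    cohort_traits_frame(rows).to_csv(traits_path, index=False)
    files.append(traits_path)
    manifest_path = _write_manifest(outdir, config, files)
    return json.loads(manifest_path.read_text())


def run_validate(config: RunConfig, rows: list[dict] | None = None,
                 pooled_threshold: float = 0.99) -> dict:
    """Correlate image-based against exact per-circle counts per replicate.

    Mirrors the validation design in which automated counts are checked
    against an independent reference count for each biological replicate and
    the per-replicate Pearson correlations are pooled through Fisher's
    z-transform.  Exact agreement gives r = 1, which has infinite z; such
    replicates are clipped to 1 - 1e-9 for pooling and reported as exact.

    By default the replicates are tangency-free fixture systems (see
    `sample_resolvable_system`): 4 x ``n_replicates`` of them, so the
    default run validates on 20 plants.  Pass ``rows`` (for example a
    simulated cohort) to validate other material.
    """
    if rows is None:
        rows = []
        for i in range(4 * config.n_replicates):
            system, traits = sample_resolvable_system(derive_seed(config.seed, "validate", i))
            rows.append({
                "genotype": "FIX", "treatment": "validation", "replicate": i,
                "system": system, "traits": traits,
            })
    logger.info("validate: %d replicates, dpi=%s", len(rows), config.dpi)
    _, analytic_mat, keys = cohort_profiles(rows, config, method="analytic")
    _, image_mat, _ = cohort_profiles(rows, config, method="image")
    width = max(analytic_mat.shape[1], image_mat.shape[1])
    analytic_mat = np.pad(analytic_mat, ((0, 0), (0, width - analytic_mat.shape[1])))
    image_mat = np.pad(image_mat, ((0, 0), (0, width - image_mat.shape[1])))
    per_replicate = []
    for i in range(len(rows)):
        a, b = analytic_mat[i], image_mat[i]
        if np.array_equal(a, b):
            per_replicate.append(1.0)
        else:
            per_replicate.append(float(np.corrcoef(a, b)[0, 1]))
    clipped = np.clip(per_replicate, -1 + 1e-9, 1 - 1e-9)
    pooled = fisher_z_pool(clipped)
    exact_fraction = float(np.mean(analytic_mat == image_mat))
    report = {
        "replicates": [
            {**keys.iloc[i].to_dict(), "pearson_r": per_replicate[i]}
            for i in range(len(rows))
        ],
        "pooled_r": pooled,
        "exact_circle_fraction": exact_fraction,
        "passed": bool(pooled >= pooled_threshold),
    }
    logger.info("validate: pooled r=%.5f exact fraction=%.4f", pooled, exact_fraction)
    return report


def run_full_pipeline(config: RunConfig, spec: CohortSpec | None = None,
                      method: str = "image") -> dict:
    """Simulate, measure, and analyse one experiment; write all tables.

    Produces, under ``config.outdir``: traits.csv, profiles.csv,
    trait_tests.csv (per-trait stress-vs-control contrasts per genotype,
    including I_T), per_circle_tests.csv, pca_variance.csv, pca_scores.csv,
    pca_trait_correlations.csv, trait_correlations.csv and manifest.json.
    Returns the tables as DataFrames.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or _cohort_spec(config)
    logger.info("pipeline: seed=%s method=%s outdir=%s", spec.seed, method, outdir)
    rows = simulate_cohort(spec)
    traits = cohort_traits_frame(rows)
    radii, counts, keys = cohort_profiles(rows, config, method=method)
    traits["I_T"] = counts.sum(axis=1)

    profiles_long = pd.concat(
        [
            keys.loc[np.repeat(keys.index, len(radii))].reset_index(drop=True),
            pd.DataFrame({
                "radius_cm": np.tile(radii, len(keys)),
                "intersections": counts.ravel(),
            }),
        ],
        axis=1,
    )

    trait_names = ["RL", "PRL", "LRL", "MLRL", "NLR", "extent", "I_T"]
    test_rows = []
    for genotype in sorted(traits["genotype"].unique()):
        sub = traits[traits["genotype"] == genotype]
        for trait in trait_names:
            groups = {
                t: sub.loc[sub["treatment"] == t, trait].to_numpy()
                for t in sorted(sub["treatment"].unique())
            }
            for res in compare_groups(groups):
                test_rows.append({
                    "genotype": genotype, "trait": trait,
                    "group_a": res.group_a, "group_b": res.group_b,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "equal_variance": res.equal_variance, "code": res.code,
                })
    trait_tests = pd.DataFrame(test_rows)

    circle_frames = []
    for genotype in sorted(traits["genotype"].unique()):
        idx = {
            t: keys.index[(keys["genotype"] == genotype) & (keys["treatment"] == t)]
            for t in sorted(keys["treatment"].unique())
        }
        groups = {t: counts[i] for t, i in idx.items()}
        frame = per_circle_tests(groups, radii)
        frame.insert(0, "genotype", genotype)
        circle_frames.append(frame)
    circle_tests = pd.concat(circle_frames, ignore_index=True)

    pca = profile_pca(counts)
    n_pc = min(5, pca.scores.shape[1])
    score_cols = {f"PC{i + 1}": pca.scores[:, i] for i in range(n_pc)}
    pca_scores = pd.concat([keys, pd.DataFrame(score_cols)], axis=1)
    pca_variance = pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(len(pca.variance_fraction))],
        "variance_fraction": pca.variance_fraction,
    })
    manual_traits = traits[["RL", "PRL", "LRL", "MLRL", "NLR"]]
    pc_trait_corr = correlate_traits(manual_traits, pd.DataFrame(score_cols))
    trait_corr = correlate_traits(
        traits[["NLR", "RL", "PRL", "LRL", "MLRL"]], traits[["I_T", "RL", "MLRL"]]
    )

    tables = {
        "traits": traits,
        "profiles": profiles_long,
        "trait_tests": trait_tests,
        "per_circle_tests": circle_tests,
        "pca_variance": pca_variance,
        "pca_scores": pca_scores,
        "pca_trait_correlations": pc_trait_corr,
        "trait_correlations": trait_corr,
    }
    files = []
    for name, frame in tables.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        files.append(path)
    _write_manifest(outdir, config, files)
    return tables
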