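"""Downstream statistics for root-architecture cohorts.

Covers the analysis path used on genotype x treatment cohorts of five
replicates: Bartlett variance-homogeneity gating of pairwise two-sample
t-tests (pooled variance when homogeneous, Welch otherwise) with the
significance coding # / * / ** / *** at p < 0.1 / 0.05 / 0.01 / 0.001,
per-circle treatment comparisons along the Sholl grid, centred
(unit-preserving, unscaled) PCA of circle-specific intersection profiles,
Pearson trait correlations, Fisher z-transform pooling of per-replicate
correlations, and the Michel & Kaufmann (1973) polynomial for the osmotic
potential of PEG 6000 solutions.

No multiple-testing adjustment is applied by default (a Holm option is
available but off), and variance homogeneity is the only distributional
gate: normality is not formally tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import InvalidInputError, InvalidParameterError, ShollProfile

__all__ = [
    "TestResult",
    "PCAResult",
    "significance_code",
    "bartlett_gate",
    "pairwise_t",
    "compare_groups",
    "align_profiles",
    "per_circle_tests",
    "profile_pca",
    "correlate_traits",
    "fisher_z_pool",
    "peg6000_osmotic_potential",
]

#: significance thresholds and their codes, most stringent first
_CODES = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "#"))


def significance_code(p_value: float) -> str:
    """Map a p-value to its significance code ('' when p >= 0.1)."""
    if not 0 <= p_value <= 1:
        if np.isnan(p_value):
            return ""
        raise InvalidParameterError("p-value must be in [0, 1]")
    for threshold, code in _CODES:
        if p_value < threshold:
            return code
    return ""


@dataclass(frozen=True)
class TestResult:
    """One pairwise comparison with its variance gate and significance code."""

    group_a: str
    group_b: str
    statistic: float
    p_value: float
    equal_variance: bool
    code: str


@dataclass(frozen=True)
class PCAResult:
    """Centred PCA of a replicates x radii profile matrix."""

    scores: np.ndarray          # replicates x components
    loadings: np.ndarray        # radii x components
    variance_fraction: np.ndarray  # per component, non-increasing


def bartlett_gate(*groups, alpha: float = 0.05) -> tuple[float, bool]:
    """Bartlett test of variance homogeneity; flag True when p >= alpha.

    A zero-variance group makes the statistic undefined (log of zero): the
    p-value is reported as NaN and the gate defaults to unequal variances.
    """
    if len(groups) < 2:
        raise InvalidInputError("bartlett_gate needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise InvalidInputError("each group needs at least two observations")
    if any(np.var(a) == 0 for a in arrays):
        return float("nan"), False
    with warnings.catch_warnings():
        # near-identical samples trigger benign precision-loss warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = sps.bartlett(*arrays)
    return float(p), bool(p >= alpha)


def _t_pair(a: np.ndarray, b: np.ndarray, equal_variance: bool) -> tuple[float, float]:
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, equal_var=equal_variance)
    return float(t), float(p)


def pairwise_t(groups: dict, equal_variance: bool, adjust: str | None = None) -> list[TestResult]:
    """Two-sample t-tests for every pair of labelled groups.

    Pooled-variance t when ``equal_variance`` is True, Welch-Satterthwaite
    otherwise.  ``adjust='holm'`` applies a Holm step-down correction across
    the pairs; the default is no adjustment.
    """
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(a) < 2 for a in arrays.values()):
        raise InvalidInputError("each group needs at least two observations")
    raw = [
        (la, lb, *_t_pair(arrays[la], arrays[lb], equal_variance))
        for la, lb in combinations(labels, 2)
    ]
    ps = np.array([p for *_, p in raw])
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests
        ps = multipletests(ps, method="holm")[1]
    elif adjust is not None:
        raise InvalidParameterError(f"unknown adjustment {adjust!r}")
    return [
        TestResult(la, lb, t, float(p), equal_variance, significance_code(p))
        for (la, lb, t, _), p in zip(raw, ps)
    ]


def compare_groups(groups: dict, alpha: float = 0.05, adjust: str | None = None) -> list[TestResult]:
    """Bartlett-gated pairwise t-tests: the standard group-comparison recipe."""
    _, homogeneous = bartlett_gate(*groups.values(), alpha=alpha)
    return pairwise_t(groups, equal_variance=homogeneous, adjust=adjust)


def align_profiles(profiles: list[ShollProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Stack profiles on a common grid, zero-padding beyond each extent.

    All profiles must share start radius and step.  A circle beyond a
    replicate's outermost tip genuinely has zero intersections, so padding
    with zeros is measurement, not imputation.
    """
    if not profiles:
        raise InvalidInputError("no profiles to align")
    starts = {round(float(p.radii[0]), 9) for p in profiles}
    steps = {round(float(np.diff(p.radii)[0]), 9) for p in profiles if len(p.radii) > 1}
    if len(starts) > 1 or len(steps) > 1:
        raise InvalidInputError("profiles must share start radius and step")
    longest = max(profiles, key=lambda p: len(p.radii))
    radii = longest.radii
    mat = np.zeros((len(profiles), len(radii)), dtype=int)
    for i, p in enumerate(profiles):
        mat[i, : len(p.counts)] = p.counts
    return radii, mat


def per_circle_tests(groups: dict, radii: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Bartlett-gated t-test of per-replicate I_k at every radius.

    ``groups`` maps exactly two labels to (replicates x radii) count
    matrices on the common ``radii`` grid.  Radii where both groups are
    constant and identical (for example the all-zero padded tail) are
    reported as not applicable (NaN p-value, empty code).
    """
    if len(groups) != 2:
        raise InvalidInputError("per_circle_tests compares exactly two groups")
    (la, a), (lb, b) = groups.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != len(radii) or b.shape[1] != len(radii):
        raise InvalidInputError("count matrices must match the radii grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidInputError("need at least two replicates per group")
    rows = []
    for k, r in enumerate(radii):
        xa, xb = a[:, k], b[:, k]
        ma, mb = float(np.mean(xa)), float(np.mean(xb))
        degenerate = np.var(xa) == 0 and np.var(xb) == 0 and ma == mb
        if degenerate:
            rows.append((r, ma, mb, np.nan, np.nan, False, "", False))
            continue
        _, homogeneous = bartlett_gate(xa, xb, alpha=alpha)
        t, p = _t_pair(xa, xb, equal_variance=homogeneous)
        rows.append((r, ma, mb, t, p, homogeneous, significance_code(p), True))
    return pd.DataFrame(
        rows,
        columns=["radius_cm", "mean_a", "mean_b", "statistic", "p_value",
                 "equal_variance", "code", "tested"],
    ).assign(group_a=la, group_b=lb)


def profile_pca(profiles: np.ndarray, n_components: int | None = None) -> PCAResult:
    """Centred, unscaled PCA of a replicates x radii intersection matrix.

    Profiles share units (counts), so columns are centred but not scaled to
    unit variance.  Requesting more components than min(n-1, radii) supports
    is truncated with a warning.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidInputError("need a 2-d matrix with >= 2 replicates")
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = max_rank
    elif n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components, data supports {max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        variance_fraction=pca.explained_variance_ratio_,
    )


def correlate_traits(x: pd.DataFrame, y: pd.DataFrame) -> pd.DataFrame:
    """Pearson r with two-sided t-based p for every (x column, y column) pair.

    Returns a long-format table with columns x, y, r, p_value, code.  A
    zero-variance column has no defined correlation and raises.
    """
    x = pd.DataFrame(x)
    y = pd.DataFrame(y)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("need >= 3 paired observations")
    rows = []
    for cx in x.columns:
        if np.var(x[cx].to_numpy(dtype=float)) == 0:
            raise InvalidInputError(f"column {cx!r} has zero variance")
        for cy in y.columns:
            if np.var(y[cy].to_numpy(dtype=float)) == 0:
                raise InvalidInputError(f"column {cy!r} has zero variance")
            r, p = sps.pearsonr(x[cx], y[cy])
            rows.append((cx, cy, float(r), float(p), significance_code(p)))
    return pd.DataFrame(rows, columns=["x", "y", "r", "p_value", "code"])


def fisher_z_pool(correlations) -> float:
    """Pool Pearson correlations via Fisher's z: tanh(mean(atanh(r)))."""
    r = np.asarray(list(correlations), dtype=float)
    if r.size == 0:
        raise InvalidInputError("nothing to pool")
    if np.any(np.abs(r) >= 1):
        raise InvalidParameterError("|r| must be < 1 for the z-transform")
    return float(np.tanh(np.mean(np.arctanh(r))))


def peg6000_osmotic_potential(concentration: float, temperature: float) -> float:
    """Osmotic potential (MPa) of a PEG 6000 solution.

    Michel & Kaufmann (1973) polynomial with C in g PEG 6000 per kg water
    (= 10 x the %-w/w concentration) and T in deg C, evaluated in bars and
    converted to MPa.
    """
    if concentration < 0:
        raise InvalidParameterError("concentration must be non-negative")
    c = 10.0 * concentration
    bars = (
        -1.18e-2 * c
        - 1.18e-4 * c**2
        + 2.67e-4 * c * temperature
        + 8.39e-7 * c**2 * temperature
    )
    return bars / 10.0
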