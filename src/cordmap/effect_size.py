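"""Hedges' G effect sizes and the two-level hierarchical bootstrap.

Positional comparisons between groups of tracing experiments are reported
as effect sizes, never p-values: with coordinate samples of thousands of
cells, even biologically meaningless micrometre-scale shifts reach
arbitrarily small p-values, and the nested animal/cell structure breaks
the independence assumptions of pooled tests.

Hedges' G is the bias-corrected standardized mean difference

    g = J * (mean_a - mean_b) / s_pooled,
    s_pooled = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)),
    J = 1 - 3 / (4 (n_a + n_b) - 9).

Group-level comparisons respect the nesting with a two-level bootstrap:
animals are resampled with replacement (first level), then each drawn
animal's coordinates are resampled with replacement at its own sample size
(second level), pooling the result into one replica sample per group. With
5000 replicas per group, replicas of A are paired with independently drawn
replicas of B, g is computed per pair, and the median and interquartile
range of that g distribution are reported.

Absolute effect sizes are banded as none (< 0.2), small (0.2-0.49),
medium (0.5-0.79) and large (>= 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (EmptyInputError, InsufficientDataError,
                     UndefinedEffectError)
from .normalization import QuadrantLabel, quadrant_of

DEFAULT_N_REPLICAS = 5000
#: |g| thresholds for the none/small/medium/large bands
EFFECT_BANDS = (0.2, 0.5, 0.8)


def effect_band(g: float, thresholds: tuple[float, float, float] = EFFECT_BANDS) -> str:
    """Classify |g| into none / small / medium / large."""
    a = abs(g)
    small, medium, large = thresholds
    if a < small:
        return "none"
    if a < medium:
        return "small"
    if a < large:
        return "medium"
    return "large"


@dataclass(frozen=True)
class EffectSizeResult:
    """Summary of a bootstrap Hedges' G distribution."""

    g_median: float
    g_iqr: tuple[float, float]
    n_replicas: int
    seed: int
    n_animals: tuple[int, int]
    n_cells: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.g_iqr
        if not (lo <= self.g_median <= hi):
            raise ValueError("IQR must bracket the median")

    @property
    def band(self) -> str:
        return effect_band(self.g_median)


@dataclass(frozen=True)
class PositionalSummary:
    """Median position of one experiment's interneurons in one quadrant."""

    experiment_id: str
    quadrant: QuadrantLabel
    axis: str
    median_um: float
    n_cells: int


def _moments(sample: np.ndarray) -> tuple[int, float, float]:
    n = sample.size
    return n, float(sample.mean()), float(sample.var(ddof=1))


def hedges_g(sample_a, sample_b) -> float:
    """Bias-corrected standardized mean difference between two samples.

    Antisymmetric under swapping the samples; requires n >= 2 per sample and
    non-zero pooled SD.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"need >= 2 observations per sample, got {a.size} and {b.size}")
    return _g_from_moments(*_moments(a), *_moments(b))


def _g_from_moments(na: int, ma: float, va: float,
                    nb: int, mb: float, vb: float) -> float:
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 <= 0.0:
        raise UndefinedEffectError("pooled SD is zero; Hedges' G undefined")
    correction = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return correction * (ma - mb) / np.sqrt(sp2)


def _as_group(group) -> list[np.ndarray]:
    arrays = [np.asarray(a, dtype=float).ravel() for a in group]
    if not arrays:
        raise InsufficientDataError("group has no animals")
    if any(a.size == 0 for a in arrays):
        raise InsufficientDataError("every animal needs at least one coordinate")
    return arrays

def _replica_moments(group: list[np.ndarray], n_replicas: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_replicas, 3) array of (n, mean, var ddof=1) of pooled replicas.

    One animal degrades gracefully to a flat bootstrap of that animal's
    cells. Uniform per-animal sizes use a fully vectorized path.
    """
    n_anim = len(group)
    sizes = {a.size for a in group}
    anim_idx = rng.integers(0, n_anim, size=(n_replicas, n_anim))
    if len(sizes) == 1:
        c = group[0].size
        values = np.stack(group)                       # (A, C)
        cell_idx = rng.integers(0, c, size=(n_replicas, n_anim, c))
        sampled = values[anim_idx[:, :, None], cell_idx]
        n = n_anim * c
        s1 = sampled.sum(axis=(1, 2))
        s2 = (sampled ** 2).sum(axis=(1, 2))
        mean = s1 / n
        var = (s2 - n * mean ** 2) / (n - 1) if n > 1 else np.zeros_like(mean)
        return np.column_stack([np.full(n_replicas, n), mean, np.maximum(var, 0.0)])
    out = np.empty((n_replicas, 3))
    for r in range(n_replicas):
        parts = []
        for k in anim_idx[r]:
            a = group[k]
            parts.append(a[rng.integers(0, a.size, size=a.size)])
        pooled = np.concatenate(parts)
        n = pooled.size
        mean = pooled.mean()
        var = pooled.var(ddof=1) if n > 1 else 0.0
        out[r] = (n, mean, var)
    return out


def hierarchical_bootstrap(group_a, group_b,
                           n_replicas: int = DEFAULT_N_REPLICAS,
                           seed: int = 0) -> EffectSizeResult:
    """Two-level bootstrap Hedges' G between two groups of animals.

    ``group_a`` / ``group_b`` are sequences of per-animal 1D coordinate
    arrays. Each replica resamples animals with replacement, then each drawn
    animal's coordinates with replacement at its own size; replica i of A is
    paired with an independently drawn replica of B and g computed per pair.
    Deterministic given ``seed``.
    """
    ga = _as_group(group_a)
    gb = _as_group(group_b)
    if n_replicas < 1:
        raise InsufficientDataError("need at least one replica")
    rng = np.random.default_rng(seed)
    mom_a = _replica_moments(ga, n_replicas, rng)
    mom_b = _replica_moments(gb, n_replicas, rng)
    pair_b = rng.integers(0, n_replicas, size=n_replicas)

    na, ma, va = mom_a[:, 0], mom_a[:, 1], mom_a[:, 2]
    nb = mom_b[pair_b, 0]
    mb = mom_b[pair_b, 1]
    vb = mom_b[pair_b, 2]
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if (sp2 <= 0.0).any():
        raise UndefinedEffectError(
            "a bootstrap replica has zero pooled SD; Hedges' G undefined")
    correction = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    g = correction * (ma - mb) / np.sqrt(sp2)

    lo, med, hi = np.percentile(g, [25.0, 50.0, 75.0])
    return EffectSizeResult(
        g_median=float(med), g_iqr=(float(lo), float(hi)),
        n_replicas=int(n_replicas), seed=int(seed),
        n_animals=(len(ga), len(gb)),
        n_cells=(int(sum(a.size for a in ga)), int(sum(b.size for b in gb))),
    )


def quadrant_coords(experiment, quadrant: QuadrantLabel, axis: str = "x") -> np.ndarray:
    """Normalized ``axis`` coordinates of interneurons inside ``quadrant``."""
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    col = 0 if axis == "x" else 1
    coords = experiment.coords(which="interneurons")
    keep = [i for i in range(coords.shape[0])
            if quadrant_of(coords[i, 0], coords[i, 1]) == quadrant]
    return coords[keep, col]


def median_position(experiment, quadrant: QuadrantLabel,
                    axis: str = "x") -> PositionalSummary:
    """Median normalized position of one experiment in one quadrant.

    Motor neurons are excluded where classified. An empty quadrant raises
    :class:`EmptyInputError` (the caller may record an empty-quadrant flag).
    """
    vals = quadrant_coords(experiment, quadrant, axis)
    if vals.size == 0:
        raise EmptyInputError(
            f"experiment {experiment.experiment_id}: no interneurons in "
            f"{quadrant}")
    return PositionalSummary(
        experiment_id=experiment.experiment_id, quadrant=quadrant, axis=axis,
        median_um=float(np.median(vals)), n_cells=int(vals.size))


def pairwise_effect_matrix(experiments, quadrant: QuadrantLabel,
                           axis: str = "x"):
    """Plain (non-bootstrap) Hedges' G for every pair of experiments.

    Returns ``(matrix, summary)``: a lower-triangular DataFrame of |g|
    (upper triangle NaN, mirroring the figure convention) and a dict with
    the median and IQR of the signed per-pair g values, taken in (i, j)
    order with i preceding j in the input. Pairs whose g is undefined are
    recorded as missing.
    """
    import pandas as pd

    if len(experiments) < 2:
        raise InsufficientDataError("need at least two experiments")
    samples = [quadrant_coords(e, quadrant, axis) for e in experiments]
    ids = [e.experiment_id for e in experiments]
    n = len(ids)
    mat = np.full((n, n), np.nan)
    signed: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                g = hedges_g(samples[i], samples[j])
            except (InsufficientDataError, UndefinedEffectError):
                continue
            signed.append(g)
            mat[j, i] = abs(g)
    matrix = pd.DataFrame(mat, index=ids, columns=ids)
    if signed:
        lo, med, hi = np.percentile(signed, [25.0, 50.0, 75.0])
        summary = {"g_median": float(med), "g_iqr": (float(lo), float(hi)),
                   "n_pairs": len(signed)}
    else:
        summary = {"g_median": None, "g_iqr": None, "n_pairs": 0}
    return matrix, summary
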