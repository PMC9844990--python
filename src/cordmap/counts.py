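"""Count scaling, power-law fitting and starter-cell bookkeeping.

Monosynaptic rabies tracing yields, per injected muscle, a count of
primarily infected ("starter") motor neurons and of transsynaptically
labelled premotor interneurons. Laboratories analyse different fractions
of the serial sections (1/2, 1/8, ...), so raw counts are divided by the
sampling fraction to estimate whole-cord totals before any cross-
experiment comparison.

Across tracing datasets the number of secondary cells grows with the
number of starter cells as a power law, y = a * x^b. The fit here is
ordinary least squares on (log x, log y) — the conventional reading of a
power-law fit with an R², matching the log-log axes such data are plotted
on. Interneuron/motor-neuron count ratios are summarized per titre class
(high >= 5e9 IU/ml, low < 1e9 IU/ml by default) as median and IQR.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ParameterError
from .io_model import CountRecord, read_metadata

#: default titre classes (IU/ml)
HIGH_TITRE_MIN = 5e9
LOW_TITRE_MAX = 1e9


@dataclass(frozen=True)
class PowerLawFit:
    """y = amplitude * x^exponent, fitted in log-log space."""

    amplitude: float
    exponent: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")

    def predict(self, x):
        return self.amplitude * np.asarray(x, dtype=float) ** self.exponent


@dataclass(frozen=True)
class RatioSummary:
    """Median/IQR of interneuron-per-motor-neuron ratios in one group."""

    label: str
    median: float
    iqr: tuple[float, float]
    n: int


def scale_count(count: float, sampling_fraction: float) -> float:
    """Estimate a whole-cord total: ``count / sampling_fraction``."""
    if count < 0:
        raise ParameterError(f"count must be non-negative, got {count}")
    if not 0.0 < sampling_fraction <= 1.0:
        raise ParameterError(
            f"sampling_fraction must be in (0, 1], got {sampling_fraction}")
    return count / sampling_fraction


def usable_for_fit(records: Iterable[CountRecord]) -> tuple[list[CountRecord], list[CountRecord]]:
    """Split records into (usable, excluded) for MN-dependent fits.

    Usable records have a known, positive starter-MN count and a positive
    premotor count; rows with unknown MN entries (e.g. laboratories that did
    not identify motor neurons) are excluded, not treated as zero.
    """
    usable, excluded = [], []
    for r in records:
        if r.n_starter_mn and r.n_starter_mn > 0 and r.n_premotor > 0:
            usable.append(r)
        else:
            excluded.append(r)
    return usable, excluded


def fit_power_law(records: Iterable[CountRecord],
                  scale_both: bool = True) -> PowerLawFit:
    """Fit premotor-IN vs starter-MN counts with a log-log OLS line.

    Counts are divided by each record's sampling fraction first; by default
    both axes are scaled (both are per-animal totals undercounted by the
    same section sampling), controlled by ``scale_both``.
    """
    usable, _ = usable_for_fit(records)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 usable records for a power-law fit, got {len(usable)}")
    x = np.array([scale_count(r.n_starter_mn, r.sampling_fraction) if scale_both
                  else float(r.n_starter_mn) for r in usable])
    y = np.array([scale_count(r.n_premotor, r.sampling_fraction)
                  for r in usable])
    ly = np.log(y)
    if np.allclose(ly, ly[0]):
        raise InsufficientDataError("zero variance in log counts; fit undefined")
    res = stats.linregress(np.log(x), ly)
    return PowerLawFit(amplitude=float(np.exp(res.intercept)),
                       exponent=float(res.slope),
                       r_squared=float(res.rvalue ** 2),
                       n_points=len(usable))


def titre_class(titre_IU_per_ml: float | None,
                high_min: float = HIGH_TITRE_MIN,
                low_max: float = LOW_TITRE_MAX) -> str | None:
    """Classify a titre as "high", "low" or None (unclassified/unknown)."""
    if titre_IU_per_ml is None:
        return None
    if titre_IU_per_ml >= high_min:
        return "high"
    if titre_IU_per_ml < low_max:
        return "low"
    return None


def ratio_summary(records: Iterable[CountRecord],
                  grouping: Callable[[CountRecord], str | None] = None
                  ) -> dict[str, RatioSummary]:
    """Median and IQR of IN/MN ratios per group.

    ``grouping`` maps a record to a group label (None = leave out); the
    default groups by titre class. Records without a positive MN count are
    skipped. The ratio uses raw counts: both counts carry the same sampling
    fraction, which cancels.
    """
    if grouping is None:
        grouping = lambda r: titre_class(r.titre_IU_per_ml)  # noqa: E731
    groups: dict[str, list[float]] = {}
    for r in records:
        label = grouping(r)
        if label is None or not r.n_starter_mn:
            continue
        groups.setdefault(label, []).append(r.n_premotor / r.n_starter_mn)
    out = {}
    for label, ratios in groups.items():
        lo, med, hi = np.percentile(ratios, [25.0, 50.0, 75.0])
        out[label] = RatioSummary(label=label, median=float(med),
                                  iqr=(float(lo), float(hi)), n=len(ratios))
    return out


def default_double_injection_selector(rows: list[CountRecord]) -> bool:
    """LG+TA double injections with a recorded double-labelled MN count."""
    muscles = {r.muscle for r in rows}
    has_double_count = any(r.n_double_mn is not None for r in rows)
    return {"LG", "TA"} <= muscles and has_double_count


def starter_mn_summary(records: Iterable[CountRecord],
                       selector: Callable[[list[CountRecord]], bool] = None
                       ) -> dict:
    """Starter motor-neuron bookkeeping over double-injection experiments.

    Groups records by experiment, keeps experiments passing ``selector``
    (default: LG+TA doubles with a recorded double-labelled entry), and sums
    per-muscle MN counts and double-labelled counts. Selected rows with a
    missing MN count are excluded from the per-muscle sums.
    """
    if selector is None:
        selector = default_double_injection_selector
    by_exp: dict[str, list[CountRecord]] = {}
    for r in records:
        by_exp.setdefault(r.experiment_id, []).append(r)
    per_muscle: dict[str, int] = {}
    double = 0
    selected: list[str] = []
    for exp_id, rows in by_exp.items():
        if not selector(rows):
            continue
        selected.append(exp_id)
        for r in rows:
            if r.n_starter_mn is None:
                continue
            per_muscle[r.muscle] = per_muscle.get(r.muscle, 0) + r.n_starter_mn
            if r.n_double_mn is not None:
                double += r.n_double_mn
    return {
        "experiments": selected,
        "mn_per_muscle": per_muscle,
        "n_double_labelled": double,
        "empty_selection": not selected,
    }


def load_reference_counts() -> list[CountRecord]:
    """Published per-experiment tracing counts shipped with the package.

    A compilation of hindlimb rabies-tracing experiments from four
    laboratories: per injected muscle, the starter motor-neuron count (where
    identified), double-labelled motor neurons in double injections, total
    premotor interneurons, virus titre and section sampling.
    """
    ref = resources.files("cordmap.data") / "tracing_experiment_counts.csv"
    with resources.as_file(ref) as path:
        return read_metadata(path)
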