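"""Landmark normalization into the idealized spinal-cord frame.

Transverse sections of the lumbar cord vary in size and shape along the
rostro-caudal axis and deform during histology. To pool cells across
sections and animals, each section is mapped independently into an
idealized transverse frame, 1700 μm wide (medio-lateral) by 900 μm tall
(dorso-ventral), with a piecewise-linear map per quadrant:

* x is scaled so the lateral white-matter edge at central-canal level on
  the cell's side maps to ±850 μm,
* y is scaled per quadrant so the outermost dorsal (ventral) white-matter
  point on the cell's side maps to the idealized dorsal (ventral) extent.

The central canal (origin) is a fixed point, so quadrant membership is
preserved exactly. Experiments are aligned rostro-caudally by shifting
each animal's z so its widest section — the L4/L5 border — sits at z = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ParameterError
from .io_model import CellRecord, Experiment, SectionGeometry, with_normalized_cells

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_UM = 800.0
#: annotation order of lumbar segments along the aligned axis
LUMBAR_SEGMENTS = ("L1", "L2", "L3", "L4", "L5", "L6")


@dataclass(frozen=True)
class IdealizedFrame:
    """Idealized transverse frame: 1700 μm wide, 900 μm tall.

    The dorso-ventral split of the 900 μm total is symmetric by default
    (+450 / −450) and configurable.
    """

    ml_halfwidth_um: float = 850.0
    dv_dorsal_um: float = 450.0
    dv_ventral_um: float = -450.0

    def __post_init__(self) -> None:
        if self.ml_halfwidth_um <= 0:
            raise ValueError("ml_halfwidth_um must be positive")
        if not (self.dv_dorsal_um > 0 > self.dv_ventral_um):
            raise ValueError("need dv_dorsal_um > 0 > dv_ventral_um")

    @property
    def width_um(self) -> float:
        return 2.0 * self.ml_halfwidth_um

    @property
    def height_um(self) -> float:
        return self.dv_dorsal_um - self.dv_ventral_um


@dataclass(frozen=True)
class QuadrantLabel:
    side: str  # "ipsi" | "contra"
    half: str  # "dorsal" | "ventral"

    def __post_init__(self) -> None:
        if self.side not in ("ipsi", "contra") or self.half not in ("dorsal", "ventral"):
            raise ValueError(f"invalid quadrant {self!r}")

    def __str__(self) -> str:
        return f"{self.half}-{self.side}"


def quadrant_of(cell_or_x, y: float | None = None, normalized: bool = True) -> QuadrantLabel:
    """Quadrant of a cell (or an (x, y) pair) from coordinate signs.

    The boundary x = 0 (y = 0) is assigned to ipsi (dorsal): a deterministic
    rule with zero-measure effect.
    """
    if y is None:
        cell = cell_or_x
        if normalized:
            if cell.x_norm_um is None or cell.y_norm_um is None:
                raise ValueError("cell has no normalized coordinates")
            x, y = cell.x_norm_um, cell.y_norm_um
        else:
            x, y = cell.x_um, cell.y_um
    else:
        x = cell_or_x
    return QuadrantLabel(side="ipsi" if x >= 0 else "contra",
                         half="dorsal" if y >= 0 else "ventral")


def _scale_factors(geom: SectionGeometry, frame: IdealizedFrame):
    for name in ("x_edge_ipsi", "x_edge_contra", "y_dorsal_ipsi",
                 "y_dorsal_contra", "y_ventral_ipsi", "y_ventral_contra"):
        if getattr(geom, name) == 0:
            raise DegenerateGeometryError(
                f"section {geom.section_id}: landmark {name} has zero magnitude")


def normalize_section(
    cells: list[CellRecord],
    geom: SectionGeometry,
    frame: IdealizedFrame = IdealizedFrame(),
) -> list[CellRecord]:
    """Map one section's cells into the idealized frame.

    Returns new records with ``x_norm_um`` / ``y_norm_um`` filled in; raw
    coordinates are untouched. The map is linear per quadrant and fixes the
    origin, so signs (and hence quadrants) are preserved.
    """
    _scale_factors(geom, frame)
    out: list[CellRecord] = []
    for c in cells:
        if c.section_id != geom.section_id:
            raise ValueError(
                f"cell section {c.section_id!r} does not match geometry "
                f"{geom.section_id!r}")
        ipsi = c.x_um >= 0
        x_edge = geom.x_edge_ipsi if ipsi else abs(geom.x_edge_contra)
        x_norm = c.x_um / x_edge * frame.ml_halfwidth_um
        if c.y_um >= 0:
            y_ref = geom.y_dorsal_ipsi if ipsi else geom.y_dorsal_contra
            y_norm = c.y_um / y_ref * frame.dv_dorsal_um
        else:
            y_ref = abs(geom.y_ventral_ipsi if ipsi else geom.y_ventral_contra)
            y_norm = c.y_um / y_ref * abs(frame.dv_ventral_um)
        rec = CellRecord(
            section_id=c.section_id, x_um=c.x_um, y_um=c.y_um, z_um=c.z_um,
            channel=c.channel, cell_class=c.cell_class, glyt2=c.glyt2,
            x_norm_um=x_norm, y_norm_um=y_norm, z_aligned_um=c.z_aligned_um,
            extras=dict(c.extras),
        )
        out.append(rec)
    return out


def _average_geometry(experiment: Experiment) -> SectionGeometry:
    """Experiment-level mean landmark geometry (fallback for lost sections)."""
    geoms = list(experiment.sections.values())
    if not geoms:
        raise DegenerateGeometryError(
            f"experiment {experiment.experiment_id}: no section geometry at all")
    mean = {
        name: float(np.mean([getattr(g, name) for g in geoms]))
        for name in ("x_edge_ipsi", "x_edge_contra", "y_dorsal_ipsi",
                     "y_dorsal_contra", "y_ventral_ipsi", "y_ventral_contra")
    }
    return SectionGeometry(section_id="__average__", z_um=0.0, **mean)


def normalize_experiment(
    experiment: Experiment, frame: IdealizedFrame = IdealizedFrame()
) -> Experiment:
    """Normalize every section of an experiment independently.

    Cells whose section lacks landmark geometry are normalized with the
    experiment-average geometry, with a logged warning.
    """
    by_section: dict[str, list[CellRecord]] = {}
    for c in experiment.cells:
        by_section.setdefault(c.section_id, []).append(c)
    fallback: SectionGeometry | None = None
    normalized: dict[int, CellRecord] = {}
    order = {id(c): i for i, c in enumerate(experiment.cells)}
    out: list[CellRecord | None] = [None] * len(experiment.cells)
    for sid, cells in by_section.items():
        geom = experiment.sections.get(sid)
        if geom is None:
            if fallback is None:
                fallback = _average_geometry(experiment)
            logger.warning(
                "experiment %s: section %s has no landmark geometry; "
                "using experiment-average fallback", experiment.experiment_id, sid)
            geom = SectionGeometry(
                section_id=sid, z_um=fallback.z_um,
                **{k: getattr(fallback, k)
                   for k in ("x_edge_ipsi", "x_edge_contra", "y_dorsal_ipsi",
                             "y_dorsal_contra", "y_ventral_ipsi",
                             "y_ventral_contra")})
        for orig, norm in zip(cells, normalize_section(cells, geom, frame)):
            out[order[id(orig)]] = norm
    return with_normalized_cells(experiment, out)


def widest_section_z(experiment: Experiment) -> float:
    """z of the widest section; ties break to the most rostral (smallest z)."""
    geoms = sorted(experiment.sections.values(), key=lambda g: g.z_um)
    if not geoms:
        raise DegenerateGeometryError(
            f"experiment {experiment.experiment_id}: no sections")
    widths = np.array([g.width_um for g in geoms])
    return geoms[int(np.argmax(widths))].z_um


def align_rostrocaudal(experiments: list[Experiment],
                       reference: str = "widest_section") -> dict[str, float]:
    """Per-experiment additive z offsets placing each widest section at z = 0.

    The widest medio-lateral section marks the L4/L5 segment border; aligning
    on it puts all animals in register along the rostro-caudal axis without
    changing within-animal spacings. Experiments with fewer than two sections
    cannot be aligned and get offset 0 with a warning. ``reference="none"``
    returns all-zero offsets.
    """
    offsets: dict[str, float] = {}
    for exp in experiments:
        if reference == "none":
            offsets[exp.experiment_id] = 0.0
            continue
        if len(exp.sections) < 2:
            warnings.warn(
                f"experiment {exp.experiment_id}: fewer than 2 sections; "
                "rostro-caudal alignment skipped (offset 0)")
            offsets[exp.experiment_id] = 0.0
            continue
        offsets[exp.experiment_id] = -widest_section_z(exp)
    return offsets


def apply_alignment(experiment: Experiment, offset: float) -> Experiment:
    """Fill ``z_aligned_um = z_um + offset`` on every cell."""
    cells = [
        CellRecord(
            section_id=c.section_id, x_um=c.x_um, y_um=c.y_um, z_um=c.z_um,
            channel=c.channel, cell_class=c.cell_class, glyt2=c.glyt2,
            x_norm_um=c.x_norm_um, y_norm_um=c.y_norm_um,
            z_aligned_um=c.z_um + offset, extras=dict(c.extras),
        )
        for c in experiment.cells
    ]
    return with_normalized_cells(experiment, cells)


def bin_rostrocaudal(cells: list[CellRecord],
                     bin_width_um: float = DEFAULT_BIN_WIDTH_UM) -> dict[int, list[CellRecord]]:
    """Partition cells into half-open rostro-caudal bins [k·w, (k+1)·w).

    Uses the aligned z when present, raw z otherwise. Every cell lands in
    exactly one bin; empty input gives an empty mapping.
    """
    if bin_width_um <= 0:
        raise ParameterError(f"bin width must be positive, got {bin_width_um}")
    bins: dict[int, list[CellRecord]] = {}
    for c in cells:
        z = c.z_aligned_um if c.z_aligned_um is not None else c.z_um
        k = int(np.floor(z / bin_width_um))
        # guard against rounding at bin boundaries (incl. subnormal z)
        if z < k * bin_width_um:
            k -= 1
        elif z >= (k + 1) * bin_width_um:
            k += 1
        bins.setdefault(k, []).append(c)
    return bins
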