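"""Data model and tabular I/O for viral-tracing cell coordinates.

The unit of analysis is an *experiment*: one muscle of one animal, traced
with one rabies reporter channel. Each experiment carries per-cell
coordinates exported from microscopy cell-detection software, per-section
white-matter landmark geometry, and count metadata (starter motor neurons,
premotor interneurons, virus titre, section-sampling fraction).

Coordinate convention (raw, per-section frame):

* origin at the central canal of each transverse section,
* ``x_um`` medio-lateral, positive toward the injected (ipsilateral) side,
* ``y_um`` dorso-ventral, positive dorsal,
* ``z_um`` rostro-caudal, increasing caudally.

Normalized coordinates live in separate fields (``x_norm_um``,
``y_norm_um``, ``z_aligned_um``) and never overwrite raw values.

Files are comma-separated UTF-8 with a header: one cells file, one sections
file and one metadata file per experiment or cohort (a neutral stand-in for
proprietary Imaris/Neurolucida exports).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import RowParseError, SchemaError, VocabularyError

CHANNELS = frozenset({"eGFP", "mCherry", "other"})
CELL_CLASSES = frozenset({"interneuron", "motor_neuron", "unclassified"})
GLYT2_STATES = frozenset({"on", "off", "unknown"})

#: common channel spellings accepted by default
DEFAULT_CHANNEL_ALIASES = {
    "GFP": "eGFP", "egfp": "eGFP", "EGFP": "eGFP",
    "mcherry": "mCherry", "Cherry": "mCherry", "RFP": "mCherry",
}

CELL_COLUMNS = ["section_id", "x_um", "y_um", "z_um", "channel", "cell_class"]
NORMALIZED_COLUMNS = ["x_norm_um", "y_norm_um", "z_aligned_um"]
SECTION_COLUMNS = [
    "section_id", "z_um", "x_edge_ipsi", "x_edge_contra",
    "y_dorsal_ipsi", "y_dorsal_contra", "y_ventral_ipsi", "y_ventral_contra",
]


@dataclass
class CellRecord:
    """One labelled cell."""

    section_id: str
    x_um: float
    y_um: float
    z_um: float
    channel: str = "other"
    cell_class: str = "unclassified"
    glyt2: str = "unknown"
    x_norm_um: float | None = None
    y_norm_um: float | None = None
    z_aligned_um: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("x_um", "y_um", "z_um"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.channel not in CHANNELS:
            raise VocabularyError(
                f"unknown channel {self.channel!r}; expected one of {sorted(CHANNELS)}")
        if self.cell_class not in CELL_CLASSES:
            raise VocabularyError(
                f"unknown cell_class {self.cell_class!r}; "
                f"expected one of {sorted(CELL_CLASSES)}")
        if self.glyt2 not in GLYT2_STATES:
            raise VocabularyError(
                f"unknown glyt2 state {self.glyt2!r}; "
                f"expected one of {sorted(GLYT2_STATES)}")


@dataclass
class SectionGeometry:
    """White-matter landmarks of one transverse section.

    ``x_edge_*`` are the lateral white-matter edges at central-canal level;
    ``y_dorsal_*`` / ``y_ventral_*`` the outermost dorsal/ventral white-matter
    points, per side. Signs follow the raw coordinate convention.
    """

    section_id: str
    z_um: float
    x_edge_ipsi: float
    x_edge_contra: float
    y_dorsal_ipsi: float
    y_dorsal_contra: float
    y_ventral_ipsi: float
    y_ventral_contra: float

    def __post_init__(self) -> None:
        if not self.x_edge_ipsi > 0:
            raise ValueError(f"x_edge_ipsi must be > 0, got {self.x_edge_ipsi}")
        if not self.x_edge_contra < 0:
            raise ValueError(f"x_edge_contra must be < 0, got {self.x_edge_contra}")
        for name in ("y_dorsal_ipsi", "y_dorsal_contra"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("y_ventral_ipsi", "y_ventral_contra"):
            if not getattr(self, name) < 0:
                raise ValueError(f"{name} must be < 0, got {getattr(self, name)}")

    @property
    def width_um(self) -> float:
        """Medio-lateral extent, the alignment reference measure."""
        return self.x_edge_ipsi - self.x_edge_contra


@dataclass
class Experiment:
    """One injected muscle of one animal: metadata, cells and sections."""

    experiment_id: str
    muscle: str = "unknown"
    lab: str = "unknown"
    mouse_line: str = "unknown"
    channel: str = "other"
    titre_IU_per_ml: float | None = None
    injection_age: str | None = None
    perfusion_age: str | None = None
    sampling_fraction: float = 1.0
    cells: list[CellRecord] = field(default_factory=list)
    sections: dict[str, SectionGeometry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ValueError(
                f"sampling_fraction must be in (0, 1], got {self.sampling_fraction}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def interneurons(self) -> list[CellRecord]:
        """Cells entering premotor-distribution analyses.

        Motor neurons are excluded when classified; unclassified cells are
        kept (some laboratories did not identify infected motor neurons).
        """
        return [c for c in self.cells if c.cell_class != "motor_neuron"]

    def coords(self, which: str = "interneurons", normalized: bool = True) -> np.ndarray:
        """(n, 3) array of (x, y, z) coordinates.

        ``which``: "interneurons", "motor_neurons" or "all".
        """
        if which == "interneurons":
            cells = self.interneurons()
        elif which == "motor_neurons":
            cells = [c for c in self.cells if c.cell_class == "motor_neuron"]
        elif which == "all":
            cells = self.cells
        else:
            raise ValueError(f"unknown selection {which!r}")
        if normalized:
            rows = [
                (c.x_norm_um, c.y_norm_um,
                 c.z_aligned_um if c.z_aligned_um is not None else c.z_um)
                for c in cells
            ]
            if any(r[0] is None or r[1] is None for r in rows):
                raise ValueError(
                    f"experiment {self.experiment_id}: normalized coordinates "
                    "missing; run normalization first")
        else:
            rows = [(c.x_um, c.y_um, c.z_um) for c in cells]
        return np.asarray(rows, dtype=float).reshape(-1, 3)


@dataclass
class CountRecord:
    """Per-experiment cell-count bookkeeping (one muscle/channel row)."""

    experiment_id: str
    muscle: str
    n_premotor: int
    n_starter_mn: int | None = None
    n_double_mn: int | None = None
    sampling_fraction: float = 1.0
    titre_IU_per_ml: float | None = None
    lab: str = "unknown"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_premotor", "n_starter_mn", "n_double_mn"):
            v = getattr(self, name)
            if v is not None and (v < 0 or int(v) != v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ValueError(
                f"sampling_fraction must be in (0, 1], got {self.sampling_fraction}")


_SAMPLING_RE = re.compile(
    r"^\s*(?P<frac>All|\d+\s*/\s*\d+)\s*(?:\(\s*(?P<thick>\d+(?:\.\d+)?)\s*(?:μm|um)?\s*\))?\s*$",
    re.IGNORECASE,
)


def parse_sampling(token: str) -> float:
    """Parse a section-sampling token like ``"1/2 (30 μm)"`` to a fraction.

    Grammar: ``<All | p/q> (<thickness> μm)``; the thickness suffix is
    optional. ``"All (40 μm)"`` -> 1.0, ``"1/8 (60 μm)"`` -> 0.125.
    """
    m = _SAMPLING_RE.match(str(token))
    if not m:
        raise RowParseError(f"unparsable section-sampling token {token!r}")
    frac = m.group("frac")
    if frac.lower() == "all":
        return 1.0
    p, q = (int(s) for s in frac.split("/"))
    if q == 0:
        raise RowParseError(f"zero denominator in sampling token {token!r}")
    return p / q


_TITRE_RE = re.compile(
    r"^\s*(?P<mant>\d+(?:\.\d+)?)\s*[x×]\s*10\s*\^?\s*(?P<exp>-?\d+)\s*\^?\s*$")


def parse_titre(token) -> float | None:
    """Parse a virus titre in IU/ml: plain numbers or ``"5×10^9"`` notation."""
    if token is None:
        return None
    s = str(token).strip()
    if s in {"", "-", "N/A", "NA", "nan"}:
        return None
    m = _TITRE_RE.match(s)
    if m:
        return float(m.group("mant")) * 10.0 ** int(m.group("exp"))
    try:
        return float(s)
    except ValueError as exc:
        raise RowParseError(f"unparsable titre token {token!r}") from exc


def _parse_count(token) -> int | None:
    """Missing-count tokens ('-', 'N/A', blank) become None, never zero."""
    if token is None:
        return None
    s = str(token).strip()
    if s in {"", "-", "N/A", "NA", "nan"}:
        return None
    try:
        f = float(s)
    except ValueError as exc:
        raise RowParseError(f"unparsable count token {token!r}") from exc
    if f < 0 or int(f) != f:
        raise RowParseError(f"count must be a non-negative integer, got {token!r}")
    return int(f)


def _norm_token(value, vocab: frozenset, aliases: dict, kind: str, line: int) -> str:
    s = str(value).strip()
    s = aliases.get(s, s)
    if s not in vocab:
        raise VocabularyError(
            f"line {line}: unknown {kind} token {value!r} "
            f"(known: {sorted(vocab)}; aliases: {sorted(aliases)})")
    return s


def read_cells(
    path,
    *,
    experiment_id: str | None = None,
    channel_aliases: dict | None = None,
    class_aliases: dict | None = None,
    glyt2_aliases: dict | None = None,
    injected_side: str | None = None,
    **metadata,
) -> Experiment:
    """Read a cells CSV into an :class:`Experiment`.

    Required columns: section_id, x_um, y_um, z_um, channel, cell_class.
    Optional: glyt2, experiment_id, normalized-coordinate columns; any other
    column is preserved per cell in ``extras``. Row order is preserved.

    If ``injected_side`` is ``"left"`` the x axis is reflected so that
    positive x is always ipsilateral (files are assumed to record positive x
    as anatomical right). ``metadata`` keywords (muscle, lab, titre_IU_per_ml,
    sampling_fraction, ...) are forwarded to the Experiment.
    """
    channel_aliases = {**DEFAULT_CHANNEL_ALIASES, **(channel_aliases or {})}
    class_aliases = dict(class_aliases or {})
    glyt2_aliases = dict(glyt2_aliases or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    known = set(CELL_COLUMNS) | set(NORMALIZED_COLUMNS) | {"glyt2", "experiment_id"}
    extra_cols = [c for c in df.columns if c not in known]

    reflect = -1.0 if injected_side == "left" else 1.0
    cells: list[CellRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rec = dict(zip(df.columns, row))
        try:
            x = float(rec["x_um"]) * reflect
            y = float(rec["y_um"])
            z = float(rec["z_um"])
        except ValueError as exc:
            raise RowParseError(f"{path}: line {line}: unparsable coordinate: {exc}")
        kwargs = {}
        for col, attr in (("x_norm_um", "x_norm_um"), ("y_norm_um", "y_norm_um"),
                          ("z_aligned_um", "z_aligned_um")):
            tok = rec.get(col, "")
            if tok not in ("", "nan"):
                try:
                    v = float(tok)
                except ValueError as exc:
                    raise RowParseError(
                        f"{path}: line {line}: unparsable coordinate: {exc}")
                if col == "x_norm_um":
                    v *= reflect
                kwargs[attr] = v
        cells.append(CellRecord(
            section_id=str(rec["section_id"]),
            x_um=x, y_um=y, z_um=z,
            channel=_norm_token(rec["channel"], CHANNELS, channel_aliases,
                                "channel", line),
            cell_class=_norm_token(rec["cell_class"], CELL_CLASSES, class_aliases,
                                   "cell_class", line),
            glyt2=_norm_token(rec.get("glyt2", "unknown") or "unknown",
                              GLYT2_STATES, glyt2_aliases, "glyt2", line),
            extras={c: rec[c] for c in extra_cols},
            **kwargs,
        ))
    if experiment_id is None:
        ids = df["experiment_id"].unique() if "experiment_id" in df.columns else []
        experiment_id = str(ids[0]) if len(ids) else "unnamed"
    return Experiment(experiment_id=experiment_id, cells=cells, **metadata)


def read_sections(path) -> dict[str, SectionGeometry]:
    """Read a sections CSV into a mapping section_id -> geometry."""
    df = pd.read_csv(path)
    missing = [c for c in SECTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    out: dict[str, SectionGeometry] = {}
    for i, row in df.iterrows():
        try:
            geom = SectionGeometry(
                section_id=str(row["section_id"]),
                **{c: float(row[c]) for c in SECTION_COLUMNS[1:]},
            )
        except (ValueError, TypeError) as exc:
            raise RowParseError(f"{path}: line {i + 2}: {exc}") from exc
        out[geom.section_id] = geom
    return out


def write_sections(sections: dict[str, SectionGeometry], path) -> None:
    rows = [{c: getattr(g, c) for c in SECTION_COLUMNS} for g in sections.values()]
    pd.DataFrame(rows, columns=SECTION_COLUMNS).to_csv(path, index=False)


def cells_to_frame(experiment: Experiment) -> pd.DataFrame:
    """Tabular view of an experiment's cells, raw + normalized columns."""
    rows = []
    for c in experiment.cells:
        rows.append({
            "experiment_id": experiment.experiment_id,
            "section_id": c.section_id,
            "x_um": c.x_um, "y_um": c.y_um, "z_um": c.z_um,
            "channel": c.channel, "cell_class": c.cell_class, "glyt2": c.glyt2,
            "x_norm_um": c.x_norm_um, "y_norm_um": c.y_norm_um,
            "z_aligned_um": c.z_aligned_um,
            **c.extras,
        })
    cols = ["experiment_id", "section_id", "x_um", "y_um", "z_um",
            "channel", "cell_class", "glyt2"] + NORMALIZED_COLUMNS
    extra = [c for c in (rows[0].keys() if rows else []) if c not in cols]
    return pd.DataFrame(rows, columns=cols + sorted(extra))


def write_cells(experiment: Experiment, path) -> None:
    """Write an experiment's cells (raw and any normalized columns) to CSV."""
    cells_to_frame(experiment).to_csv(path, index=False, float_format="%.10g")


def write_normalized(experiment: Experiment, path) -> None:
    """Write cells with normalized coordinates; round-trips via read_cells."""
    if any(c.x_norm_um is None or c.y_norm_um is None for c in experiment.cells):
        raise ValueError(
            f"experiment {experiment.experiment_id}: normalized coordinates "
            "missing; run normalization before write_normalized")
    write_cells(experiment, path)


# Table-1-shaped metadata ---------------------------------------------------

METADATA_COLUMNS = ["experiment_id", "lab", "muscle", "titre", "mns",
                    "double_mns", "total_premotor_ins", "sampling"]


def read_metadata(path) -> list[CountRecord]:
    """Read per-experiment count metadata into :class:`CountRecord` rows.

    The file mirrors the published per-experiment tables: one row per
    injected muscle with lab, titre, starter-MN count (may be missing),
    double-labelled MN count (may be missing), total premotor-interneuron
    count and a section-sampling token such as ``"1/2 (30 μm)"``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    records: list[CountRecord] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            records.append(CountRecord(
                experiment_id=str(row["experiment_id"]),
                lab=str(row["lab"]),
                muscle=str(row["muscle"]),
                titre_IU_per_ml=parse_titre(row["titre"]),
                n_starter_mn=_parse_count(row["mns"]),
                n_double_mn=_parse_count(row["double_mns"]),
                n_premotor=_parse_count(row["total_premotor_ins"]) or 0,
                sampling_fraction=parse_sampling(row["sampling"]),
                extras={c: row[c] for c in extra_cols},
            ))
        except (RowParseError, ValueError) as exc:
            raise RowParseError(f"{path}: line {line}: {exc}") from exc
    return records


def with_normalized_cells(experiment: Experiment, cells: list[CellRecord]) -> Experiment:
    """Copy of ``experiment`` with its cell list replaced."""
    return replace(experiment, cells=cells)
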