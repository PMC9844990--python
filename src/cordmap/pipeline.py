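"""Full analysis orchestration: read/simulate -> normalize -> densities ->
correlations -> effect sizes -> counts -> report.

Every stage is a pure function of (inputs, config, seed); a rerun with the
same config and seed reproduces the summary byte for byte. Each figure's
numbers also land in ``summary.json`` so nothing exists only as pixels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import counts as counts_mod
from .config import RunConfig
from .density import (DensityMatrix, GridSpec, correlation_matrix,
                      density_correlation, density_matrix, marginal,
                      pooled_density)
from .effect_size import (effect_band, hierarchical_bootstrap, median_position,
                          pairwise_effect_matrix, quadrant_coords)
from .errors import (CordmapError, EmptyInputError, InsufficientDataError,
                     SelectorError, UndefinedCorrelationError)
from .io_model import Experiment, read_cells, read_metadata, read_sections, write_cells
from .normalization import (QuadrantLabel, align_rostrocaudal, apply_alignment,
                            bin_rostrocaudal, normalize_experiment)
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

DORSAL_IPSI = QuadrantLabel(side="ipsi", half="dorsal")


@dataclass
class RunReport:
    """Structured pipeline result plus where its files were written."""

    summary: dict
    output_dir: Path
    experiments: list[Experiment]


def load_experiments(config: RunConfig) -> list[Experiment]:
    """Load a cohort from disk or generate it from the synthetic spec."""
    if config.input_dir is not None:
        return _load_cohort_dir(Path(config.input_dir))
    spec_kwargs = dict(config.synthetic or {})
    spec_kwargs.setdefault("seed", config.seed)
    if "muscles" in spec_kwargs:
        spec_kwargs["muscles"] = tuple(spec_kwargs["muscles"])
    return generate_cohort(CohortSpec(**spec_kwargs))


def _load_cohort_dir(root: Path) -> list[Experiment]:
    meta = {}
    meta_path = root / "metadata.csv"
    if meta_path.exists():
        for rec in read_metadata(meta_path):
            meta[rec.experiment_id] = rec
    experiments = []
    for cells_path in sorted(root.glob("*_cells.csv")):
        exp_id = cells_path.name[: -len("_cells.csv")]
        rec = meta.get(exp_id)
        exp = read_cells(
            cells_path, experiment_id=exp_id,
            muscle=rec.muscle if rec else "unknown",
            lab=rec.lab if rec else "unknown",
            titre_IU_per_ml=rec.titre_IU_per_ml if rec else None,
            sampling_fraction=rec.sampling_fraction if rec else 1.0,
        )
        sections_path = root / f"{exp_id}_sections.csv"
        if sections_path.exists():
            exp.sections.update(read_sections(sections_path))
        experiments.append(exp)
    if not experiments:
        raise CordmapError(f"no *_cells.csv files under {root}")
    return experiments


def prepare(experiments: list[Experiment], config: RunConfig) -> list[Experiment]:
    """Normalize all experiments and align them rostro-caudally."""
    normalized = [normalize_experiment(e, config.frame) for e in experiments]
    offsets = align_rostrocaudal(normalized, reference=config.alignment_reference)
    return [apply_alignment(e, offsets[e.experiment_id]) for e in normalized]


def _density_of(exp_or_coords, grid: GridSpec, config: RunConfig) -> DensityMatrix:
    if isinstance(exp_or_coords, Experiment):
        c = exp_or_coords.coords(which="interneurons")
        x, y = c[:, 0], c[:, 1]
    else:
        x, y = exp_or_coords
    fixed = config.density.fixed_bandwidth()
    bw = (fixed, fixed) if fixed is not None else None
    return density_matrix(x, y, grid=grid, bandwidth=bw,
                          truncation_sigmas=config.density.truncation_sigmas)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _muscle_groups(experiments: list[Experiment]) -> dict[str, list[Experiment]]:
    groups: dict[str, list[Experiment]] = {}
    for e in experiments:
        groups.setdefault(e.muscle, []).append(e)
    return groups


def select(experiments: list[Experiment], selector) -> list[Experiment]:
    """Filter experiments by a dict of attribute values or a predicate.

    Dict keys: muscle, lab, mouse_line, channel, or titre_class
    ("high"/"low").
    """
    if callable(selector):
        out = [e for e in experiments if selector(e)]
    else:
        def match(e: Experiment) -> bool:
            for key, want in selector.items():
                if key == "titre_class":
                    if counts_mod.titre_class(e.titre_IU_per_ml) != want:
                        return False
                elif getattr(e, key, None) != want:
                    return False
            return True
        out = [e for e in experiments if match(e)]
    if not out:
        available = {
            "muscle": sorted({e.muscle for e in experiments}),
            "lab": sorted({e.lab for e in experiments}),
        }
        raise SelectorError(f"selector {selector!r} matched nothing; "
                            f"available: {available}")
    return out


def compare_groups(experiments: list[Experiment], selector_a, selector_b,
                   config: RunConfig, label_a: str = "A", label_b: str = "B") -> dict:
    """Pooled-density correlation, bootstrap Hedges' G and medians for two groups."""
    group_a = select(experiments, selector_a)
    group_b = select(experiments, selector_b)
    grid = GridSpec.for_frame(config.frame, config.density.grid_um)
    rho_a = pooled_density(group_a, grid=grid)
    rho_b = pooled_density(group_b, grid=grid)
    try:
        r = density_correlation(rho_a, rho_b)
    except UndefinedCorrelationError:
        r = None
    coords_a = [quadrant_coords(e, DORSAL_IPSI, config.quadrant_axis)
                for e in group_a]
    coords_b = [quadrant_coords(e, DORSAL_IPSI, config.quadrant_axis)
                for e in group_b]
    boot = hierarchical_bootstrap(
        [c for c in coords_a if c.size], [c for c in coords_b if c.size],
        n_replicas=config.bootstrap.n_replicas, seed=config.bootstrap.seed)
    med_a = float(np.median(np.concatenate([c for c in coords_a if c.size])))
    med_b = float(np.median(np.concatenate([c for c in coords_b if c.size])))
    return {
        "labels": [label_a, label_b],
        "n_experiments": [len(group_a), len(group_b)],
        "pooled_correlation": r,
        "g_median": boot.g_median,
        "g_iqr": list(boot.g_iqr),
        "effect_band": effect_band(boot.g_median, config.effect_thresholds),
        "n_replicas": boot.n_replicas,
        "bootstrap_seed": boot.seed,
        "pooled_median_um": [med_a, med_b],
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and write all artefacts to the output dir.

    Emits normalized cell tables, per-experiment and per-muscle density
    grids, a pairwise correlation/|G| matrix, per-experiment dorsal-
    ipsilateral medians, 800 μm rostro-caudal bin distributions, a GlyT2
    split when labels are present, a counts report when metadata is
    available, figures, and a deterministic ``summary.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root_logger = logging.getLogger("cordmap")
    root_logger.addHandler(handler)
    try:
        report = _run(config, out)
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return report


def _run(config: RunConfig, out: Path) -> RunReport:
    summary: dict = {"config": config.to_dict(), "stages": {}}
    raw = load_experiments(config)
    logger.info("loaded %d experiments, %d cells total",
                len(raw), sum(e.n_cells for e in raw))
    experiments = prepare(raw, config)
    norm_dir = out / "normalized"
    norm_dir.mkdir(exist_ok=True)
    for e in experiments:
        write_cells(e, norm_dir / f"{e.experiment_id}_cells.csv")
    n_mn = sum(sum(c.cell_class == "motor_neuron" for c in e.cells)
               for e in experiments)
    summary["stages"]["normalize"] = {
        "n_experiments": len(experiments),
        "n_cells": int(sum(e.n_cells for e in experiments)),
        "n_motor_neurons_excluded_from_distributions": int(n_mn),
    }

    grid = GridSpec.for_frame(config.frame, config.density.grid_um)
    densities: dict[str, DensityMatrix] = {}
    per_exp: dict = {}
    for e in experiments:
        try:
            rho = _density_of(e, grid, config)
        except EmptyInputError:
            logger.warning("experiment %s: no interneurons; density skipped",
                           e.experiment_id)
            continue
        densities[e.experiment_id] = rho
        np.savetxt(out / f"density_{e.experiment_id}.csv", rho.values,
                   delimiter=",")
        entry = {"muscle": e.muscle, "n_cells": rho.n_cells,
                 "bandwidth_um": list(rho.bandwidth),
                 "marginal_x_sum": marginal(rho, "x").total,
                 "marginal_y_sum": marginal(rho, "y").total}
        try:
            ps = median_position(e, DORSAL_IPSI, config.quadrant_axis)
            entry["dorsal_ipsi_median_um"] = ps.median_um
            entry["dorsal_ipsi_n"] = ps.n_cells
        except EmptyInputError:
            entry["dorsal_ipsi_median_um"] = None
        per_exp[e.experiment_id] = entry
    summary["stages"]["density"] = per_exp

    if len(densities) >= 2:
        corr = correlation_matrix(densities)
        corr.to_csv(out / "correlation_matrix.csv")
        gmat, gsum = pairwise_effect_matrix(
            [e for e in experiments if e.experiment_id in densities],
            DORSAL_IPSI, config.quadrant_axis)
        gmat.to_csv(out / "pairwise_g_matrix.csv")
        offdiag = corr.values[np.triu_indices_from(corr.values, k=1)]
        offdiag = offdiag[~np.isnan(offdiag)]
        summary["stages"]["pairwise"] = {
            "correlation_min": float(offdiag.min()) if offdiag.size else None,
            "correlation_median": float(np.median(offdiag)) if offdiag.size else None,
            "g_summary": gsum,
        }
    else:
        logger.info("single experiment: comparison stages skipped")
        summary["stages"]["pairwise"] = {"skipped": "fewer than 2 experiments"}

    # rostro-caudal bins of the pooled cohort
    pooled_cells = [c for e in experiments for c in e.interneurons()]
    bins = bin_rostrocaudal(pooled_cells, config.binning_width_um)
    summary["stages"]["rostrocaudal_bins"] = {
        str(k): len(v) for k, v in sorted(bins.items())}

    groups = _muscle_groups(experiments)
    if len(groups) >= 2:
        a, b = sorted(groups)[:2]
        comparison = compare_groups(experiments, {"muscle": a}, {"muscle": b},
                                    config, label_a=a, label_b=b)
        summary["stages"]["muscle_contrast"] = comparison
    else:
        summary["stages"]["muscle_contrast"] = {
            "skipped": "fewer than 2 muscles"}

    glyt2_states = {c.glyt2 for e in experiments for c in e.cells}
    if {"on", "off"} <= glyt2_states:
        summary["stages"]["glyt2_split"] = _glyt2_split(experiments, config)

    meta_path = (Path(config.input_dir) / "metadata.csv"
                 if config.input_dir else None)
    if meta_path is not None and meta_path.exists():
        records = read_metadata(meta_path)
        summary["stages"]["counts"] = _counts_report(records, config, out)

    if config.write_figures:
        _figures(experiments, densities, config, out)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default))
    return RunReport(summary=summary, output_dir=out, experiments=experiments)


def _glyt2_split(experiments: list[Experiment], config: RunConfig) -> dict:
    """Per-muscle GlyT2-on vs GlyT2-off positional contrast."""
    out: dict = {}
    for muscle, group in _muscle_groups(experiments).items():
        per_state: dict[str, list[np.ndarray]] = {"on": [], "off": []}
        for e in group:
            coords = e.coords(which="interneurons")
            states = [c.glyt2 for c in e.interneurons()]
            for s in ("on", "off"):
                keep = [i for i, st in enumerate(states) if st == s]
                if keep:
                    per_state[s].append(coords[keep, 0])
        if not per_state["on"] or not per_state["off"]:
            continue
        boot = hierarchical_bootstrap(
            per_state["on"], per_state["off"],
            n_replicas=config.bootstrap.n_replicas, seed=config.bootstrap.seed)
        out[muscle] = {
            "median_on_um": float(np.median(np.concatenate(per_state["on"]))),
            "median_off_um": float(np.median(np.concatenate(per_state["off"]))),
            "g_median": boot.g_median, "g_iqr": list(boot.g_iqr),
        }
    return out


def _counts_report(records, config: RunConfig, out: Path) -> dict:
    report: dict = {}
    try:
        fit = counts_mod.fit_power_law(records,
                                       scale_both=config.counts.scale_both)
        report["power_law"] = {"amplitude": fit.amplitude,
                               "exponent": fit.exponent,
                               "r_squared": fit.r_squared,
                               "n_points": fit.n_points}
    except InsufficientDataError as exc:
        report["power_law"] = {"skipped": str(exc)}
    ratios = counts_mod.ratio_summary(records)
    report["ratios"] = {k: {"median": v.median, "iqr": list(v.iqr), "n": v.n}
                        for k, v in ratios.items()}
    report["starter_mns"] = counts_mod.starter_mn_summary(records)
    scaled = [{"experiment_id": r.experiment_id, "muscle": r.muscle,
               "scaled_premotor": counts_mod.scale_count(
                   r.n_premotor, r.sampling_fraction),
               "scaled_mns": (counts_mod.scale_count(
                   r.n_starter_mn, r.sampling_fraction)
                   if r.n_starter_mn is not None else None)}
              for r in records]
    import pandas as pd

    pd.DataFrame(scaled).to_csv(out / "counts_report.csv", index=False)
    return report


def _figures(experiments, densities, config: RunConfig, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = _muscle_groups(experiments)
    fig, axes = plt.subplots(1, max(len(groups), 1), figsize=(5 * len(groups), 5),
                             squeeze=False)
    for ax, (muscle, group) in zip(axes[0], sorted(groups.items())):
        for e in group:
            c = e.coords(which="interneurons")
            ax.plot(c[:, 0], c[:, 1], ".", ms=1.5, alpha=0.4)
        ax.set(title=f"{muscle} (n={len(group)})", xlabel="medio-lateral (μm)",
               ylabel="dorso-ventral (μm)",
               xlim=(-config.frame.ml_halfwidth_um, config.frame.ml_halfwidth_um),
               ylim=(config.frame.dv_ventral_um, config.frame.dv_dorsal_um))
        ax.axhline(0, color="0.8", lw=0.5)
        ax.axvline(0, color="0.8", lw=0.5)
    fig.tight_layout()
    fig.savefig(out / "transverse_maps.svg")
    plt.close(fig)

    if len(densities) >= 2:
        corr = correlation_matrix(densities)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(corr.values, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(corr)), corr.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="median-centred correlation r")
        fig.tight_layout()
        fig.savefig(out / "correlation_matrix.svg")
        plt.close(fig)
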