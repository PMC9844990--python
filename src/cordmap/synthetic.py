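"""Virtual tracing experiments with the structure the analysis assumes.

The generator emulates the empirical organisation of hindlimb premotor
maps: labelled interneurons fall in four quadrant-anchored Gaussian
clusters (a dominant dorsal-ipsilateral cluster centred ~320 μm from the
midline, ventral clusters on both sides, a sparse dorsal-contralateral
remainder), starter motor neurons sit in the ventral ipsilateral horn,
each animal carries a small positional jitter, and only a fraction of the
serial sections is analysed.

Cells are drawn in the idealized frame and then mapped *back* into each
section's raw coordinates by inverting the landmark normalization, so the
full pipeline — raw files in, normalized maps out — is exercised
end-to-end rather than bypassed. Section landmark magnitudes vary along
the cord with a bulge at the L4/L5 border (the lumbar enlargement), which
is what the rostro-caudal alignment step keys on.

An optional medio-lateral offset ``delta_ml_um`` shifts the second
muscle's interneuron clusters, providing the ground-truth segregation the
effect-size machinery must detect (and, at zero, must not invent).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import (CellRecord, Experiment, SectionGeometry, write_cells,
                       write_sections)
from .normalization import IdealizedFrame

QUADRANTS = ("dorsal-ipsi", "ventral-ipsi", "ventral-contra", "dorsal-contra")


def _default_cluster_means() -> dict[str, tuple[float, float]]:
    return {
        "dorsal-ipsi": (320.0, 230.0),
        "ventral-ipsi": (300.0, -200.0),
        "ventral-contra": (-250.0, -200.0),
        "dorsal-contra": (-300.0, 230.0),
    }


def _default_cluster_sds() -> dict[str, tuple[float, float]]:
    return {
        "dorsal-ipsi": (110.0, 90.0),
        "ventral-ipsi": (120.0, 100.0),
        "ventral-contra": (120.0, 100.0),
        "dorsal-contra": (110.0, 90.0),
    }


def _default_glyt2_on_prob() -> dict[str, float]:
    # glycinergic cells enriched ventral-ipsilaterally, depleted contralaterally
    return {
        "dorsal-ipsi": 0.45,
        "ventral-ipsi": 0.80,
        "ventral-contra": 0.20,
        "dorsal-contra": 0.45,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the scale of real tracing experiments: a handful of
    animals per muscle, hundreds of interneurons per animal (negative-
    binomially dispersed), tens of starter motor neurons, half the sections
    analysed, and a 4800 μm lumbar extent (six 800 μm segments).
    """

    muscles: tuple[str, ...] = ("LG", "TA")
    n_animals_per_muscle: int = 6
    cells_per_animal_mean: float = 800.0
    cells_per_animal_dispersion: float = 10.0
    mixture_weights: tuple[float, float, float, float] = (0.55, 0.25, 0.15, 0.05)
    cluster_means: dict = field(default_factory=_default_cluster_means)
    cluster_sds: dict = field(default_factory=_default_cluster_sds)
    delta_ml_um: float = 0.0
    jitter_sd_um: float = 10.0
    starter_mn_mean: float = 30.0
    sampling_fraction: float = 0.5
    glyt2_on_prob: dict = field(default_factory=_default_glyt2_on_prob)
    z_extent_um: float = 4800.0
    section_pitch_um: float = 60.0
    titre_IU_per_ml: float = 1e10
    frame: IdealizedFrame = IdealizedFrame()
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError(
                f"mixture weights must be >= 0 and sum to 1, got {tuple(w)}")
        for q in QUADRANTS:
            sx, sy = self.cluster_sds[q]
            if sx <= 0 or sy <= 0:
                raise ValueError(f"cluster SDs must be positive ({q}: {sx}, {sy})")
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.n_animals_per_muscle < 0:
            raise ValueError("n_animals_per_muscle must be >= 0")


def _rng_for(spec: CohortSpec, muscle: str, animal_index: int) -> np.random.Generator:
    return np.random.default_rng(
        [spec.seed, spec.muscles.index(muscle), animal_index])


def _sections_for(spec: CohortSpec, rng: np.random.Generator
                  ) -> dict[str, SectionGeometry]:
    """Kept sections with landmark magnitudes bulging at the L4/L5 border."""
    frame = spec.frame
    z_all = np.arange(0.0, spec.z_extent_um, spec.section_pitch_um)
    step = max(1, int(round(1.0 / spec.sampling_fraction)))
    z_mid = spec.z_extent_um / 2.0
    sections: dict[str, SectionGeometry] = {}
    for i, z in enumerate(z_all):
        if i % step:
            continue  # section cut but not analysed
        bulge = 1.0 + 0.12 * np.exp(-(((z - z_mid) / 800.0) ** 2))
        noise = np.clip(rng.normal(1.0, 0.04, size=6), 0.7, 1.3)
        sid = f"s{i:03d}"
        sections[sid] = SectionGeometry(
            section_id=sid, z_um=float(z),
            x_edge_ipsi=frame.ml_halfwidth_um * bulge * noise[0],
            x_edge_contra=-frame.ml_halfwidth_um * bulge * noise[1],
            y_dorsal_ipsi=frame.dv_dorsal_um * bulge * noise[2],
            y_dorsal_contra=frame.dv_dorsal_um * bulge * noise[3],
            y_ventral_ipsi=frame.dv_ventral_um * bulge * noise[4],
            y_ventral_contra=frame.dv_ventral_um * bulge * noise[5],
        )
    return sections


def _fold_into_quadrant(x: np.ndarray, y: np.ndarray, quadrant: str,
                        frame: IdealizedFrame) -> tuple[np.ndarray, np.ndarray]:
    """Reflect draws across the axes so every cell lands in its cluster's
    quadrant (boundary rule: x = 0 / y = 0 belong to ipsi / dorsal)."""
    half, side = quadrant.split("-")
    x = np.abs(x) if side == "ipsi" else -np.maximum(np.abs(x), 1e-6)
    y = np.abs(y) if half == "dorsal" else -np.maximum(np.abs(y), 1e-6)
    x = np.clip(x, -frame.ml_halfwidth_um + 1.0, frame.ml_halfwidth_um - 1.0)
    y = np.clip(y, frame.dv_ventral_um + 1.0, frame.dv_dorsal_um - 1.0)
    return x, y


def _invert_normalization(x_n: float, y_n: float, geom: SectionGeometry,
                          frame: IdealizedFrame) -> tuple[float, float]:
    """Raw-frame position whose normalization gives (x_n, y_n) exactly."""
    ipsi = x_n >= 0
    x_edge = geom.x_edge_ipsi if ipsi else abs(geom.x_edge_contra)
    x_raw = x_n / frame.ml_halfwidth_um * x_edge
    if y_n >= 0:
        y_ref = geom.y_dorsal_ipsi if ipsi else geom.y_dorsal_contra
        y_raw = y_n / frame.dv_dorsal_um * y_ref
    else:
        y_ref = abs(geom.y_ventral_ipsi if ipsi else geom.y_ventral_contra)
        y_raw = y_n / abs(frame.dv_ventral_um) * y_ref
    return x_raw, y_raw


def generate_experiment(spec: CohortSpec, muscle: str,
                        animal_index: int) -> Experiment:
    """One virtual animal/muscle: raw-frame cells plus section geometry.

    Deterministic under ``(spec.seed, muscle, animal_index)``. The second
    and later muscles' interneuron clusters are shifted medio-laterally by
    ``spec.delta_ml_um``.
    """
    if muscle not in spec.muscles:
        raise ValueError(f"muscle {muscle!r} not in spec.muscles {spec.muscles}")
    rng = _rng_for(spec, muscle, animal_index)
    frame = spec.frame
    sections = _sections_for(spec, rng)
    sids = list(sections)

    delta = spec.delta_ml_um if spec.muscles.index(muscle) > 0 else 0.0
    jitter = rng.normal(0.0, spec.jitter_sd_um, size=2)

    mean = spec.cells_per_animal_mean
    r = spec.cells_per_animal_dispersion
    n_cells = max(int(rng.negative_binomial(r, r / (r + mean))), 20)
    counts = rng.multinomial(n_cells, spec.mixture_weights)

    channel = "eGFP" if spec.muscles.index(muscle) == 0 else "mCherry"
    cells: list[CellRecord] = []
    for quadrant, n_q in zip(QUADRANTS, counts):
        if n_q == 0:
            continue
        (mx, my), (sx, sy) = spec.cluster_means[quadrant], spec.cluster_sds[quadrant]
        x = rng.normal(mx + delta + jitter[0], sx, size=n_q)
        y = rng.normal(my + jitter[1], sy, size=n_q)
        x, y = _fold_into_quadrant(x, y, quadrant, frame)
        glyt2 = np.where(rng.random(n_q) < spec.glyt2_on_prob[quadrant],
                         "on", "off")
        sec_idx = rng.integers(0, len(sids), size=n_q)
        for k in range(n_q):
            geom = sections[sids[sec_idx[k]]]
            x_raw, y_raw = _invert_normalization(x[k], y[k], geom, frame)
            cells.append(CellRecord(
                section_id=geom.section_id, x_um=x_raw, y_um=y_raw,
                z_um=geom.z_um, channel=channel, cell_class="interneuron",
                glyt2=str(glyt2[k])))

    # starter motor neurons: ventral ipsilateral horn
    n_mn = int(rng.poisson(spec.starter_mn_mean))
    if n_mn:
        x = rng.normal(300.0 + jitter[0], 60.0, size=n_mn)
        y = rng.normal(-250.0 + jitter[1], 60.0, size=n_mn)
        x, y = _fold_into_quadrant(x, y, "ventral-ipsi", frame)
        sec_idx = rng.integers(0, len(sids), size=n_mn)
        for k in range(n_mn):
            geom = sections[sids[sec_idx[k]]]
            x_raw, y_raw = _invert_normalization(x[k], y[k], geom, frame)
            cells.append(CellRecord(
                section_id=geom.section_id, x_um=x_raw, y_um=y_raw,
                z_um=geom.z_um, channel=channel, cell_class="motor_neuron"))

    return Experiment(
        experiment_id=f"{muscle}{animal_index:02d}",
        muscle=muscle, lab="synthetic", mouse_line="synthetic",
        channel=channel, titre_IU_per_ml=spec.titre_IU_per_ml,
        sampling_fraction=spec.sampling_fraction,
        cells=cells, sections=sections)


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None
                    ) -> list[Experiment]:
    """All animals of all muscles; optionally written as a cohort directory.

    The directory holds one cells and one sections CSV per experiment, a
    Table-shaped ``metadata.csv`` and a ``manifest.json`` recording the spec
    and seed. Same spec + seed always produces identical files.
    """
    experiments = [
        generate_experiment(spec, muscle, i)
        for muscle in spec.muscles
        for i in range(spec.n_animals_per_muscle)
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta_rows = []
        for exp in experiments:
            write_cells(exp, out / f"{exp.experiment_id}_cells.csv")
            write_sections(exp.sections, out / f"{exp.experiment_id}_sections.csv")
            n_mn = sum(c.cell_class == "motor_neuron" for c in exp.cells)
            n_in = sum(c.cell_class == "interneuron" for c in exp.cells)
            meta_rows.append({
                "experiment_id": exp.experiment_id, "lab": exp.lab,
                "muscle": exp.muscle, "titre": exp.titre_IU_per_ml,
                "mns": n_mn, "double_mns": "-",
                "total_premotor_ins": n_in,
                "sampling": _sampling_token(spec),
            })
        import pandas as pd

        pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
        manifest = dataclasses.asdict(spec)
        manifest["muscles"] = list(spec.muscles)
        manifest["frame"] = dataclasses.asdict(spec.frame)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return experiments


def _sampling_token(spec: CohortSpec) -> str:
    step = max(1, int(round(1.0 / spec.sampling_fraction)))
    thick = int(spec.section_pitch_um)
    return f"All ({thick} μm)" if step == 1 else f"1/{step} ({thick} μm)"


def generate_count_table(a: float, b: float, noise_sd: float,
                         n_experiments: int, seed: int = 0):
    """Synthetic starter-MN / premotor-IN count records following a power law.

    MN counts are log-uniform over [1, 120] (the observed starter range);
    IN = round(a * MN^b * exp(eps)) with eps ~ Normal(0, noise_sd).
    """
    from .io_model import CountRecord

    if a <= 0:
        raise ValueError(f"amplitude a must be positive, got {a}")
    rng = np.random.default_rng(seed)
    mn = np.maximum(np.round(np.exp(rng.uniform(np.log(1.0), np.log(120.0),
                                                size=n_experiments))), 1)
    eps = rng.normal(0.0, noise_sd, size=n_experiments) if noise_sd > 0 else 0.0
    ins = np.maximum(np.round(a * mn ** b * np.exp(eps)), 1)
    return [
        CountRecord(experiment_id=f"sim{i:03d}", muscle="LG",
                    n_premotor=int(ins[i]), n_starter_mn=int(mn[i]),
                    sampling_fraction=1.0, titre_IU_per_ml=1e10,
                    lab="synthetic")
        for i in range(n_experiments)
    ]
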