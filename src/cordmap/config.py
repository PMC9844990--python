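"""Run configuration: one YAML file, one root seed, explicit defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .density import DEFAULT_GRID_UM, DEFAULT_TRUNCATION_SIGMAS
from .effect_size import DEFAULT_N_REPLICAS, EFFECT_BANDS
from .errors import ParameterError
from .normalization import DEFAULT_BIN_WIDTH_UM, IdealizedFrame


@dataclass(frozen=True)
class DensityConfig:
    grid_um: float = DEFAULT_GRID_UM
    bandwidth_rule: str = "scott"
    truncation_sigmas: float = DEFAULT_TRUNCATION_SIGMAS

    def fixed_bandwidth(self) -> float | None:
        """None for the data-driven rule, a value for "fixed:<μm>"."""
        if self.bandwidth_rule == "scott":
            return None
        if self.bandwidth_rule.startswith("fixed:"):
            v = float(self.bandwidth_rule.split(":", 1)[1])
            if v <= 0:
                raise ParameterError(f"fixed bandwidth must be positive: {v}")
            return v
        raise ParameterError(
            f"unknown bandwidth rule {self.bandwidth_rule!r} "
            "(expected 'scott' or 'fixed:<μm>')")


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicas: int = DEFAULT_N_REPLICAS
    seed: int = 0


@dataclass(frozen=True)
class CountsConfig:
    scale_both: bool = True
    high_titre_min: float = 5e9
    low_titre_max: float = 1e9


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, validated up front."""

    input_dir: str | None = None
    synthetic: dict | None = None
    output_dir: str = "cordmap_out"
    seed: int = 0
    frame: IdealizedFrame = IdealizedFrame()
    binning_width_um: float = DEFAULT_BIN_WIDTH_UM
    alignment_reference: str = "widest_section"
    density: DensityConfig = DensityConfig()
    bootstrap: BootstrapConfig = BootstrapConfig()
    counts: CountsConfig = CountsConfig()
    effect_thresholds: tuple[float, float, float] = EFFECT_BANDS
    quadrant_axis: str = "x"
    write_figures: bool = True

    def __post_init__(self) -> None:
        if self.input_dir is None and self.synthetic is None:
            raise ParameterError("config needs input_dir or a synthetic spec")
        if self.binning_width_um <= 0:
            raise ParameterError("binning width must be positive")
        if self.alignment_reference not in ("widest_section", "none"):
            raise ParameterError(
                f"unknown alignment reference {self.alignment_reference!r}")
        self.density.fixed_bandwidth()  # validates the rule string

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame"] = dataclasses.asdict(self.frame)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig`.

    Recognized top-level keys: input_dir, synthetic, output_dir, seed,
    frame {ml_halfwidth_um, dv_dorsal_um, dv_ventral_um},
    binning {width_um}, alignment {reference},
    density {grid_um, bandwidth_rule, truncation_sigmas},
    bootstrap {n_replicas, seed}, counts {scale_both, high_titre_min,
    low_titre_max}, effects {thresholds}.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("input_dir", "synthetic", "output_dir", "seed",
                "quadrant_axis", "write_figures"):
        if key in raw:
            kwargs[key] = raw[key]
    if "frame" in raw:
        kwargs["frame"] = IdealizedFrame(**raw["frame"])
    if "binning" in raw:
        kwargs["binning_width_um"] = raw["binning"].get(
            "width_um", DEFAULT_BIN_WIDTH_UM)
    if "alignment" in raw:
        kwargs["alignment_reference"] = raw["alignment"].get(
            "reference", "widest_section")
    if "density" in raw:
        kwargs["density"] = DensityConfig(**raw["density"])
    if "bootstrap" in raw:
        kwargs["bootstrap"] = BootstrapConfig(**raw["bootstrap"])
    if "counts" in raw:
        kwargs["counts"] = CountsConfig(**raw["counts"])
    if "effects" in raw:
        kwargs["effect_thresholds"] = tuple(raw["effects"]["thresholds"])
    return RunConfig(**kwargs)
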