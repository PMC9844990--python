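# cordmap

Spatial statistics for monosynaptic rabies tracing of spinal premotor
interneurons.

When a glycoprotein-deleted rabies virus is injected into a hindlimb
muscle of a mouse engineered to complement the glycoprotein in motor
neurons, the virus jumps exactly one synapse backwards: from the muscle's
motor pool onto the *premotor interneurons* that drive it. The question
such experiments ask is positional — do the interneuron populations
premotor to antagonist muscles (ankle flexors such as tibialis anterior,
TA, versus extensors such as lateral gastrocnemius, LG) occupy different
territories of the spinal grey matter, or are they spatially
intermingled? Answering it requires comparing tens of thousands of
labelled-cell coordinates across animals, laboratories, tracing methods
and section-sampling schemes, which is a statistics problem more than an
imaging one. `cordmap` implements that statistical workflow as a tested,
reusable Python library:

* **Landmark normalization.** Each transverse section's cell coordinates
  (origin at the central canal, x medio-lateral with ipsilateral positive,
  y dorso-ventral with dorsal positive) are mapped quadrant-by-quadrant
  onto an idealized cord 1700 μm wide and 900 μm tall, scaling x to the
  lateral white-matter edge and y to the outermost dorsal/ventral
  white-matter points of the cell's own quadrant. Experiments are aligned
  rostro-caudally on each animal's widest section (the L4/L5 border).
* **Density maps.** Normalized positions are convolved with a Gaussian
  kernel whose width follows a Scott-type rule, σ = SD·n^(−1/5) per axis,
  giving a unit-mass density matrix ρ(xᵢ, yⱼ) per experiment, plus
  unit-mass marginal distributions along each axis.
* **Median-centred density correlation.** Two experiments' maps are
  compared with

      r_nm = Σᵢⱼ (ρ_n(i,j) − med ρ_n)(ρ_m(i,j) − med ρ_m)
             / √( Σᵢⱼ (ρ_n − med ρ_n)² · Σᵢⱼ (ρ_m − med ρ_m)² )

  — centred on the median over grid entries rather than the mean, so the
  mostly-empty anatomical background does not dominate.
* **Hierarchical-bootstrap effect sizes.** Group differences in position
  are reported as Hedges' G (bias-corrected standardized mean difference)
  with a two-level bootstrap that resamples animals, then cells within
  each drawn animal, 5000 replicas, reporting the median and IQR of the G
  distribution. No p-values: with samples of thousands of cells they
  detect biologically meaningless micrometre shifts, and pooled tests
  ignore the nested animal/cell structure. |G| is banded as none (<0.2),
  small, medium, large (≥0.8).
* **Count scaling and power law.** Per-experiment counts are divided by
  the section-sampling fraction (e.g. "1/8 (60 μm)" → 1/8), and the
  relation between premotor-interneuron and starter-motor-neuron counts
  is fitted as y = a·xᵇ by ordinary least squares in log-log space.
* **Synthetic cohorts.** A generator produces virtual experiments with
  the empirical structure of real data (quadrant-anchored clusters,
  ventral-horn starter cells, per-animal jitter, section subsampling,
  GlyT2 on/off composition), drawn in the idealized frame and mapped back
  through inverted section geometry so the whole pipeline is testable
  end-to-end without any raw microscopy data.

A transcription of the published per-experiment count table (70 rows from
four laboratories) ships with the package for the count analyses.

## Worked example

```python
from cordmap import (RunConfig, run_pipeline, load_reference_counts,
                     fit_power_law)
from cordmap.config import BootstrapConfig

cfg = RunConfig(
    synthetic=dict(n_animals_per_muscle=3, cells_per_animal_mean=400, seed=7),
    output_dir="demo_out", seed=7,
    bootstrap=BootstrapConfig(n_replicas=5000, seed=7))
report = run_pipeline(cfg)
s = report.summary["stages"]
print(s["pairwise"]["correlation_min"])   # 0.9411724172235247
print(s["muscle_contrast"]["g_median"])   # 0.18834444391914104
print(s["muscle_contrast"]["effect_band"])  # 'none'

fit = fit_power_law(load_reference_counts())
print(fit.exponent, fit.r_squared)  # 0.5325429157544195 0.4877007906323451
```

The run simulates a null cohort (LG and TA premotor maps drawn from the
same spatial distribution), normalizes it, and reports the pairwise
density correlations (all above 0.94: the maps are statistically
indistinguishable) and the hierarchical-bootstrap Hedges' G for the
muscle contrast (0.19, in the "no effect" band — the pipeline correctly
declines to invent a flexor/extensor segregation). The power-law fit on
the shipped reference counts gives an exponent of 0.53 with R² = 0.49:
interneuron yield grows sub-linearly with starter-cell number, and
starter count explains about half the log-scale variance.

The same workflow is scriptable from a shell:

```sh
cordmap simulate --out cohort --seed 7 --animals 3 --cells 400
cordmap analyze --config run.yaml
cordmap compare --config run.yaml --group-a muscle=LG --group-b muscle=TA
```

## Layout

| module | contents |
| --- | --- |
| `cordmap.io_model` | data model (cells, sections, experiments, counts) and CSV readers/writers |
| `cordmap.normalization` | idealized frame, quadrant-wise landmark scaling, z alignment, 800 μm binning |
| `cordmap.density` | bandwidth rule, density matrices, marginals, median-centred correlation |
| `cordmap.effect_size` | Hedges' G, two-level hierarchical bootstrap, positional medians |
| `cordmap.counts` | sampling-fraction scaling, power-law fit, titre-class ratios, starter bookkeeping |
| `cordmap.synthetic` | virtual cohort and count-table generators |
| `cordmap.pipeline` / `cordmap.cli` | orchestration, group comparisons, figures, `cordmap` command |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
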