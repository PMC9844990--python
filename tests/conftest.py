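import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from cordmap import (CellRecord, Experiment, IdealizedFrame, SectionGeometry,
                     load_reference_counts)


def make_section(section_id="s0", z=0.0, xe_i=850.0, xe_c=-850.0,
                 yd_i=450.0, yd_c=450.0, yv_i=-450.0, yv_c=-450.0):
    return SectionGeometry(
        section_id=section_id, z_um=z, x_edge_ipsi=xe_i, x_edge_contra=xe_c,
        y_dorsal_ipsi=yd_i, y_dorsal_contra=yd_c,
        y_ventral_ipsi=yv_i, y_ventral_contra=yv_c)


def make_experiment(xy, experiment_id="e0", muscle="LG", cell_class="interneuron",
                    normalized=True, **kwargs):
    """Experiment from an (n, 2) array of idealized coordinates.

    With ``normalized=True`` the positions are stored directly as normalized
    coordinates (the section landmarks already match the idealized frame).
    """
    xy = np.asarray(xy, dtype=float)
    cells = []
    for x, y in xy:
        cells.append(CellRecord(
            section_id="s0", x_um=x, y_um=y, z_um=0.0,
            cell_class=cell_class,
            x_norm_um=x if normalized else None,
            y_norm_um=y if normalized else None))
    return Experiment(experiment_id=experiment_id, muscle=muscle,
                      cells=cells, sections={"s0": make_section()}, **kwargs)


@pytest.fixture(scope="session")
def reference_counts():
    return load_reference_counts()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def frame():
    return IdealizedFrame()
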