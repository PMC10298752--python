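import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from elastoca import ObservableSeries, SimulationConfig


def series_from_attached(areas):
    """Minimal observable series with a prescribed attached-area trajectory."""
    s = ObservableSeries()
    for t, a in enumerate(areas):
        s.append(
            {
                "step": t,
                "monomer_content_sum": 0.0,
                "monomer_cell_count": 0,
                "n_attached": 0,
                "area_attached": a,
                "n_unattached": 0,
                "area_unattached": 0,
                "mean_area_unattached_ge3": 0.0,
            }
        )
    return s


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """20x20 domain, short run: exercises every code path cheaply."""
    return SimulationConfig(
        n=20, tile_area_px=100.0, linewidth_px=2, total_Time=60, generate_Time=30, seed=3
    )
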