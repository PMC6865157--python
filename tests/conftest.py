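import numpy as np
import pandas as pd
import pytest

from genolrt.panel_io import HaplotypePanel
from genolrt.panel_synth import PanelConfig, apoe_like_config, synth_panel


def make_panel(haplotypes) -> HaplotypePanel:
    """Wrap a raw 0/1 matrix into a panel with generic metadata."""
    hap = np.asarray(haplotypes, dtype=np.int8)
    meta = pd.DataFrame(
        {
            "id": [f"v{k}" for k in range(hap.shape[1])],
            "pos": np.arange(1, hap.shape[1] + 1) * 10,
            "ref": "A",
            "alt": "T",
        }
    )
    return HaplotypePanel(haplotypes=hap, variant_meta=meta)


@pytest.fixture(scope="session")
def apoe_config():
    return apoe_like_config()


@pytest.fixture(scope="session")
def apoe_panel(apoe_config):
    """The canonical reference panel (1092 individuals, 33 variants)."""
    return synth_panel(apoe_config)


@pytest.fixture(scope="session")
def variant_index(apoe_config):
    ids = apoe_config.variant_ids
    return {v: ids.index(v) for v in ids}


@pytest.fixture()
def small_region_config():
    """A 10-variant region with common, independent-ish variants: every
    variant is testable, so search combinatorics are exact."""
    rng = np.random.default_rng(123)
    freqs = np.linspace(0.12, 0.45, 10)
    blocks = [
        (np.array([[1], [0]], dtype=np.int8), np.array([q, 1 - q])) for q in freqs
    ]
    return PanelConfig(blocks=blocks, n_individuals=300, seed=5)
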