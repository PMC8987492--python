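import numpy as np
import pandas as pd
import pytest

from boablup import FounderSimConfig, HaplotypePanel, MarkerMap, simulate_founder_breeds


def make_map(positions_bp, chromosome=1, morgan_per_bp=1e-8):
    """Single-chromosome map at the given bp positions (1 cM/Mb default)."""
    positions_bp = list(positions_bp)
    return MarkerMap(pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(len(positions_bp))],
        "chromosome": chromosome,
        "position_bp": positions_bp,
        "genetic_pos_morgan": [p * morgan_per_bp for p in positions_bp],
    }))


def make_panel(haps, breed="AN", marker_map=None, sires=None, dams=None, prefix="I"):
    haps = np.asarray(haps, dtype=np.uint8)
    n = haps.shape[0]
    if marker_map is None:
        marker_map = make_map(range(1, haps.shape[2] + 1))
    table = pd.DataFrame({
        "id": [f"{prefix}{j}" for j in range(n)],
        "sire_id": sires if sires is not None else [None] * n,
        "dam_id": dams if dams is not None else [None] * n,
        "breed_label": breed,
    })
    return HaplotypePanel(table, haps, marker_map)


@pytest.fixture(scope="session")
def small_founders():
    """Modest two-breed founder simulation shared across tests."""
    cfg = FounderSimConfig(
        n_markers=1200, n_chromosomes=3, breed_sizes={"AN": 300, "HF": 400},
        n_pool_haplotypes=60, seed=42,
    )
    return cfg, simulate_founder_breeds(cfg)
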