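import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from areacomp import CellTable, qc_filter
from areacomp.spatial import CubeletTable, make_cubelets
from areacomp.synthetic import SimulationConfig, simulate

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def build_cells(reads, genes_detected, n_genes=104, **obs_kwargs):
    """Cell table with prescribed per-cell totals and detection counts."""
    n = len(reads)
    counts = np.zeros((n, n_genes), dtype=int)
    for i, (r, g) in enumerate(zip(reads, genes_detected)):
        assert g <= n_genes and r >= g
        counts[i, 1:g] = 1
        counts[i, 0] = r - (g - 1)
    obs = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "brain": obs_kwargs.get("brain", "b0"),
        "litter": obs_kwargs.get("litter", "l0"),
        "condition": obs_kwargs.get("condition", "control"),
        "slice": obs_kwargs.get("slice", 0),
        "x_um": np.arange(n, dtype=float),
        "depth": np.linspace(0.1, 0.9, n),
        "area": obs_kwargs.get("area", "A"),
    })
    genes = ["Slc17a7", "Gad1"] + [f"g{i}" for i in range(2, n_genes)]
    return CellTable(obs, sp.csr_matrix(counts), genes)


def build_cubelet_table(composition, area, brain, litter=None, condition=None,
                        slice_index=None):
    """CubeletTable from explicit composition rows and metadata vectors."""
    comp = np.asarray(composition, dtype=float)
    n = comp.shape[0]
    ids = pd.Index([f"cb{i:04d}" for i in range(n)], name="cubelet_id")
    meta = pd.DataFrame({
        "cubelet_id": ids,
        "brain": brain if not np.isscalar(brain) else [brain] * n,
        "litter": litter if litter is not None else ["l0"] * n,
        "condition": condition if condition is not None else ["control"] * n,
        "slice": slice_index if slice_index is not None else [0] * n,
        "x_start": np.arange(n, dtype=float) * 180,
        "x_end": (np.arange(n, dtype=float) + 1) * 180,
        "area": area if not np.isscalar(area) else [area] * n,
        "n_cells": 100, "n_excitatory": 80,
    }).reset_index(drop=True)
    cols = [f"T{j}" for j in range(comp.shape[1])]
    comp_df = pd.DataFrame(comp, index=ids, columns=cols)
    pb = pd.DataFrame(comp, index=ids, columns=cols)
    return CubeletTable(meta=meta, composition=comp_df, pseudobulk=pb,
                        raw_pseudobulk=pb, assignment=pd.Series(dtype=object))


@pytest.fixture(scope="session")
def typing_sim():
    """Separable 3-H2 x 2-H3 simulation at 20,000 cells, with the full
    typing pipeline (H1 split + recursive clustering) already run."""
    from areacomp.celltypes import assign_h1, cluster_recursive
    from areacomp.synthetic import build_panel

    cfg = SimulationConfig(seed=42, n_h2=3, h3_per_h2=2, n_inhibitory=2,
                           n_litters=1, n_slices=1, cells_per_um=1.55)
    cells, truth = simulate(cfg)
    cells = qc_filter(cells)
    panel = build_panel(cfg)
    assign_h1(cells, panel, seed=0)
    tax = cluster_recursive(cells, seed=0)
    return cfg, cells, truth, tax


@pytest.fixture(scope="session")
def small_sim():
    """Modest default-structure simulation shared across tests."""
    cfg = SimulationConfig(seed=5, n_litters=2, n_slices=2, cells_per_um=0.4)
    cells, truth = simulate(cfg)
    cells = qc_filter(cells)
    truth.apply_labels(cells)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def small_cubelets(small_sim):
    _, cells, _ = small_sim
    return make_cubelets(cells, target_width_um=180.0)
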