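"""Shared fixtures: one synthetic study dataset generated at default
conditions and reused (read-only) across the suite, plus small toy objects."""

import warnings

import numpy as np
import pytest

import floratlas as fa


@pytest.fixture(scope="session")
def synth():
    """Default synthetic study: dome map, nuclei, reconstruction, LOOCV."""
    smap, truth = fa.make_meristem_map(n_cells=300, n_ref_genes=8, seed=1)
    expr, labels, truth = fa.simulate_nuclei(
        smap, truth, n_nuclei=1000, n_probe_genes=50, noise_sd=0.3,
        dropout=0.2, contaminant_frac=0.1, seed=1)
    result = fa.reconstruct(expr, smap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        loocv = fa.loocv_reference_genes(
            result.expr, result.spatial_map, fa.OTConfig(),
            fa.DistanceConfig(), exclude=fa.GeneSet([]))
    return {
        "map": smap, "truth": truth, "expr": expr, "labels": labels,
        "result": result, "loocv": loocv,
    }


@pytest.fixture
def toy_map():
    """6-cell, 2-reference-gene map with a simple geometry."""
    coords = np.array([
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0],
        [0.0, 1.0, 0.0], [1.0, 1.0, 0.0], [2.0, 1.0, 0.0],
    ])
    expr = np.array([[1, 0], [1, 0], [1, 1], [0, 1], [0, 1], [1, 1]])
    return fa.SpatialMap([f"c{i}" for i in range(6)], coords,
                         ["G1", "G2"], expr)


@pytest.fixture
def toy_expr():
    """5-nuclei × 4-gene matrix (first two genes mirror the toy map's)."""
    values = np.array([
        [1.0, 0.0, 2.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
        [0.0, 2.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 2.0],
        [3.0, 0.0, 2.5, 0.0],
    ])
    return fa.ExpressionMatrix([f"n{i}" for i in range(5)],
                               ["G1", "G2", "G3", "G4"], values)
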