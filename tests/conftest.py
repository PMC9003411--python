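"""Shared fixtures: the default synthetic trial, its feature table,
and benchmark values from a published sugarcane field trial (GRA
ranking, VI correlation matrix, irrigation confusion counts) used as
fixed inputs for the reporting-side computations."""

import numpy as np
import pandas as pd
import pytest

import canespec as cs

# --- benchmark inputs: sugarcane trial, 3 irrigation x 5 fertilizer
# levels, 324 grid samples --------------------------------------------

#: grey relational degree of each VI with the measured CNC
BENCHMARK_GRD = {
    "SRPI": 0.94, "NPCI": 0.93, "RVI": 0.92, "MSRI": 0.89, "NDVI": 0.88,
    "SIPI": 0.87, "OSAVI": 0.84, "SAVI": 0.82, "NGBDI": 0.70, "RVI2": 0.58,
}

#: upper triangle of the VI Pearson correlation matrix, same trial
_VI_ORDER = ["SRPI", "NPCI", "RVI", "MSRI", "NDVI", "SIPI", "OSAVI", "SAVI", "NGBDI", "RVI2"]
_VI_CORR_UPPER = [
    [1.00, -0.97, 0.98, 0.98, 0.98, -0.96, 0.98, 0.97, -0.54, 0.15],
    [np.nan, 1.00, -0.96, -0.96, -0.96, 0.99, -0.98, -0.99, 0.60, -0.20],
    [np.nan, np.nan, 1.00, 1.00, 1.00, -0.93, 0.99, 0.97, -0.51, 0.14],
    [np.nan, np.nan, np.nan, 1.00, 1.00, -0.93, 0.99, 0.98, -0.52, 0.14],
    [np.nan, np.nan, np.nan, np.nan, 1.00, -0.94, 0.99, 0.98, -0.52, 0.14],
    [np.nan, np.nan, np.nan, np.nan, np.nan, 1.00, -0.96, -0.97, 0.62, -0.21],
    [np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.00, 1.00, -0.53, 0.13],
    [np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.00, -0.53, 0.12],
    [np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.00, -0.88],
    [np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.00],
]


def benchmark_vi_correlations() -> pd.DataFrame:
    m = np.array(_VI_CORR_UPPER)
    iu = np.isnan(m)
    m[iu] = m.T[iu]  # symmetrize from the upper triangle
    return pd.DataFrame(m, index=_VI_ORDER, columns=_VI_ORDER)


#: pooled 3-fold confusion counts, rows actual / cols predicted,
#: classes ordered Irrigation_0, Irrigation_180, Irrigation_300
BENCHMARK_SVM_COUNTS = [[94, 13, 1], [5, 89, 14], [0, 30, 78]]
BENCHMARK_BPNN_COUNTS = [[80, 25, 3], [15, 61, 32], [2, 47, 59]]


@pytest.fixture(scope="session")
def dataset():
    return cs.generate_dataset(cs.TreatmentDesign.default(), cs.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def feature_table(dataset):
    return cs.build_feature_table(dataset)


@pytest.fixture(scope="session")
def benchmark_gra() -> cs.GraResult:
    grd = pd.Series(BENCHMARK_GRD)
    order = sorted(grd.index, key=lambda c: (-grd[c], c))
    rank = pd.Series({c: i + 1 for i, c in enumerate(order)})
    return cs.GraResult(reference="cnc", grd=grd, rank=rank[grd.index])


@pytest.fixture(scope="session")
def benchmark_corr() -> pd.DataFrame:
    return benchmark_vi_correlations()
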