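"""Published benchmark results on the ten FunCat yeast datasets.

Reference AU(PRC) comparison matrices for eight hierarchical multi-label
classifiers — the four HMC-LMLP variants (Labels, Predicted, True,
NoLabels), the predictive-clustering-tree methods Clus-HMC, Clus-HSC and
Clus-SC, and the ant-colony rule learner hmAnt-Miner — on the standard
FunCat-annotated yeast benchmarks (Seq, Pheno, Cellcycle, Church, Derisi,
Eisen, Expr, Gasch1, Gasch2, Spo).  One 10×8 matrix per evaluation measure:
pooled AU(PRC), frequency-weighted mean per-class AUPRC, and uniform mean
per-class AUPRC.

These grids are distributed with the package as inputs for the rank-based
method-comparison machinery (:func:`hmclmlp.evaluation.average_ranks`);
they are reference numbers, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["METHODS", "DATASETS", "AU_PRC_MICRO", "AUPRC_WEIGHTED",
           "AUPRC_UNIFORM", "TABLES", "EISEN_SUMMARY"]

METHODS = [
    "Labels", "Predicted", "True", "NoLabels",
    "Clus-HMC", "Clus-HSC", "Clus-SC", "hmAnt-Miner",
]

DATASETS = [
    "Cellcycle", "Church", "Derisi", "Eisen", "Gasch1",
    "Gasch2", "Pheno", "Spo", "Expr", "Seq",
]


def _table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, index=DATASETS, columns=METHODS, dtype=float)


#: Pooled (micro-averaged) AU(PRC) on the test split of each dataset.
AU_PRC_MICRO = _table([
    [0.185, 0.207, 0.203, 0.205, 0.172, 0.111, 0.106, 0.155],
    [0.164, 0.173, 0.167, 0.169, 0.170, 0.131, 0.128, 0.165],
    [0.171, 0.183, 0.176, 0.182, 0.175, 0.094, 0.089, 0.149],
    [0.208, 0.245, 0.236, 0.240, 0.204, 0.127, 0.132, 0.181],
    [0.196, 0.236, 0.229, 0.234, 0.205, 0.106, 0.104, 0.173],
    [0.184, 0.211, 0.201, 0.208, 0.195, 0.121, 0.119, 0.152],
    [0.159, 0.159, 0.158, 0.159, 0.160, 0.152, 0.149, 0.161],
    [0.172, 0.186, 0.180, 0.184, 0.186, 0.103, 0.098, 0.177],
    [0.196, 0.243, 0.238, 0.240, 0.210, 0.127, 0.123, 0.180],
    [0.195, 0.236, 0.233, 0.232, 0.211, 0.091, 0.095, 0.186],
])

#: Frequency-weighted mean of the per-class AUPRC values.
AUPRC_WEIGHTED = _table([
    [0.145, 0.184, 0.178, 0.181, 0.142, 0.146, 0.146, 0.133],
    [0.118, 0.131, 0.129, 0.127, 0.129, 0.127, 0.128, 0.123],
    [0.127, 0.146, 0.141, 0.144, 0.137, 0.125, 0.122, 0.132],
    [0.163, 0.221, 0.210, 0.213, 0.183, 0.169, 0.173, 0.151],
    [0.157, 0.213, 0.207, 0.211, 0.176, 0.154, 0.153, 0.154],
    [0.142, 0.185, 0.174, 0.179, 0.156, 0.148, 0.147, 0.142],
    [0.114, 0.125, 0.118, 0.123, 0.124, 0.125, 0.127, 0.121],
    [0.129, 0.152, 0.148, 0.150, 0.153, 0.139, 0.139, 0.139],
    [0.167, 0.236, 0.232, 0.233, 0.179, 0.167, 0.167, 0.159],
    [0.166, 0.220, 0.218, 0.219, 0.183, 0.151, 0.154, 0.155],
])

#: Uniform (1/|C|) mean of the per-class AUPRC values.
AUPRC_UNIFORM = _table([
    [0.022, 0.035, 0.031, 0.033, 0.034, 0.036, 0.038, 0.030],
    [0.019, 0.023, 0.022, 0.022, 0.029, 0.029, 0.031, 0.026],
    [0.020, 0.027, 0.024, 0.025, 0.033, 0.029, 0.028, 0.031],
    [0.027, 0.048, 0.041, 0.043, 0.052, 0.052, 0.055, 0.039],
    [0.024, 0.046, 0.041, 0.045, 0.049, 0.047, 0.047, 0.036],
    [0.022, 0.038, 0.031, 0.033, 0.039, 0.042, 0.037, 0.032],
    [0.019, 0.023, 0.021, 0.022, 0.030, 0.031, 0.031, 0.028],
    [0.021, 0.027, 0.026, 0.026, 0.035, 0.038, 0.034, 0.032],
    [0.021, 0.053, 0.051, 0.051, 0.052, 0.054, 0.050, 0.038],
    [0.019, 0.041, 0.041, 0.041, 0.053, 0.043, 0.042, 0.036],
])

TABLES = {
    "au_prc_micro": AU_PRC_MICRO,
    "auprc_weighted": AUPRC_WEIGHTED,
    "auprc_uniform": AUPRC_UNIFORM,
}

#: Structure of the Eisen dataset as distributed (training split size,
#: total class count, classes per level) — used to validate ingestion when
#: the public files are available locally.
EISEN_SUMMARY = {
    "n_train": 1058,
    "n_classes": 461,
    "level_sizes": [18, 76, 165, 131, 67, 4],
    "predicted_au_prc_micro": 0.245,
}
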