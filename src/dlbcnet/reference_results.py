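"""Reported reference results for DLBCNet on the public blood-cell dataset.

The original DLBCNet study evaluated the full pipeline (GAN-augmented
training set, fine-tuned ResNet50 trunk, voting ensemble of randomized
networks) on the four-class Kaggle blood-cell dataset over five independent
runs.  The per-run, per-class metrics it reported are reproduced here as
plain data: they serve as the worked-example input to the aggregation
arithmetic in :mod:`dlbcnet.metrics` (run averaging followed by macro
averaging), and as a sanity anchor for the metric formulas.  Reproducing the
underlying classifier runs themselves requires the external image dataset
and a pre-trained trunk and is out of scope here.

All values are percentages as printed (two decimals).
"""

from __future__ import annotations

import pandas as pd

from .metrics import METRIC_NAMES, MetricsReport

CLASS_NAMES = ["Eosinophil", "Lymphocyte", "Monocyte", "Neutrophil"]

# run -> class -> (accuracy, sensitivity, precision, specificity, f1), in %
PER_RUN_PER_CLASS = {
    1: {
        "Eosinophil": (94.31, 91.00, 95.41, 86.54, 93.15),
        "Lymphocyte": (98.74, 99.76, 99.95, 99.84, 99.85),
        "Monocyte": (95.77, 87.66, 99.97, 99.91, 93.41),
        "Neutrophil": (93.90, 93.79, 95.41, 87.19, 94.59),
    },
    2: {
        "Eosinophil": (95.76, 92.83, 96.74, 90.46, 94.74),
        "Lymphocyte": (97.63, 100.00, 100.00, 100.00, 100.00),
        "Monocyte": (94.33, 86.55, 99.97, 99.91, 92.78),
        "Neutrophil": (92.05, 93.95, 94.40, 84.83, 94.17),
    },
    3: {
        "Eosinophil": (96.26, 92.28, 97.58, 92.72, 94.86),
        "Lymphocyte": (97.42, 100.00, 99.97, 99.92, 99.99),
        "Monocyte": (94.41, 87.66, 99.97, 99.91, 93.41),
        "Neutrophil": (91.68, 94.51, 93.95, 83.89, 94.23),
    },
    4: {
        "Eosinophil": (95.50, 91.80, 96.74, 90.36, 94.20),
        "Lymphocyte": (97.53, 99.60, 100.00, 100.00, 99.81),
        "Monocyte": (94.56, 87.50, 99.97, 99.91, 93.32),
        "Neutrophil": (91.55, 93.15, 93.98, 83.75, 93.56),
    },
    5: {
        "Eosinophil": (95.68, 92.52, 96.74, 90.42, 94.58),
        "Lymphocyte": (97.63, 100.00, 100.00, 100.00, 100.00),
        "Monocyte": (94.35, 86.54, 100.00, 100.00, 92.79),
        "Neutrophil": (91.96, 93.95, 94.27, 84.53, 94.11),
    },
}

# reported run-averaged per-class table, in %
REPORTED_PER_CLASS = {
    "Eosinophil": (95.50, 92.09, 96.64, 90.16, 94.31),
    "Lymphocyte": (97.79, 99.87, 99.98, 99.95, 99.93),
    "Monocyte": (94.68, 87.18, 99.98, 99.93, 93.14),
    "Neutrophil": (92.23, 93.87, 94.40, 84.84, 94.13),
}

# reported overall macro averages, in %
REPORTED_MACRO = {
    "accuracy": 95.05,
    "sensitivity": 93.25,
    "precision": 97.75,
    "specificity": 93.72,
    "f1": 95.38,
}

# reference per-class train/test composition: class -> (original train,
# synthetic train, original test); the augmented training split adds 3000
# synthetic images per class, the test split stays original-only
DATASET_COMPOSITION = {
    "Eosinophil": (2184, 3000, 936),
    "Lymphocyte": (2172, 3000, 931),
    "Monocyte": (2169, 3000, 929),
    "Neutrophil": (2186, 3000, 937),
}


def per_run_reports(scale: float = 0.01) -> list[MetricsReport]:
    """The five reported runs as MetricsReport objects (fractions by default)."""
    reports = []
    for run, table in sorted(PER_RUN_PER_CLASS.items()):
        df = pd.DataFrame.from_dict(table, orient="index", columns=METRIC_NAMES)
        df.index.name = "class"
        reports.append(MetricsReport(df * scale, run_id=f"run{run}"))
    return reports


def reported_per_class_frame(scale: float = 0.01) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(REPORTED_PER_CLASS, orient="index",
                                columns=METRIC_NAMES)
    df.index.name = "class"
    return df * scale
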