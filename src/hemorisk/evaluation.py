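"""Prediction-quality reporting: mean error and its spread per learner.

"Mean error" is the mean absolute residual on unit-scaled labels (percent /
100); "std" is the population standard deviation of the residuals.  A signed
mean is available via ``metric="signed"`` for bias diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import build_basis, predict
from .deep_layers import TrainingSet
from .learners import ALGORITHMS, FitResult, INNConfig, LSLCConfig, SCEConfig, fit


@dataclass
class EvaluationReport:
    """mean_error / std_error / n per (algorithm, partition) cell."""

    table: pd.DataFrame  # columns: algorithm, partition, mean_error, std_error, n

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def cell(self, algorithm: str, partition: str) -> dict:
        rows = self.table[
            (self.table["algorithm"] == algorithm)
            & (self.table["partition"] == partition)
        ]
        return rows.iloc[0].to_dict()

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def evaluate_model(
    fr: FitResult, ts: TrainingSet, partition: str, metric: str = "absolute"
) -> tuple[float, float]:
    """Mean (absolute) error and population std of residuals on one partition.

    Residuals are computed on unit-scaled labels (percent / 100).
    """
    part = ts.partition(partition) if ts.split_tag is not None else ts
    if part.m == 0:
        raise ValueError(f"partition {partition!r} is empty")
    y = part.d_tr / 100.0
    e = y - predict(fr.w, build_basis(part.d_e))
    if metric == "absolute":
        mean_error = float(np.mean(np.abs(e)))
    elif metric == "signed":
        mean_error = float(np.mean(e))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return mean_error, float(np.std(e, ddof=0))


def compare_algorithms(
    ts: TrainingSet,
    inn: INNConfig = INNConfig(),
    lslc: LSLCConfig = LSLCConfig(),
    sce: SCEConfig = SCEConfig(),
    algorithms: tuple = ALGORITHMS,
) -> tuple[EvaluationReport, dict[str, FitResult]]:
    """Fit every learner on the train partition and score both partitions.

    A learner that raises is flagged with NaN cells; the others still report.
    """
    if ts.split_tag is None:
        raise ValueError("training set must be split before comparison")
    rows = []
    fits: dict[str, FitResult] = {}
    for algo in algorithms:
        try:
            fr = fit(algo, ts, inn=inn, lslc=lslc, sce=sce)
            fits[algo] = fr
            for partition in ("train", "test"):
                me, se = evaluate_model(fr, ts, partition)
                rows.append(
                    {
                        "algorithm": algo,
                        "partition": partition,
                        "mean_error": me,
                        "std_error": se,
                        "n": ts.partition(partition).m,
                    }
                )
        except Exception as exc:  # one learner failing must not kill the report
            for partition in ("train", "test"):
                rows.append(
                    {
                        "algorithm": algo,
                        "partition": partition,
                        "mean_error": np.nan,
                        "std_error": np.nan,
                        "n": 0,
                        "error": str(exc),
                    }
                )
    return EvaluationReport(table=pd.DataFrame(rows)), fits


def prediction_dump(fr: FitResult, ts: TrainingSet) -> pd.DataFrame:
    """Per-sample label vs prediction table (percent scale), for plotting."""
    y_hat = predict(fr.w, build_basis(ts.d_e)) * 100.0
    return pd.DataFrame(
        {
            "label": ts.d_tr,
            "prediction": y_hat,
            "split": ts.split_tag if ts.split_tag is not None else "",
        }
    )
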