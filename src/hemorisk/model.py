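"""Model/results objects tying the pipeline together.

``HealthRiskModel`` holds a self-labelled training set (normalized analyte
rows + signed-percent risk labels) and fits the 35-parameter norm-power
basis predictor with any of the four learners; ``fit`` returns a
``HealthRiskResults`` carrying the weights, the objective trace, per-
partition error metrics and a printable ``summary()``.

Typical use::

    records = synthetic.generate_panels(GeneratorConfig(n=20000, seed=7))
    model = HealthRiskModel.from_records(records, seed=7)
    res = model.fit(method="bls")
    print(res.summary())
    risk_percent = res.predict(new_normalized_rows)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import deep_layers, panel_io
from .basis import BASIS_COLUMN_NAMES, build_basis, predict as _basis_predict
from .deep_layers import (
    EliminationConfig,
    SelectionConfig,
    SelectionSummary,
    TrainingSet,
)
from .evaluation import evaluate_model
from .learners import ALGORITHMS, FitResult, INNConfig, LSLCConfig, SCEConfig, fit


class HealthRiskModel:
    """Risk regression on a self-labelled blood-panel training set."""

    def __init__(self, training_set: TrainingSet):
        if training_set.m == 0:
            raise ValueError("training set is empty")
        self.training_set = training_set
        self.selection_summary: SelectionSummary | None = None
        self.normalization_bounds = None

    @classmethod
    def from_records(
        cls,
        records,
        a_fe: float = 1.0,
        i_t: int = 300,
        interval_width: int = 10,
        split_fraction: float = 0.75,
        seed: int = 0,
    ) -> "HealthRiskModel":
        """Run the full preprocessing stack on raw panel records.

        normalize -> stats -> band elimination -> self-weighting ->
        interval-balanced selection -> stratified split.
        """
        raw = panel_io.records_to_matrix(records)
        norm, bounds = panel_io.min_max_normalize(raw)
        stats = panel_io.analyte_stats(norm)
        keep = deep_layers.eliminate_normal_records(
            norm, stats, EliminationConfig(a_fe=a_fe)
        )
        wp = deep_layers.self_weight(norm, stats, keep)
        ts, summary = deep_layers.select_by_interval(
            wp, SelectionConfig(i_t=i_t, interval_width=interval_width)
        )
        ts = deep_layers.split_train_test(ts, fraction=split_fraction, seed=seed)
        model = cls(ts)
        model.selection_summary = summary
        model.normalization_bounds = bounds
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HealthRiskModel":
        """Build from a raw panel DataFrame with the canonical CSV columns."""
        records = [
            panel_io.BloodPanelRecord(
                subject_id=str(row["subject_id"]),
                age=int(row["age"]),
                gender=int(row["gender"]),
                **{a: float(row[a]) for a in panel_io.ANALYTES},
            )
            for _, row in df.iterrows()
        ]
        return cls.from_records(records, **kwargs)

    def fit(
        self,
        method: str = "bls",
        inn: INNConfig = INNConfig(),
        lslc: LSLCConfig = LSLCConfig(),
        sce: SCEConfig = SCEConfig(),
    ) -> "HealthRiskResults":
        if method not in ALGORITHMS:
            raise ValueError(f"method must be one of {ALGORITHMS}, got {method!r}")
        fr = fit(method, self.training_set, inn=inn, lslc=lslc, sce=sce)
        return HealthRiskResults(self, fr)


class HealthRiskResults:
    """Fitted weights plus diagnostics for one learner on one training set."""

    def __init__(self, model: HealthRiskModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    @property
    def params(self) -> pd.Series:
        """The 35 basis weights, indexed by basis column name."""
        return pd.Series(self.fit_result.w, index=list(BASIS_COLUMN_NAMES))

    @property
    def algorithm(self) -> str:
        return self.fit_result.algorithm

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def error_trace(self) -> np.ndarray:
        return np.asarray(self.fit_result.error_trace)

    def predict(self, d_e: np.ndarray) -> np.ndarray:
        """Predicted risk (percent scale) for normalized analyte rows."""
        return _basis_predict(self.fit_result.w, build_basis(d_e)) * 100.0

    def evaluate(self, partition: str = "test", metric: str = "absolute"):
        """(mean_error, std_error) on unit-scaled labels for one partition."""
        return evaluate_model(self.fit_result, self.model.training_set,
                              partition, metric=metric)

    def summary(self) -> str:
        ts = self.model.training_set
        lines = [
            "Health Risk Basis Regression Results",
            "=" * 52,
            f"Algorithm:        {self.algorithm.upper()}",
            f"No. parameters:   {self.fit_result.w.size}",
            f"Converged:        {self.converged}",
            f"Final sq. error:  {self.error_trace[-1]:.6g}",
        ]
        if ts.split_tag is not None:
            for part in ("train", "test"):
                me, se = self.evaluate(part)
                n = ts.partition(part).m
                lines.append(
                    f"{part.capitalize():<5} (n={n:>5}):  "
                    f"mean |error| {me:.4f},  std {se:.4f}"
                )
        lines.append("=" * 52)
        top = self.params.abs().sort_values(ascending=False).head(5)
        lines.append("Largest-magnitude weights:")
        for name in top.index:
            lines.append(f"  {name:<12} {self.params[name]:>10.4f}")
        return "\n".join(lines)
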