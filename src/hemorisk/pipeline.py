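"""End-to-end pipeline orchestration with a run config and a run manifest.

``run_pipeline`` executes normalize -> stats -> eliminate -> self-weight ->
select -> split -> fit (all four learners) -> evaluate, writing every stage
artifact plus a JSON manifest (config echo, seed, stage record counts).  The
manifest is deterministic: identical config + seed give byte-identical
manifests.  A stage failure aborts with the stage name and removes the
partial artifacts of this run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from . import deep_layers, panel_io
from .deep_layers import EliminationConfig, SelectionConfig
from .evaluation import EvaluationReport, compare_algorithms
from .learners import INNConfig, LSLCConfig, SCEConfig
from .synthetic import GeneratorConfig, generate_panels


@dataclass
class RunConfig:
    """Pipeline-wide parameters (study-condition defaults)."""

    a_fe: float = 1.0
    i_t: int = 300
    interval_width: int = 10
    eta: float = 0.05
    eta_c: float = 0.05
    lslc_alpha: float = 1.0  # scalar; expanded to a constant 35-vector
    lslc_p: float = 10.0
    inn_epochs: int = 1
    sce_n: int = 10
    sce_A: int = 4
    sce_q: int = 5
    sce_alpha: int = 3
    sce_beta: int = 5
    sce_Omega: int = 100
    sce_f_q: float = 0.0
    sce_bound: float = 10.0
    split_fraction: float = 0.75
    seed: int = 0
    simulate_n: int = 0  # > 0: generate a synthetic panel instead of reading
    input_csv: str | None = None
    out_dir: str = "hemorisk_run"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a key-value config file; CLI overrides win; unknown keys rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a mapping of key: value pairs")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def sub_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the run seed."""
        h = np.random.SeedSequence([self.seed & 0x7FFFFFFF,
                                    sum(map(ord, stage))])
        return int(h.generate_state(1)[0] % (2**31))

    def learner_configs(self) -> tuple[INNConfig, LSLCConfig, SCEConfig]:
        return (
            INNConfig(eta=self.eta, epochs=self.inn_epochs),
            LSLCConfig(eta_c=self.eta_c,
                       alpha=np.full(35, self.lslc_alpha), p=self.lslc_p),
            SCEConfig(
                n=self.sce_n, A=self.sce_A, q=self.sce_q,
                alpha_sce=self.sce_alpha, beta_sce=self.sce_beta,
                Omega=self.sce_Omega, f_q=self.sce_f_q,
                bounds=(-self.sce_bound, self.sce_bound),
                seed=self.sub_seed("sce"),
            ),
        )


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_counts(records, a_fe: float = 1.0, i_t: int = 300) -> dict:
    """Record counts through each preprocessing stage (default conditions)."""
    raw = panel_io.records_to_matrix(records)
    norm, _ = panel_io.min_max_normalize(raw)
    stats = panel_io.analyte_stats(norm)
    keep = deep_layers.eliminate_normal_records(norm, stats,
                                                EliminationConfig(a_fe=a_fe))
    wp = deep_layers.self_weight(norm, stats, keep)
    ts, summary = deep_layers.select_by_interval(wp, SelectionConfig(i_t=i_t))
    per_bin = {
        f"existing_{int(r.interval):+d}_{tag}": int(r[f"existing_{tag}"])
        for _, r in summary.table.iterrows()
        for tag in ("pos", "neg")
    }
    return {
        "n_total": raw.n,
        "n_eliminated": keep.n_eliminated,
        "n_retained": keep.n_retained,
        "n_selected": ts.m,
        **per_bin,
    }


def run_pipeline(config: RunConfig) -> tuple[EvaluationReport, dict]:
    """Execute the full pipeline, writing artifacts and a run manifest.

    Returns the evaluation report and the manifest dict.  Either
    ``config.input_csv`` must name a panel CSV or ``config.simulate_n`` must
    request a synthetic panel.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    stage = "input"
    try:
        if config.simulate_n > 0:
            records = generate_panels(
                GeneratorConfig(n=config.simulate_n, seed=config.sub_seed("simulate"))
            )
            _write("panel.csv", lambda p: panel_io.write_panel_csv(records, p))
        elif config.input_csv:
            records = panel_io.read_panel_csv(config.input_csv)
        else:
            raise ValueError("config needs input_csv or simulate_n > 0")

        stage = "normalize"
        raw = panel_io.records_to_matrix(records)
        norm, bounds = panel_io.min_max_normalize(raw)
        stage = "stats"
        stats = panel_io.analyte_stats(norm)
        _write("stats.json", lambda p: p.write_text(json.dumps(
            {
                a: {
                    "min": float(bounds[0][j]), "max": float(bounds[1][j]),
                    "mean_norm": float(stats.mean[j]), "std_norm": float(stats.std[j]),
                }
                for j, a in enumerate(panel_io.ANALYTES)
            },
            indent=2, sort_keys=True,
        )))

        stage = "eliminate"
        keep = deep_layers.eliminate_normal_records(
            norm, stats, EliminationConfig(a_fe=config.a_fe)
        )
        stage = "self-weight"
        wp = deep_layers.self_weight(norm, stats, keep)
        stage = "select"
        ts, summary = deep_layers.select_by_interval(
            wp, SelectionConfig(i_t=config.i_t, interval_width=config.interval_width)
        )
        _write("selection_summary.csv", summary.to_csv)
        stage = "split"
        ts = deep_layers.split_train_test(
            ts, fraction=config.split_fraction, seed=config.sub_seed("split")
        )
        _write("training_set.csv", ts.to_csv)

        stage = "fit"
        inn, lslc, sce = config.learner_configs()
        report, fits = compare_algorithms(ts, inn=inn, lslc=lslc, sce=sce)
        for algo, fr in fits.items():
            _write(f"fit_{algo}.json",
                   lambda p, fr=fr: p.write_text(json.dumps(fr.to_dict())))
        stage = "evaluate"
        _write("evaluation_report.csv", report.to_csv)

        manifest = {
            "config": asdict(config),
            "seed": config.seed,
            "sub_seeds": {s: config.sub_seed(s)
                          for s in ("simulate", "split", "sce")},
            "stage_counts": {
                "n_total": raw.n,
                "n_eliminated": keep.n_eliminated,
                "n_retained": keep.n_retained,
                "n_selected": ts.m,
                "n_train": int((ts.split_tag == "train").sum()),
                "n_test": int((ts.split_tag == "test").sum()),
            },
        }
        _write("manifest.json", lambda p: p.write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        ))
        return report, manifest
    except Exception as exc:
        for path in written:  # drop partial artifacts of this failed run
            path.unlink(missing_ok=True)
        raise StageError(f"pipeline failed at stage {stage!r}: {exc}") from exc
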