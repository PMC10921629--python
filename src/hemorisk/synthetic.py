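"""Synthetic CBC panel generator emulating a screening-population dataset.

The generator reproduces the statistical structure the pipeline is built
for, without any real subjects:

* a heavily male-skewed population (default 8.6% female),
* analytes drawn from normal-component Gaussians centred on standard adult
  CBC reference values, with PLT an order of magnitude above the others,
* a minority of "abnormal" records in which 1-2 analytes are drawn from a
  shifted tail component — mostly on the low side, with high-side
  abnormalities deliberately scarce (default 15% of abnormal draws), which
  is what makes positive risk labels rare downstream,
* ages drawn from fixed bins with screening-population weights.

Everything is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel_io import ANALYTES, BloodPanelRecord, write_panel_csv


@dataclass(frozen=True)
class AnalyteParams:
    """Normal-component mean/sd and the low/high tail shifts, in lab units."""

    mean: float
    sd: float
    low_shift: float  # subtracted from mean for the low abnormal tail
    high_shift: float  # added to mean for the high abnormal tail


#: Normal-component parameters per analyte: adult CBC reference values.
#: HTC %, HGB g/dL, WBC 10^9/L, PLT 10^9/L, MPV fL.
DEFAULT_ANALYTE_PARAMS: dict[str, AnalyteParams] = {
    "htc": AnalyteParams(mean=42.0, sd=3.5, low_shift=14.0, high_shift=12.0),
    "hgb": AnalyteParams(mean=14.0, sd=1.3, low_shift=5.0, high_shift=4.0),
    "wbc": AnalyteParams(mean=7.0, sd=1.7, low_shift=4.5, high_shift=9.0),
    "plt": AnalyteParams(mean=250.0, sd=60.0, low_shift=170.0, high_shift=350.0),
    "mpv": AnalyteParams(mean=10.0, sd=0.9, low_shift=3.5, high_shift=3.0),
}

#: Age bins (years) with screening-population weights.
DEFAULT_AGE_BINS: tuple[tuple[int, int], ...] = (
    (18, 40),
    (41, 50),
    (51, 64),
    (65, 90),
)
DEFAULT_AGE_WEIGHTS: tuple[float, ...] = (0.492, 0.178, 0.076, 0.254)


def _normalized_age_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    return w / w.sum()


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic panel population."""

    n: int = 1000
    female_fraction: float = 0.086
    abnormal_fraction: float = 0.45
    high_side_share: float = 0.15
    analyte_params: dict = field(
        default_factory=lambda: dict(DEFAULT_ANALYTE_PARAMS)
    )
    age_bins: tuple = DEFAULT_AGE_BINS
    age_weights: tuple = DEFAULT_AGE_WEIGHTS
    abnormal_correlation: float = 0.0  # optional cross-analyte stress knob
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name in ("female_fraction", "abnormal_fraction", "high_side_share"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for a, p in self.analyte_params.items():
            if p.sd <= 0:
                raise ValueError(f"analyte {a}: sd must be > 0")
        if len(self.age_bins) != len(self.age_weights):
            raise ValueError("age_bins and age_weights length mismatch")


def generate_panels(c: GeneratorConfig) -> list[BloodPanelRecord]:
    """Draw a synthetic panel population, deterministic per seed."""
    rng = np.random.default_rng(c.seed)
    n = c.n

    gender = np.where(rng.random(n) < c.female_fraction, -1, 1)

    weights = _normalized_age_weights(c.age_weights)
    bin_idx = rng.choice(len(c.age_bins), size=n, p=weights)
    ages = np.array(
        [rng.integers(c.age_bins[b][0], c.age_bins[b][1] + 1) for b in bin_idx]
    )

    # normal component for everyone, tails patched in below
    values = np.empty((n, len(ANALYTES)))
    for j, a in enumerate(ANALYTES):
        p = c.analyte_params[a]
        values[:, j] = rng.normal(p.mean, p.sd, size=n)

    abnormal = rng.random(n) < c.abnormal_fraction
    for i in np.nonzero(abnormal)[0]:
        k = rng.integers(1, 3)  # 1 or 2 abnormal analytes per abnormal record
        if c.abnormal_correlation > 0 and rng.random() < c.abnormal_correlation:
            # correlated stress mode: shift HTC and HGB together
            cols = np.array([0, 1])[:k]
        else:
            cols = rng.choice(len(ANALYTES), size=k, replace=False)
        for j in cols:
            p = c.analyte_params[ANALYTES[j]]
            if rng.random() < c.high_side_share:
                centre = p.mean + p.high_shift
            else:
                centre = p.mean - p.low_shift
            values[i, j] = rng.normal(centre, p.sd / 2.0)

    values = np.clip(values, 0.0, None)  # lab values cannot be negative

    return [
        BloodPanelRecord(
            subject_id=f"S{i:06d}",
            age=int(ages[i]),
            gender=int(gender[i]),
            **{a: float(values[i, j]) for j, a in enumerate(ANALYTES)},
        )
        for i in range(n)
    ]


#: Frozen fixture contracts: (record count, seed) per size tag.
FIXTURE_SPECS = {"small": (500, 11), "medium": (5000, 12)}


def make_fixture(size: str, out_dir) -> tuple[Path, Path]:
    """Write a seeded panel CSV plus a manifest of expected pipeline counts.

    The manifest records what the pipeline itself computes on the fixture
    (eliminated/retained counts, per-bin existing counts) so regressions in
    any stage show up as count drift.
    """
    from .pipeline import stage_counts  # local import: pipeline imports us

    if size not in FIXTURE_SPECS:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SPECS)}, got {size!r}")
    n, seed = FIXTURE_SPECS[size]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = generate_panels(GeneratorConfig(n=n, seed=seed))
    csv_path = out_dir / f"panel_{size}.csv"
    write_panel_csv(records, csv_path)

    manifest = {"size": size, "n": n, "seed": seed, **stage_counts(records)}
    manifest_path = out_dir / f"panel_{size}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return csv_path, manifest_path
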