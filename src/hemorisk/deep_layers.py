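"""The self-supervised preprocessing stack: elimination, weighting, selection.

Three stages turn an unlabelled, mostly-normal panel into a balanced,
self-labelled training set:

1. **Band elimination** — each analyte gets a "normal band"
   [mean - a_fe*std, mean + a_fe*std] from its own column statistics.  A
   record is dropped only when *all five* analytes sit inside their bands;
   one out-of-band value is enough to keep the whole record, because a single
   abnormal analyte already signals a health risk.  The band half-width
   multiplier ``a_fe`` is the tuning knob: larger bands eliminate more.

2. **Self-weighting** — every retained analyte value is mapped to a signed
   percentage: 0 inside the band, growing linearly with the excursion beyond
   the band edge, reaching -100 at the observed column minimum and +100 at
   the observed maximum (worst-case low / worst-case high).  A record's
   scalar risk label is its most abnormal analyte's weight.

3. **Interval selection** — labels are binned into signed 10%-wide risk
   intervals and each (interval, sign) cell contributes at most ``i_t``
   records, ranked most-extreme first.  This caps the over-represented
   mild-risk bins so no risk level dominates training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import (
    ANALYTES,
    AnalyteStats,
    DegenerateInputError,
    PanelMatrix,
    PanelValidationError,
)


@dataclass(frozen=True)
class EliminationConfig:
    """Band half-width multiplier for normal-record elimination."""

    a_fe: float = 1.0

    def __post_init__(self) -> None:
        if self.a_fe < 0:
            raise ValueError(f"a_fe must be >= 0, got {self.a_fe}")


@dataclass
class EliminationResult:
    """Keep/drop decision per record plus the per-analyte normal bands."""

    keep_mask: np.ndarray
    bounds: tuple[np.ndarray, np.ndarray]  # (lower, upper), each length 5
    a_fe: float

    @property
    def n_eliminated(self) -> int:
        return int((~self.keep_mask).sum())

    @property
    def n_retained(self) -> int:
        return int(self.keep_mask.sum())


@dataclass
class WeightedPanel:
    """Self-weights per retained record/analyte and the scalar record labels.

    Weights and labels are signed percentages in [-100, 100]; a weight is 0
    exactly when that analyte sits inside its normal band.
    """

    analyte_weights: np.ndarray  # N_r x 5
    record_label: np.ndarray  # length N_r
    source_rows: np.ndarray  # indices into the original panel
    values: np.ndarray  # N_r x 5 normalized analyte rows (for training)


@dataclass(frozen=True)
class SelectionConfig:
    """Per-interval quota and interval width for balanced selection."""

    i_t: int = 300
    interval_width: int = 10

    def __post_init__(self) -> None:
        if self.i_t < 1:
            raise ValueError(f"i_t must be >= 1, got {self.i_t}")
        if self.interval_width < 1 or 100 % self.interval_width != 0:
            raise ValueError(
                f"interval_width must divide 100, got {self.interval_width}"
            )


@dataclass
class SelectionSummary:
    """Existing/selected record counts per signed risk interval.

    One row per interval magnitude (10%, 20%, ... by default) with the
    existing and selected counts on the positive and negative sides.
    """

    table: pd.DataFrame  # columns: interval, existing_pos, selected_pos,
    #                                existing_neg, selected_neg

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def total_selected(self) -> int:
        return int(
            self.table["selected_pos"].sum() + self.table["selected_neg"].sum()
        )

    @property
    def total_existing(self) -> int:
        return int(
            self.table["existing_pos"].sum() + self.table["existing_neg"].sum()
        )


@dataclass
class TrainingSet:
    """Selected normalized analyte rows, their risk labels, and a split tag.

    ``d_e`` is M x 5, ``d_tr`` the aligned labels in percent, ``bin_id`` the
    signed interval each row was selected from, and ``split_tag`` either
    "train"/"test" per row or None before splitting.
    """

    d_e: np.ndarray
    d_tr: np.ndarray
    bin_id: np.ndarray
    source_rows: np.ndarray
    split_tag: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.d_e.shape[0]

    def partition(self, which: str) -> "TrainingSet":
        """Rows tagged 'train' or 'test' as a new (untagged) TrainingSet."""
        if self.split_tag is None:
            raise ValueError("training set has not been split")
        mask = self.split_tag == which
        return TrainingSet(
            d_e=self.d_e[mask],
            d_tr=self.d_tr[mask],
            bin_id=self.bin_id[mask],
            source_rows=self.source_rows[mask],
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.d_e, columns=[f"{a}_n" for a in ANALYTES])
        df["label"] = self.d_tr
        df["split"] = self.split_tag if self.split_tag is not None else ""
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainingSet":
        df = pd.read_csv(path)
        cols = [f"{a}_n" for a in ANALYTES]
        labels = df["label"].to_numpy(dtype=float)
        split = df["split"].astype(str).to_numpy()
        ts = cls(
            d_e=df[cols].to_numpy(dtype=float),
            d_tr=labels,
            bin_id=_bin_ids_for_labels(labels, 10),
            source_rows=np.arange(len(df)),
            split_tag=split if set(split) & {"train", "test"} else None,
        )
        return ts


def eliminate_normal_records(
    m: PanelMatrix, s: AnalyteStats, c: EliminationConfig = EliminationConfig()
) -> EliminationResult:
    """Drop records whose five analytes all lie inside their normal bands.

    The band for each analyte is [mean - a_fe*std, mean + a_fe*std]
    (inclusive); a record with even one analyte outside any band is kept.
    """
    if not m.normalized:
        raise PanelValidationError("elimination expects a normalized matrix")
    if m.values.shape[1] != s.mean.shape[0]:
        raise PanelValidationError("stats/matrix analyte count mismatch")
    lower = s.mean - c.a_fe * s.std
    upper = s.mean + c.a_fe * s.std
    inside = (m.values >= lower) & (m.values <= upper)
    keep = ~inside.all(axis=1)
    return EliminationResult(keep_mask=keep, bounds=(lower, upper), a_fe=c.a_fe)


def elimination_sweep(
    m: PanelMatrix, s: AnalyteStats, a_fe_values
) -> pd.DataFrame:
    """Eliminated-record counts across a sweep of band multipliers a_fe."""
    a_fe_values = list(a_fe_values)
    if not a_fe_values:
        raise ValueError("a_fe_values must be non-empty")
    rows = []
    for a in a_fe_values:
        res = eliminate_normal_records(m, s, EliminationConfig(a_fe=float(a)))
        rows.append({"a_fe": float(a), "n_eliminated": res.n_eliminated})
    return pd.DataFrame(rows)


def self_weight(
    m: PanelMatrix, s: AnalyteStats, keep: EliminationResult
) -> WeightedPanel:
    """Map each retained analyte value to a signed risk percentage.

    With band half-width beta = a_fe*std, excursions beyond the band are
    scaled side-specifically so the observed column extremes map to exactly
    -100 (minimum) and +100 (maximum):

        weight = 0                                    if |x - mean| <= beta
        weight = 100*sign(x-mean)*(|x-mean| - beta)/(D_side - beta)  else

    where D_side is (max - mean) above the band and (mean - min) below it.
    """
    if not m.normalized:
        raise PanelValidationError("self_weight expects a normalized matrix")
    beta = keep.a_fe * s.std
    dev = m.values[keep.keep_mask] - s.mean
    d_pos = s.max - s.mean
    d_neg = s.mean - s.min

    abs_excess = np.abs(dev) - beta
    out_of_band = abs_excess > 0
    side_scale = np.where(dev > 0, d_pos - beta, d_neg - beta)
    bad = out_of_band & (side_scale <= 0)
    if np.any(bad):
        names = sorted({ANALYTES[j] for j in np.nonzero(bad.any(axis=0))[0]})
        raise DegenerateInputError(
            "normal band reaches the observed extreme for analyte(s) "
            f"{', '.join(names)}: side scale is zero with out-of-band values"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(
            out_of_band,
            100.0 * np.sign(dev) * abs_excess / side_scale,
            0.0,
        )
    labels = np.array([assign_record_label(row) for row in w])
    return WeightedPanel(
        analyte_weights=w,
        record_label=labels,
        source_rows=np.nonzero(keep.keep_mask)[0],
        values=m.values[keep.keep_mask],
    )


def assign_record_label(analyte_weights) -> float:
    """Reduce a record's five analyte weights to one scalar risk label.

    The label is the weight of maximal absolute value — a record's risk is
    driven by its most abnormal analyte.  Exact |weight| ties break by fixed
    analyte priority HTC > HGB > WBC > PLT > MPV (argmax order).
    """
    w = np.asarray(analyte_weights, dtype=float)
    if np.all(w == 0):
        raise ValueError(
            "all-zero weights: record is fully in-band and should have been eliminated"
        )
    return float(w[np.argmax(np.abs(w))])


def _bin_ids_for_labels(labels: np.ndarray, width: int) -> np.ndarray:
    """Signed interval id per label: +k means (k-width, k], -k means [-k, -k+width).

    Every label in [-100, 100] \\ {0} falls in exactly one bin; the id is the
    bin's outer (signed) edge in percent.
    """
    labels = np.asarray(labels, dtype=float)
    mag = np.ceil(np.abs(labels) / width).astype(int) * width
    mag = np.clip(mag, width, 100)
    return np.where(labels >= 0, mag, -mag)


def select_by_interval(
    wp: WeightedPanel, c: SelectionConfig = SelectionConfig()
) -> tuple[TrainingSet, SelectionSummary]:
    """Cap each signed risk interval at i_t records, most-extreme first.

    Labels are binned into signed ``interval_width``-percent intervals; per
    bin and sign at most ``i_t`` records are selected, ranked by |label|
    descending (ties by source row index ascending).
    """
    if wp.record_label.size == 0:
        raise ValueError("weighted panel is empty")
    width = c.interval_width
    bin_ids = _bin_ids_for_labels(wp.record_label, width)

    edges = list(range(width, 101, width))
    rows = []
    selected_idx: list[np.ndarray] = []
    for k in edges:
        cells = {}
        for sign, tag in ((1, "pos"), (-1, "neg")):
            in_bin = np.nonzero(bin_ids == sign * k)[0]
            order = np.lexsort((in_bin, -np.abs(wp.record_label[in_bin])))
            take = in_bin[order][: c.i_t]
            selected_idx.append(take)
            cells[f"existing_{tag}"] = len(in_bin)
            cells[f"selected_{tag}"] = len(take)
        rows.append({"interval": k, **cells})

    summary = SelectionSummary(
        table=pd.DataFrame(
            rows,
            columns=[
                "interval",
                "existing_pos",
                "selected_pos",
                "existing_neg",
                "selected_neg",
            ],
        )
    )
    idx = np.concatenate(selected_idx) if selected_idx else np.array([], dtype=int)
    idx = np.sort(idx)
    ts = TrainingSet(
        d_e=wp.values[idx],
        d_tr=wp.record_label[idx],
        bin_id=bin_ids[idx],
        source_rows=wp.source_rows[idx],
    )
    return ts, summary


def split_train_test(ts: TrainingSet, fraction: float = 0.75, seed: int = 0) -> TrainingSet:
    """Stratified (per signed interval) train/test split, deterministic per seed.

    Each bin contributes round(fraction * bin size) training rows; the split
    permutation is drawn from a generator seeded by (seed, bin id).
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if ts.m == 0:
        raise ValueError("cannot split an empty training set")
    tags = np.empty(ts.m, dtype=object)
    for b in np.unique(ts.bin_id):
        rows = np.nonzero(ts.bin_id == b)[0]
        rng = np.random.default_rng([seed & 0x7FFFFFFF, int(b) + 200])
        perm = rng.permutation(len(rows))
        n_train = int(round(fraction * len(rows)))
        tags[rows[perm[:n_train]]] = "train"
        tags[rows[perm[n_train:]]] = "test"
    return TrainingSet(
        d_e=ts.d_e,
        d_tr=ts.d_tr,
        bin_id=ts.bin_id,
        source_rows=ts.source_rows,
        split_tag=tags.astype(str),
    )
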