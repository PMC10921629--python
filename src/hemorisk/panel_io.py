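"""Reading, writing and pre-processing of complete blood count (CBC) panels.

A panel row carries a subject's demographics (age in years, gender coded
-1 female / +1 male) and five analytes: hematocrit (HTC), hemoglobin (HGB),
white blood cell count (WBC), platelet count (PLT) and mean platelet volume
(MPV).  PLT is numerically an order of magnitude larger than the other four
analytes, so every downstream stage works on min-max normalized columns.

Normalization maps each analyte column to [0, 1] via (x - min)/(max - min);
the training (min, max) pairs are kept so that held-out data can be mapped
onto the same scale (held-out values may then fall outside [0, 1], which is
deliberate: the deviation information is what the risk labeller uses).

Column statistics use the population convention: std = sqrt(sum((x-m)^2)/N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed analyte column order used by every matrix in the package.
ANALYTES = ("htc", "hgb", "wbc", "plt", "mpv")

#: CSV schema for a blood panel table.
PANEL_COLUMNS = ("subject_id", "age", "gender") + ANALYTES

#: Default age bins (closed intervals in years) for age-grouped correlation.
DEFAULT_AGE_BINS = ((18, 37), (38, 64))


class PanelSchemaError(ValueError):
    """A required column is missing from a panel CSV."""


class PanelValidationError(ValueError):
    """A panel row violates a field invariant (gender code, negative value...)."""


class DegenerateInputError(ValueError):
    """An operation received input it is undefined on (constant column, ...)."""


@dataclass(frozen=True)
class BloodPanelRecord:
    """One subject's demographics and raw five-analyte panel."""

    subject_id: str
    age: int
    gender: int  # -1 female, +1 male
    htc: float
    hgb: float
    wbc: float
    plt: float
    mpv: float

    def __post_init__(self) -> None:
        if self.gender not in (-1, 1):
            raise PanelValidationError(
                f"gender must be -1 or +1, got {self.gender!r} "
                f"(subject {self.subject_id})"
            )
        if self.age <= 0:
            raise PanelValidationError(
                f"age must be positive, got {self.age!r} (subject {self.subject_id})"
            )
        for name in ANALYTES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise PanelValidationError(
                    f"{name} must be finite and >= 0, got {v!r} "
                    f"(subject {self.subject_id})"
                )

    @property
    def analytes(self) -> np.ndarray:
        """The five analyte values in canonical (HTC, HGB, WBC, PLT, MPV) order."""
        return np.array([getattr(self, a) for a in ANALYTES], dtype=float)


@dataclass
class PanelMatrix:
    """N x 5 analyte matrix in canonical column order.

    ``normalized`` is True once each column has been min-max mapped; on a
    training matrix every normalized column then spans exactly [0, 1].
    """

    values: np.ndarray
    row_ids: list = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(ANALYTES):
            raise PanelValidationError(
                f"panel matrix must be N x {len(ANALYTES)}, got {self.values.shape}"
            )
        if not self.row_ids:
            self.row_ids = [str(i) for i in range(self.values.shape[0])]
        if len(self.row_ids) != self.values.shape[0]:
            raise PanelValidationError("row_ids length must match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AnalyteStats:
    """Per-analyte summary of a (normalized) panel: min, max, mean, population std."""

    min: np.ndarray
    max: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if not (np.all(self.min <= self.mean + 1e-12)
                and np.all(self.mean <= self.max + 1e-12)):
            raise PanelValidationError("analyte stats violate min <= mean <= max")
        if np.any(self.std < 0):
            raise PanelValidationError("std must be non-negative")


def records_to_matrix(records: list[BloodPanelRecord]) -> PanelMatrix:
    """Stack records into a raw PanelMatrix (canonical analyte order)."""
    if not records:
        raise PanelValidationError("no records to stack")
    values = np.array([r.analytes for r in records])
    return PanelMatrix(values=values, row_ids=[r.subject_id for r in records])


def read_panel_csv(path) -> list[BloodPanelRecord]:
    """Read a blood panel CSV into records.

    Columns are matched by header name, in any order.  Raises
    :class:`PanelSchemaError` for a missing column, :class:`ValueError`
    naming the row for a non-numeric analyte, and
    :class:`PanelValidationError` for gender codes outside {-1, +1}.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"panel CSV missing column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        vals = {}
        for name in ("age",) + ANALYTES:
            raw = getattr(row, name)
            try:
                vals[name] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {raw!r} for {name} in data row {i}"
                ) from None
        gender_raw = getattr(row, "gender")
        try:
            gender = int(gender_raw)
        except (TypeError, ValueError):
            raise PanelValidationError(
                f"gender must be -1 or +1, got {gender_raw!r} in data row {i}"
            ) from None
        records.append(
            BloodPanelRecord(
                subject_id=str(getattr(row, "subject_id")),
                age=int(vals["age"]),
                gender=gender,
                **{a: vals[a] for a in ANALYTES},
            )
        )
    return records


def write_panel_csv(records: list[BloodPanelRecord], path) -> None:
    """Write records to the canonical panel CSV dialect (UTF-8, '.' decimals)."""
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "age": r.age,
                "gender": r.gender,
                **{a: getattr(r, a) for a in ANALYTES},
            }
            for r in records
        ],
        columns=list(PANEL_COLUMNS),
    )
    df.to_csv(path, index=False)


def min_max_normalize(
    m: PanelMatrix, bounds: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[PanelMatrix, tuple[np.ndarray, np.ndarray]]:
    """Min-max map each analyte column to [0, 1].

    Returns the normalized matrix and the per-analyte (min, max) pair.  Pass
    ``bounds`` (a training (min, max) pair) to map held-out data onto the
    training scale; such values may fall outside [0, 1] and are not clipped.
    """
    if m.normalized:
        raise PanelValidationError("matrix is already normalized")
    if bounds is None:
        lo = m.values.min(axis=0)
        hi = m.values.max(axis=0)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    span = hi - lo
    if np.any(span <= 0):
        bad = [ANALYTES[i] for i in np.nonzero(span <= 0)[0]]
        raise DegenerateInputError(
            f"constant analyte column(s) {', '.join(bad)}: min-max range is zero"
        )
    norm = (m.values - lo) / span
    return PanelMatrix(values=norm, row_ids=list(m.row_ids), normalized=True), (lo, hi)


def analyte_stats(m: PanelMatrix) -> AnalyteStats:
    """Per-analyte min, max, mean and population std of a normalized panel."""
    if not m.normalized:
        raise PanelValidationError("analyte_stats expects a normalized matrix")
    if m.n < 1:
        raise DegenerateInputError("empty matrix")
    v = m.values
    return AnalyteStats(
        min=v.min(axis=0),
        max=v.max(axis=0),
        mean=v.mean(axis=0),
        std=v.std(axis=0, ddof=0),
        n=m.n,
    )


def pearson_correlation(x, y) -> float:
    """Product-moment correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant input")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_by_group(
    records: list[BloodPanelRecord],
    grouping: str = "gender",
    age_bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS,
) -> dict:
    """5x5 analyte correlation tables per gender or per age bin.

    Returns ``{group_label: DataFrame | None}``; a group with fewer than two
    records (or a constant analyte) gets ``None`` — its table is unavailable.
    """
    if grouping == "gender":
        groups = {
            "female": [r for r in records if r.gender == -1],
            "male": [r for r in records if r.gender == 1],
        }
    elif grouping == "age":
        groups = {
            f"{lo}-{hi}": [r for r in records if lo <= r.age <= hi]
            for lo, hi in age_bins
        }
    else:
        raise ValueError(f"unknown grouping {grouping!r}; use 'gender' or 'age'")

    out = {}
    for label, recs in groups.items():
        if len(recs) < 2:
            out[label] = None
            continue
        v = np.array([r.analytes for r in recs])
        if np.any(np.ptp(v, axis=0) == 0):
            out[label] = None
            continue
        table = pd.DataFrame(np.corrcoef(v, rowvar=False),
                             index=ANALYTES, columns=ANALYTES)
        out[label] = table
    return out
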