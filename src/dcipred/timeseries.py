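"""Cohort data model, file I/O, downsampling, censoring and exclusion filters.

A :class:`TimeSeries` is one physiologic channel for one patient: values on a
regular grid (``period`` seconds per sample), anchored at ``start`` hours after
aneurysm rupture (post-bleed time zero), together with a boolean observation
mask. Masked-out entries carry NaN and are never read by numeric operations.

Five bedside ICU variables are modelled: heart rate (HR), respiratory rate
(RR), systolic/diastolic blood pressure (SBP/DBP) and oxygen saturation
(SPO2). Baseline clinical covariates are age, sex, Hunt-Hess grade, modified
Fisher scale (mFS) and admission Glasgow Coma Scale (GCS); the binary outcome
is delayed cerebral ischemia (DCI).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

VARIABLES = ("HR", "RR", "SBP", "DBP", "SPO2")

#: standard downsampling periods, in minutes
DS_PERIODS_MIN = (1, 5, 10, 20, 60, 120, 240)


class CohortFormatError(ValueError):
    """Raised when an input file violates the documented CSV dialect."""


@dataclass
class TimeSeries:
    """One channel on a regular grid with a missingness mask.

    Parameters
    ----------
    values : ndarray
        Sample values; entries where ``mask`` is False are NaN sentinels.
    period : float
        Seconds per sample, > 0.
    start : float
        Hours since aneurysm rupture of the first grid point, >= 0.
    mask : ndarray of bool
        True where the sample was observed.
    """

    values: np.ndarray
    period: float
    start: float = 0.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 1 or self.mask.shape != self.values.shape:
            raise ValueError("values and mask must be equal-length 1-D arrays")
        if not self.period > 0:
            raise ValueError("period must be positive")
        if self.start < 0:
            raise ValueError("start must be non-negative (hours post-bleed)")
        # enforce the sentinel invariant
        self.values = np.where(self.mask, self.values, np.nan)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_hours(self) -> np.ndarray:
        """Grid timestamps in hours post-bleed."""
        return self.start + np.arange(len(self)) * (self.period / 3600.0)

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def observed_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class BaselineFeatures:
    """Admission covariates; any field may be None (missing)."""

    age: Optional[float] = None
    sex: Optional[int] = None          # female = 1
    hunt_hess: Optional[int] = None    # 1-5
    mfs: Optional[int] = None          # 0-4
    gcs: Optional[int] = None          # 3-15

    @property
    def hh_high(self) -> Optional[int]:
        """Hunt-Hess dichotomized: low grade 1-3, high grade 4-5."""
        return None if self.hunt_hess is None else int(self.hunt_hess >= 4)

    @property
    def mfs_high(self) -> Optional[int]:
        """Modified Fisher dichotomized: low grade 0-2, high grade 3-4."""
        return None if self.mfs is None else int(self.mfs >= 3)

    def all_missing(self) -> bool:
        return all(
            v is None for v in (self.age, self.sex, self.hunt_hess, self.mfs, self.gcs)
        )


@dataclass
class PatientRecord:
    id: str
    channels: dict = field(default_factory=dict)  # variable -> TimeSeries
    baseline: BaselineFeatures = field(default_factory=BaselineFeatures)
    dci: int = 0
    early_event_pbd: Optional[float] = None  # PBD of first VSP/DCI, if any

    def __post_init__(self) -> None:
        if self.dci not in (0, 1):
            raise ValueError("dci label must be 0 or 1")
        unknown = set(self.channels) - set(VARIABLES)
        if unknown:
            raise ValueError(
                f"unknown variable name(s) {sorted(unknown)}; accepted: {list(VARIABLES)}"
            )


@dataclass
class Cohort:
    records: list  # of PatientRecord
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> np.ndarray:
        return np.array([r.dci for r in self.records], dtype=int)

    def ids(self) -> list:
        return [r.id for r in self.records]

    def subset(self, indices: Iterable[int], provenance: str = "") -> "Cohort":
        return Cohort([self.records[i] for i in indices],
                      provenance=provenance or self.provenance)


# ---------------------------------------------------------------------------
# grid operations
# ---------------------------------------------------------------------------

def censor_window(series: TimeSeries, end_pbd: float = 4.0) -> TimeSeries:
    """Restrict a series to post-bleed time < ``end_pbd`` days.

    Physiologic data is limited to the first days after rupture to avoid the
    influence of treatment given in response to suspected vasospasm. Grid
    alignment is preserved; an empty result is allowed.
    """
    if not end_pbd > 0:
        raise ValueError("end_pbd must be positive")
    cutoff_h = end_pbd * 24.0
    keep = series.times_hours < cutoff_h
    n = int(keep.sum())  # grid times are increasing, so keep is a prefix
    return TimeSeries(series.values[:n], series.period, series.start,
                      series.mask[:n])


def downsample_mean(series: TimeSeries, period_minutes: float) -> TimeSeries:
    """Downsample by non-overlapping window means anchored at ``series.start``.

    Each output value is the mean of the *observed* samples in its window; a
    window with no observed sample is masked. Mean aggregation also absorbs
    isolated erroneous or missing samples.
    """
    out_period = period_minutes * 60.0
    ratio = out_period / series.period
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"target period {out_period}s is not an integer multiple of "
            f"series period {series.period}s"
        )
    step = int(round(ratio))
    n_out = int(np.ceil(len(series) / step))
    if n_out == 0:
        return TimeSeries(np.empty(0), out_period, series.start, np.empty(0, bool))
    padded = np.full(n_out * step, np.nan)
    padded[: len(series)] = series.values
    blocks = padded.reshape(n_out, step)
    counts = np.sum(~np.isnan(blocks), axis=1)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(blocks, axis=1)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return TimeSeries(means, out_period, series.start, counts > 0)


def contiguous_runs(series_or_mask) -> list:
    """Maximal runs of consecutive observed samples as half-open [lo, hi) pairs."""
    mask = series_or_mask.mask if isinstance(series_or_mask, TimeSeries) else np.asarray(
        series_or_mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(a), int(b)) for a, b in zip(starts, ends)]


# ---------------------------------------------------------------------------
# cohort-level exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(cohort: Cohort) -> tuple:
    """Apply the study's cohort exclusion rules.

    Drops records with a vasospasm/DCI event strictly before post-bleed day 3
    (events at exactly PBD 3 are retained) and records missing all candidate
    features (no physiologic channel with any observed sample AND no baseline
    covariate). Returns ``(filtered_cohort, report)`` where the report counts
    each reason and the remainder.
    """
    kept, n_early, n_allmiss = [], 0, 0
    for rec in cohort:
        if rec.early_event_pbd is not None and rec.early_event_pbd < 3.0:
            n_early += 1
            continue
        has_physio = any(ts.n_observed > 0 for ts in rec.channels.values())
        if not has_physio and rec.baseline.all_missing():
            n_allmiss += 1
            continue
        kept.append(rec)
    report = {
        "n_input": len(cohort),
        "excluded_early_event": n_early,
        "excluded_all_missing": n_allmiss,
        "n_remaining": len(kept),
    }
    return Cohort(kept, provenance=cohort.provenance), report


# ---------------------------------------------------------------------------
# optional artifact filter (off by default)
# ---------------------------------------------------------------------------

#: physiologically plausible ranges used by the optional clamp filter
DEFAULT_RANGES = {
    "HR": (20.0, 250.0),
    "RR": (2.0, 80.0),
    "SBP": (40.0, 280.0),
    "DBP": (15.0, 180.0),
    "SPO2": (40.0, 100.0),
}


def clamp_artifacts(series: TimeSeries, variable: str,
                    ranges: dict = None) -> TimeSeries:
    """Mask samples outside a plausible physiologic range (opt-in filter)."""
    lo, hi = (ranges or DEFAULT_RANGES)[variable]
    with np.errstate(invalid="ignore"):
        ok = series.mask & (series.values >= lo) & (series.values <= hi)
    return TimeSeries(np.where(ok, series.values, np.nan), series.period,
                      series.start, ok)


# ---------------------------------------------------------------------------
# file I/O
#
# long-CSV:  id, variable, pbd_hours, value     (one row per sample)
# wide-CSV:  id, pbd_hours, HR, RR, SBP, DBP, SPO2   (empty cell = missing)
# baseline:  id, age, sex, hunt_hess, mfs, gcs, dci, early_event_pbd
# ---------------------------------------------------------------------------

def _series_from_samples(hours: np.ndarray, vals: np.ndarray,
                         period_s: float, ctx: str) -> TimeSeries:
    """Place irregular (timestamp, value) samples on the regular grid."""
    idx = np.round(hours * 3600.0 / period_s).astype(int)
    if np.unique(idx).size != idx.size:
        raise CohortFormatError(f"duplicate (id, variable, timestamp) in {ctx}")
    start_idx = idx.min()
    n = idx.max() - start_idx + 1
    values = np.full(n, np.nan)
    values[idx - start_idx] = vals
    return TimeSeries(values, period_s, start=start_idx * period_s / 3600.0)


def load_cohort(path, fmt: str = "long-csv", baseline_path=None,
                period_s: Optional[float] = None) -> Cohort:
    """Load a cohort from the documented CSV dialects.

    Samples are placed on the regular grid (``period_s`` seconds) by
    timestamp; gaps become masked entries; duplicate timestamps within a
    channel are an error. If ``period_s`` is omitted, a ``<path>.json``
    sidecar written by :func:`write_cohort` is consulted, falling back to
    5 s (0.2 Hz).
    """
    path = Path(path)
    if period_s is None:
        sidecar = Path(str(path) + ".json")
        period_s = (json.loads(sidecar.read_text()).get("period_s", 5.0)
                    if sidecar.exists() else 5.0)
        period_s = 5.0 if period_s is None else float(period_s)
    df = pd.read_csv(path)
    channels_by_id: dict = {}
    if fmt == "long-csv":
        need = {"id", "variable", "pbd_hours", "value"}
        if not need.issubset(df.columns):
            raise CohortFormatError(
                f"long-csv requires columns {sorted(need)}; got {list(df.columns)}")
        bad = set(df["variable"].unique()) - set(VARIABLES)
        if bad:
            raise CohortFormatError(
                f"unknown variable name(s) {sorted(bad)}; accepted: {list(VARIABLES)}")
        if df["value"].isna().any():
            line = int(df.index[df["value"].isna()][0]) + 2  # header + 1-based
            raise CohortFormatError(f"malformed row: missing value at line {line}")
        for (pid, var), grp in df.groupby(["id", "variable"], sort=False):
            channels_by_id.setdefault(str(pid), {})[var] = _series_from_samples(
                grp["pbd_hours"].to_numpy(float), grp["value"].to_numpy(float),
                period_s, f"{path.name}: id={pid} variable={var}")
    elif fmt == "wide-csv":
        need = {"id", "pbd_hours"}
        if not need.issubset(df.columns):
            raise CohortFormatError(
                f"wide-csv requires columns {sorted(need)}; got {list(df.columns)}")
        vars_present = [v for v in VARIABLES if v in df.columns]
        extra = set(df.columns) - need - set(VARIABLES)
        if extra:
            raise CohortFormatError(
                f"unknown variable name(s) {sorted(extra)}; accepted: {list(VARIABLES)}")
        for pid, grp in df.groupby("id", sort=False):
            for var in vars_present:
                vals = grp[var].to_numpy(float)
                keep = ~np.isnan(vals)
                if keep.any():
                    channels_by_id.setdefault(str(pid), {})[var] = \
                        _series_from_samples(
                            grp["pbd_hours"].to_numpy(float)[keep], vals[keep],
                            period_s, f"{path.name}: id={pid} variable={var}")
    else:
        raise ValueError("format must be 'long-csv' or 'wide-csv'")

    baselines: dict = {}
    order: list = []
    if baseline_path is not None:
        bdf = pd.read_csv(baseline_path)
        for _, row in bdf.iterrows():
            pid = str(row["id"])
            order.append(pid)

            def _opt(col, cast=float):
                v = row.get(col)
                return None if v is None or (isinstance(v, float) and np.isnan(v)) \
                    else cast(v)

            baselines[pid] = dict(
                baseline=BaselineFeatures(
                    age=_opt("age"), sex=_opt("sex", int),
                    hunt_hess=_opt("hunt_hess", int), mfs=_opt("mfs", int),
                    gcs=_opt("gcs", int)),
                dci=int(row["dci"]) if not pd.isna(row.get("dci")) else 0,
                early_event_pbd=_opt("early_event_pbd"),
            )
    ids = order or sorted(channels_by_id, key=str)
    records = []
    for pid in ids:
        meta = baselines.get(pid, dict(baseline=BaselineFeatures(), dci=0,
                                       early_event_pbd=None))
        records.append(PatientRecord(id=pid, channels=channels_by_id.get(pid, {}),
                                     **meta))
    return Cohort(records, provenance=f"loaded from {path}")


def write_cohort(cohort: Cohort, ts_path, baseline_path) -> None:
    """Write a cohort in the long-CSV + baseline-CSV dialects (round-trips
    through :func:`load_cohort` up to float repr)."""
    rows = []
    period = None
    for rec in cohort:
        for var, ts in rec.channels.items():
            period = ts.period
            hours = ts.times_hours[ts.mask]
            for h, v in zip(hours, ts.values[ts.mask]):
                rows.append((rec.id, var, repr(float(h)), repr(float(v))))
    with open(ts_path, "w") as fh:
        fh.write("id,variable,pbd_hours,value\n")
        for r in rows:
            fh.write(",".join(map(str, r)) + "\n")
    with open(baseline_path, "w") as fh:
        fh.write("id,age,sex,hunt_hess,mfs,gcs,dci,early_event_pbd\n")
        for rec in cohort:
            b = rec.baseline
            cells = [rec.id] + ["" if v is None else repr(float(v)) for v in
                                (b.age, b.sex, b.hunt_hess, b.mfs, b.gcs)]
            cells.append(str(rec.dci))
            cells.append("" if rec.early_event_pbd is None
                         else repr(float(rec.early_event_pbd)))
            fh.write(",".join(cells) + "\n")
    # record the grid period alongside, for lossless reload
    meta = Path(str(ts_path) + ".json")
    meta.write_text(json.dumps({"period_s": period, "format": "long-csv"}))
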