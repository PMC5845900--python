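"""Kernel-derived and baseline candidate features.

A kernel feature is the maximal valid cross-correlation of a learned kernel
with a patient's series: ``f = max(X * gamma)``, the sliding template match
evaluated only where the kernel lies entirely inside contiguous observed
data, and only over contiguous runs at least twice the kernel length. If no
run qualifies the feature is missing.

The operator written ``*`` in the model is implemented as cross-correlation
(no kernel flip): the feature is a template match, and the learned kernels
are free to encode inverted motifs themselves. ``flip=True`` restores strict
(flipped) convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cdl import DictionaryBank, prepare_series
from .timeseries import Cohort, TimeSeries, contiguous_runs

BASELINE_COLUMNS = ("age", "sex", "hh_high", "mfs_high", "gcs")


@dataclass
class FeatureMatrix:
    """Patients x features with per-column provenance tags.

    ``tags`` is one dict per column: ``{kind: 'baseline'|'kernel', variable,
    ds_minutes, kernel_length, kernel_index}`` (baseline columns carry the
    covariate name in ``variable``). Missing entries are NaN.
    """

    values: np.ndarray
    tags: list
    patient_ids: list

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.patient_ids), len(self.tags)):
            raise ValueError("values shape must be (n_patients, n_tags)")
        keys = [tuple(sorted(t.items())) for t in self.tags]
        if len(set(keys)) != len(keys):
            raise ValueError("feature tags must be unique per column")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if self.patient_ids != other.patient_ids:
            raise ValueError("patient id order differs")
        return FeatureMatrix(np.hstack([self.values, other.values]),
                             self.tags + other.tags, list(self.patient_ids))

    def select(self, cols: Sequence[int]) -> "FeatureMatrix":
        cols = list(cols)
        return FeatureMatrix(self.values[:, cols],
                             [self.tags[c] for c in cols], list(self.patient_ids))

    def rows(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(self.values[idx], list(self.tags),
                             [self.patient_ids[i] for i in idx])

    def to_csv(self, values_path, tags_path) -> None:
        df = pd.DataFrame(self.values, index=self.patient_ids,
                          columns=[f"f{i}" for i in range(self.n_features)])
        df.to_csv(values_path, index_label="id")
        import json
        with open(tags_path, "w") as fh:
            json.dump(self.tags, fh)

    @classmethod
    def from_csv(cls, values_path, tags_path) -> "FeatureMatrix":
        import json
        df = pd.read_csv(values_path, index_col="id")
        with open(tags_path) as fh:
            tags = json.load(fh)
        return cls(df.to_numpy(float), tags, [str(i) for i in df.index])


def kernel_feature(series: Optional[TimeSeries], atom: np.ndarray,
                   flip: bool = False) -> float:
    """Signed maximum of the valid cross-correlation over qualifying runs.

    Runs shorter than twice the kernel length are skipped (the contiguity
    rule); returns NaN when no run qualifies or the series is absent.
    """
    if series is None:
        return np.nan
    atom = np.asarray(atom, dtype=float)
    if flip:
        atom = atom[::-1]
    r = atom.size
    best = -np.inf
    for a, b in contiguous_runs(series):
        if b - a < 2 * r:
            continue
        seg = series.values[a:b]
        c = np.correlate(seg, atom, mode="valid")
        m = c.max()
        if m > best:
            best = m
    return float(best) if np.isfinite(best) else np.nan


def build_feature_matrix(cohort: Cohort, bank: DictionaryBank,
                         censor_days: Optional[float] = 4.0,
                         flip: bool = False) -> FeatureMatrix:
    """One column per atom in the bank, one row per patient.

    Each entry is :func:`kernel_feature` on the patient's censored,
    downsampled, z-scored series for the atom's (variable, ds) cell —
    the same normalization the dictionaries were learned under. Entries are
    NaN wherever the contiguity rule yields no value.
    """
    atom_list = list(bank.iter_atoms())
    tags = [dict(kind="kernel", variable=var, ds_minutes=ds,
                 kernel_length=kl, kernel_index=k)
            for var, ds, kl, k, _ in atom_list]
    cells = sorted({(var, ds) for var, ds, _, _, _ in atom_list})
    values = np.full((len(cohort), len(atom_list)), np.nan)
    for i, rec in enumerate(cohort):
        prepared = {cell: prepare_series(rec.channels, cell[0], cell[1],
                                         bank.norm_stats, censor_days)
                    for cell in cells}
        for j, (var, ds, kl, k, atom) in enumerate(atom_list):
            values[i, j] = kernel_feature(prepared[(var, ds)], atom, flip=flip)
    return FeatureMatrix(values, tags, cohort.ids())


def assemble_baseline(cohort: Cohort, dichotomize: bool = True) -> FeatureMatrix:
    """Baseline covariate columns [age, sex, hh_high, mfs_high, gcs].

    Hunt-Hess is dichotomized at >= 4 (high grade 4-5) and the modified
    Fisher scale at >= 3 (high grade 3-4); GCS enters as a continuous
    integer; sex is encoded female = 1. ``dichotomize=False`` keeps the raw
    hunt_hess / mfs grades instead.
    """
    cols = BASELINE_COLUMNS if dichotomize else ("age", "sex", "hunt_hess",
                                                 "mfs", "gcs")
    values = np.full((len(cohort), len(cols)), np.nan)
    for i, rec in enumerate(cohort):
        b = rec.baseline
        for j, c in enumerate(cols):
            v = getattr(b, c)
            values[i, j] = np.nan if v is None else float(v)
    tags = [dict(kind="baseline", variable=c, ds_minutes=None,
                 kernel_length=None, kernel_index=None) for c in cols]
    return FeatureMatrix(values, tags, cohort.ids())


@dataclass
class FittedTransform:
    """Per-column median imputation + z-scoring, fitted on training rows only."""

    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    keep: np.ndarray          # boolean, False for dropped columns
    dropped_tags: list = field(default_factory=list)

    def apply(self, fm: FeatureMatrix) -> FeatureMatrix:
        v = fm.values.copy()
        ridx = np.where(np.isnan(v))
        v[ridx] = self.medians[ridx[1]]
        v = (v - self.means) / self.sds
        out = v[:, self.keep]
        tags = [t for t, k in zip(fm.tags, self.keep) if k]
        return FeatureMatrix(out, tags, list(fm.patient_ids))


def impute_and_standardize(train: FeatureMatrix,
                           others: Sequence[FeatureMatrix] = ()) -> tuple:
    """Fit median imputation and z-scoring on ``train``; apply everywhere.

    Columns that are entirely missing or have zero variance in the training
    rows are dropped (and reported on the returned transform). Returns
    ``(train_t, [others_t...], transform)``.
    """
    if train.values.shape[0] == 0:
        raise ValueError("training matrix is empty")
    v = train.values
    import warnings as _warnings
    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(v, axis=0)
    all_missing = np.isnan(medians)
    medians = np.where(all_missing, 0.0, medians)
    filled = np.where(np.isnan(v), medians[None, :], v)
    means = filled.mean(axis=0)
    sds = filled.std(axis=0)
    keep = (~all_missing) & (sds > 0)
    tf = FittedTransform(medians, means, np.where(sds > 0, sds, 1.0), keep,
                         dropped_tags=[t for t, k in zip(train.tags, keep) if not k])
    return tf.apply(train), [tf.apply(o) for o in others], tf
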