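"""Feature-table container, QC filtering and scaling.

A quantified lipidomic experiment is carried as a :class:`FeatureTable`:
a samples × lipids matrix of peak areas plus per-sample metadata (region of
origin, muscle part, and an optional ``role`` column distinguishing pooled
quality-control injections from biological samples).

QC filtering follows standard widely-targeted practice: a lipid is kept only
if it is detected in at least ``min_detection_rate`` of the QC injections and
its coefficient of variation over the detected QC values is at most
``max_cv``.  Remaining missing values are imputed as half the smallest
observed value of that lipid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "QCSpec",
    "Scaler",
    "qc_filter",
    "impute_missing",
    "autoscale",
    "pareto_scale",
    "read_feature_table",
    "write_feature_table",
]

_META_COLUMNS = ("region", "part", "role")


@dataclass
class FeatureTable:
    """Samples × lipids abundance matrix with sample metadata.

    Parameters
    ----------
    abundances
        DataFrame indexed by sample id, one column per lipid id, holding
        peak areas (non-negative or NaN for not-detected).
    samples
        DataFrame indexed by the same sample ids with at least ``region``
        and ``part`` columns; an optional ``role`` column marks QC
        injections (``role == "qc"``).
    """

    abundances: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.abundances.index.equals(self.samples.index):
            raise ValueError("abundance rows and sample metadata must share the same index")
        if self.abundances.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.abundances.columns.has_duplicates:
            raise ValueError("duplicate lipid ids")
        for col in ("region", "part"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def lipid_ids(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.abundances.shape[1]

    @property
    def region(self) -> pd.Series:
        return self.samples["region"]

    @property
    def part(self) -> pd.Series:
        return self.samples["part"]

    def values(self) -> np.ndarray:
        return self.abundances.to_numpy(dtype=float)

    def is_qc(self) -> pd.Series:
        if "role" in self.samples.columns:
            return self.samples["role"].eq("qc")
        return pd.Series(False, index=self.samples.index)

    def nx_labels(self) -> pd.Series:
        """Binary authentication labels: ``NX`` vs ``nonNX``."""
        return self.region.map(lambda r: "NX" if r == "NX" else "nonNX")

    # -- subsetting ----------------------------------------------------
    def subset(
        self,
        *,
        part: str | None = None,
        region: str | None = None,
        samples: list[str] | None = None,
        lipids: list[str] | None = None,
        biological_only: bool = False,
    ) -> "FeatureTable":
        mask = pd.Series(True, index=self.samples.index)
        if part is not None:
            mask &= self.part.eq(part)
        if region is not None:
            mask &= self.region.eq(region)
        if biological_only:
            mask &= ~self.is_qc()
        if samples is not None:
            mask &= self.samples.index.isin(samples)
        ab = self.abundances.loc[mask]
        if lipids is not None:
            ab = ab[lipids]
        return FeatureTable(ab.copy(), self.samples.loc[mask].copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.abundances.copy(), self.samples.copy())


@dataclass(frozen=True)
class QCSpec:
    """Detection-rate and CV thresholds for the QC filter."""

    min_detection_rate: float = 0.5
    max_cv: float = 0.3

    def __post_init__(self) -> None:
        for name in ("min_detection_rate", "max_cv"):
            v = getattr(self, name)
            if not 0 < v <= 1 and name == "min_detection_rate":
                raise ValueError(f"{name} must lie in (0, 1]")
            if v <= 0:
                raise ValueError(f"{name} must be positive")


def qc_filter(
    table: FeatureTable,
    qc_sample_ids: list[str] | None = None,
    spec: QCSpec = QCSpec(),
) -> FeatureTable:
    """Drop unreliable lipids by QC detection rate and coefficient of variation.

    A lipid is retained iff its detection rate over the QC injections is at
    least ``spec.min_detection_rate`` *and* the CV (sd/mean, population sd)
    of its detected QC values is at most ``spec.max_cv``.  Detection means a
    finite, strictly positive peak area.  Samples are never removed.
    """
    if qc_sample_ids is None:
        qc_sample_ids = list(table.samples.index[table.is_qc()])
    if not qc_sample_ids:
        raise ValueError("no QC samples given: pass qc_sample_ids or set role == 'qc'")
    missing = set(qc_sample_ids) - set(table.sample_ids)
    if missing:
        raise ValueError(f"QC ids not in table: {sorted(missing)}")
    if len(qc_sample_ids) < 2:
        raise ValueError("at least 2 QC samples are needed to compute a CV")

    qc = table.abundances.loc[qc_sample_ids]
    detected = qc.notna() & (qc > 0)
    rate = detected.mean(axis=0)

    vals = qc.where(detected)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    keep = (rate >= spec.min_detection_rate) & (cv <= spec.max_cv)
    keep = keep.fillna(False)
    kept = [lip for lip in table.lipid_ids if keep[lip]]
    if not kept:
        warnings.warn("QC filter removed every lipid; returning an empty table")
    return table.subset(lipids=kept)


def impute_missing(table: FeatureTable) -> FeatureTable:
    """Replace missing values by half the per-lipid minimum observed value."""
    ab = table.abundances.copy()
    fill = ab.min(axis=0, skipna=True) / 2.0
    ab = ab.fillna(fill)
    return FeatureTable(ab, table.samples.copy())


@dataclass
class Scaler:
    """Column centering/scaling parameters supporting an exact inverse."""

    mean: pd.Series
    scale: pd.Series
    kind: str = "auto"

    def transform(self, table: FeatureTable) -> FeatureTable:
        ab = (table.abundances - self.mean) / self.scale
        return FeatureTable(ab, table.samples.copy())

    def inverse(self, table: FeatureTable) -> FeatureTable:
        ab = table.abundances * self.scale + self.mean
        return FeatureTable(ab, table.samples.copy())


def _scale_table(table: FeatureTable, kind: str) -> tuple[FeatureTable, Scaler]:
    if table.n_samples < 2:
        raise ValueError("scaling needs at least 2 samples")
    mean = table.abundances.mean(axis=0)
    sd = table.abundances.std(axis=0, ddof=0)
    if kind == "auto":
        scale = sd.copy()
    elif kind == "pareto":
        scale = np.sqrt(sd)
    else:
        raise ValueError(f"unknown scaling kind {kind!r}")
    # constant columns: centre only, unit scale
    scale = scale.where(scale > 0, 1.0)
    scaler = Scaler(mean=mean, scale=scale, kind=kind)
    return scaler.transform(table), scaler


def autoscale(table: FeatureTable) -> tuple[FeatureTable, Scaler]:
    """Centre each lipid to mean 0 and unit (population) variance."""
    return _scale_table(table, "auto")


def pareto_scale(table: FeatureTable) -> tuple[FeatureTable, Scaler]:
    """Centre and divide by the square root of the standard deviation."""
    return _scale_table(table, "pareto")


def write_feature_table(table: FeatureTable, path) -> None:
    """Write as CSV: sample_id, region, part[, role], then one column per lipid."""
    meta_cols = [c for c in _META_COLUMNS if c in table.samples.columns]
    out = pd.concat([table.samples[meta_cols], table.abundances], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path)


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, index_col="sample_id")
    meta_cols = [c for c in _META_COLUMNS if c in df.columns]
    samples = df[meta_cols]
    ab = df.drop(columns=meta_cols).astype(float)
    return FeatureTable(ab, samples)
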