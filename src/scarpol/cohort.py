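"""Longitudinal wound cohort: records, CSV I/O, z-scoring, design matrices.

Each wound carries a (Scar_Area mm^2, Hom, DOPSlope 1/mm) triple per
month; months 1, 2, 3 and 6 are required for modeling and month 5 is
carried but never modeled.  Design matrices stack, per wound, the three
features for each month in an ascending month set K (so 3*|K| columns)
against the untransformed month-6 scar area as target.  Features are
z-scored with moments fitted across the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTriple",
    "WoundRecord",
    "Cohort",
    "DesignMatrix",
    "ZScoreParams",
    "read_cohort",
    "write_cohort",
    "build_design",
    "zscore_fit_transform",
]

FEATURES = ("scar_area", "hom", "dop_slope")
MODELING_MONTHS = (1, 2, 3, 6)
ALL_MONTHS = (1, 2, 3, 5, 6)

CSV_COLUMNS = [
    "wound_id",
    "animal_id",
    "treatment",
    "month",
    "scar_area_mm2",
    "hom",
    "dop_slope",
]


@dataclass(frozen=True)
class FeatureTriple:
    """One wound-month measurement triple."""

    scar_area: float  # mm^2
    hom: float  # unitless, in [0, 1]
    dop_slope: float  # 1/mm

    def __post_init__(self) -> None:
        vals = (self.scar_area, self.hom, self.dop_slope)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite feature value: {vals}")
        if not self.scar_area > 0:
            raise ValueError(f"scar_area must be > 0, got {self.scar_area}")
        if not (0.0 <= self.hom <= 1.0):
            raise ValueError(f"hom must lie in [0, 1], got {self.hom}")


@dataclass
class WoundRecord:
    """One wound's identity and per-month measurements."""

    wound_id: str
    animal_id: str
    treatment: str
    measurements: Dict[int, FeatureTriple]

    def __post_init__(self) -> None:
        missing = [m for m in MODELING_MONTHS if m not in self.measurements]
        if missing:
            raise ValueError(
                f"wound {self.wound_id}: missing modeling months {missing}"
            )
        for m in self.measurements:
            if m not in ALL_MONTHS:
                raise ValueError(f"wound {self.wound_id}: unexpected month {m}")


class Cohort:
    """An ordered collection of wounds with unique ids."""

    def __init__(self, records: Iterable[WoundRecord]):
        self.records: List[WoundRecord] = list(records)
        if not self.records:
            raise ValueError("cohort is empty")
        ids = [r.wound_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate wound_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[WoundRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> WoundRecord:
        return self.records[i]

    def wound_ids(self) -> List[str]:
        return [r.wound_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for month in sorted(r.measurements):
                t = r.measurements[month]
                rows.append(
                    {
                        "wound_id": r.wound_id,
                        "animal_id": r.animal_id,
                        "treatment": r.treatment,
                        "month": month,
                        "scar_area_mm2": t.scar_area,
                        "hom": t.hom,
                        "dop_slope": t.dop_slope,
                    }
                )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"cohort table missing columns: {missing_cols}")
        if len(df) == 0:
            raise ValueError("cohort table has no rows")
        dup = df.duplicated(subset=["wound_id", "month"])
        if dup.any():
            pairs = df.loc[dup, ["wound_id", "month"]].values.tolist()
            raise ValueError(f"duplicate (wound, month) rows: {pairs}")
        records = []
        for wid in df["wound_id"].drop_duplicates():
            sub = df[df["wound_id"] == wid]
            meas = {
                int(row.month): FeatureTriple(
                    scar_area=float(row.scar_area_mm2),
                    hom=float(row.hom),
                    dop_slope=float(row.dop_slope),
                )
                for row in sub.itertuples()
            }
            records.append(
                WoundRecord(
                    wound_id=str(wid),
                    animal_id=str(sub["animal_id"].iloc[0]),
                    treatment=str(sub["treatment"].iloc[0]),
                    measurements=meas,
                )
            )
        return cls(records)


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV (one row per wound-month)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty cohort file: {path}") from exc
    return Cohort.from_frame(df)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort CSV with 6-significant-digit decimals.

    The format is stable under a read/write round trip (a re-written file
    is byte-identical).
    """
    df = cohort.to_frame()
    df.to_csv(path, index=False, float_format="%.6g")


@dataclass
class DesignMatrix:
    """Feature matrix for one model variant.

    Columns are ordered blocks (scar_area, hom, dop_slope) per month of K
    in ascending order; the target y is the month-6 scar area in mm^2,
    never transformed.
    """

    X: np.ndarray
    y: np.ndarray
    columns: List[str]
    wound_ids: List[str]
    K: Tuple[int, ...]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.wound_ids), len(self.columns)):
            raise ValueError("X shape inconsistent with row/column labels")
        if self.X.shape[1] != 3 * len(self.K):
            raise ValueError("column count must be 3*|K|")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("design matrix contains non-finite entries")


@dataclass
class ZScoreParams:
    """Per-column mean and standard deviation used for z-scoring."""

    mu: np.ndarray
    sigma: np.ndarray
    columns: List[str]
    ddof: int = 1

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mu) / self.sigma

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sigma + self.mu


def build_design(cohort: Cohort, K: Sequence[int]) -> DesignMatrix:
    """Assemble the 3*|K|-column design against the month-6 scar area.

    Rows follow the cohort's record order.
    """
    K = tuple(sorted(set(int(k) for k in K)))
    if not K:
        raise ValueError("month set K must be nonempty")
    if not set(K) <= {1, 2, 3}:
        raise ValueError(f"K must be a subset of {{1, 2, 3}}, got {K}")
    missing = [
        r.wound_id
        for r in cohort
        if any(m not in r.measurements for m in K) or 6 not in r.measurements
    ]
    if missing:
        raise ValueError(f"wounds missing required months: {missing}")
    columns = [f"{feat}_m{m}" for m in K for feat in FEATURES]
    X = np.array(
        [
            [getattr(r.measurements[m], feat) for m in K for feat in FEATURES]
            for r in cohort
        ]
    )
    y = np.array([r.measurements[6].scar_area for r in cohort])
    return DesignMatrix(
        X=X, y=y, columns=columns, wound_ids=cohort.wound_ids(), K=K
    )


def zscore_fit_transform(
    design: DesignMatrix, ddof: int = 1
) -> Tuple[DesignMatrix, ZScoreParams]:
    """Standardize each feature column to mean 0, sd 1 over all rows.

    The target is left untransformed.  The moments are fitted on the full
    cohort (before any cross-validation split); ``ddof=1`` selects the
    sample standard deviation, ``ddof=0`` the population one.
    """
    mu = design.X.mean(axis=0)
    sigma = design.X.std(axis=0, ddof=ddof)
    zero = np.nonzero(sigma == 0)[0]
    if zero.size:
        names = [design.columns[i] for i in zero]
        raise ValueError(f"zero-variance column(s): {names}")
    params = ZScoreParams(mu=mu, sigma=sigma, columns=list(design.columns), ddof=ddof)
    standardized = replace(design, X=params.transform(design.X), standardized=True)
    return standardized, params
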