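"""Cohort tables: per-subject covariates plus a fixed-order ROI SUVR vector.

A cohort table is the unit of everything downstream: group networks are
built from it, and the permutation test resamples its rows.  The on-disk
form is a flat CSV with columns ``subject_id,group,age,sex,roi_001..roi_NNN``;
the ROI column order of the file is authoritative for the whole analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortTable", "ROI_PREFIX"]

ROI_PREFIX = "roi_"

_META_COLUMNS = ["subject_id", "group", "age", "sex"]
_SEX_CODES = {"F": 0.0, "M": 1.0}


@dataclass
class CohortTable:
    """Per-subject covariates and SUVR vectors for one or more groups.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``subject_id, group, age, sex`` followed by one column per
        ROI.  ROI columns may carry arbitrary names (atlas region names or
        the default ``roi_###``); their order is the ROI order.
    """

    df: pd.DataFrame
    roi_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        self.roi_names = [c for c in self.df.columns if c not in _META_COLUMNS]
        if not self.roi_names:
            raise ValueError("cohort table has no ROI columns")
        self._validate()

    def _validate(self) -> None:
        if self.df[_META_COLUMNS].isna().any().any():
            raise ValueError("cohort table has missing covariate values")
        suvr = self.df[self.roi_names].to_numpy(dtype=float)
        if not np.all(np.isfinite(suvr)):
            raise ValueError("cohort table has non-finite SUVR values")
        if np.any(suvr <= 0):
            raise ValueError("cohort table has non-positive SUVR values")
        bad_sex = set(self.df["sex"].astype(str)) - set(_SEX_CODES)
        if bad_sex:
            raise ValueError(f"sex must be coded M/F, found {sorted(bad_sex)}")

    # ------------------------------------------------------------------ #

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group"].astype(str).unique())

    def suvr_matrix(self) -> np.ndarray:
        """Subjects x ROIs SUVR array, in table row / ROI-column order."""
        return self.df[self.roi_names].to_numpy(dtype=float)

    def covariate_matrix(self, covariate_names: list[str]) -> np.ndarray:
        """Numeric design columns for the named covariates (no intercept).

        ``sex`` is encoded as a single 0/1 indicator (F=0, M=1); ``age`` is
        used as-is in years.  Any other name must be a numeric column.
        """
        cols = []
        for name in covariate_names:
            if name == "sex":
                cols.append(self.df["sex"].astype(str).map(_SEX_CODES).to_numpy())
            elif name in self.df.columns and name not in self.roi_names:
                cols.append(self.df[name].to_numpy(dtype=float))
            else:
                raise ValueError(f"unknown covariate {name!r}")
        if not cols:
            return np.empty((self.n_subjects, 0))
        return np.column_stack(cols)

    def select_group(self, group: str) -> "CohortTable":
        sub = self.df[self.df["group"].astype(str) == str(group)]
        if sub.empty:
            raise ValueError(f"no subjects in group {group!r}")
        return CohortTable(sub.reset_index(drop=True))

    def select_rows(self, indices: np.ndarray) -> "CohortTable":
        """Subjects by positional index; covariates travel with the rows."""
        return CohortTable(self.df.iloc[np.asarray(indices)].reset_index(drop=True))

    def concat(self, other: "CohortTable") -> "CohortTable":
        if other.roi_names != self.roi_names:
            raise ValueError("ROI columns differ between cohort tables")
        return CohortTable(pd.concat([self.df, other.df], ignore_index=True))

    # ------------------------------ I/O ------------------------------- #

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    @staticmethod
    def default_roi_names(n_rois: int) -> list[str]:
        width = max(3, len(str(n_rois)))
        return [f"{ROI_PREFIX}{i + 1:0{width}d}" for i in range(n_rois)]
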