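"""Longitudinal study container in a NONMEM-like record layout.

One row per dose or observation event:

======  =====================================================================
ID      subject identifier (integer)
OCC     occasion (1-based; crossover periods or the single occasion 1)
TIME    h since the occasion's 08:00 dose start (>= 0)
AMT     dose amount, mg (0 on observation rows)
DUR     infusion duration, h (0 on observation rows)
DV      observed value: concentration ng/mL (DVTYPE 1) or pH (DVTYPE 2)
DVTYPE  1 = plasma concentration, 2 = intragastric pH
MDV     1 = DV missing/not an observation (all dose rows), 0 = observation
WT      body weight, kg
SEX     0 = female, 1 = male (the sex-on-CLp multiplier applies to SEX=1)
======  =====================================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

COLUMNS = ["ID", "OCC", "TIME", "AMT", "DUR", "DV", "DVTYPE", "MDV", "WT", "SEX"]
DV_CONC = 1
DV_PH = 2

__all__ = ["COLUMNS", "DV_CONC", "DV_PH", "StudyDataset", "DatasetError"]


class DatasetError(ValueError):
    """Raised when records violate the dataset dialect."""


def _fail(msg, rows=None):
    if rows is not None and len(rows):
        shown = ", ".join(str(r) for r in rows[:5])
        more = "" if len(rows) <= 5 else f" (+{len(rows) - 5} more)"
        msg = f"{msg} at row(s) {shown}{more}"
    raise DatasetError(msg)


@dataclass
class StudyDataset:
    """Validated record table plus an optional design/provenance manifest.

    The manifest is free-form JSON-able metadata written by the generators
    (arms, seeds, parameter values, per-subject simulation truth); it is not
    required for fitting unless a step needs the simulated individual PK.
    """

    records: pd.DataFrame
    manifest: dict | None = None

    def __post_init__(self):
        self.records = self.validate(self.records)

    @staticmethod
    def validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            _fail(f"missing required column(s) {missing}")
        extra = [c for c in df.columns if c not in COLUMNS]
        if extra:
            import warnings

            warnings.warn(f"ignoring unknown column(s) {extra}", stacklevel=3)
        df = df[COLUMNS].copy().reset_index(drop=True)
        for c, dtype in [("ID", int), ("OCC", int), ("DVTYPE", int), ("MDV", int), ("SEX", int)]:
            try:
                df[c] = df[c].astype(dtype)
            except (TypeError, ValueError) as err:
                _fail(f"column {c} is not integer-valued: {err}")
        for c in ("TIME", "AMT", "DUR", "DV", "WT"):
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)

        rows = df.index + 2  # 1-based, after header, for error messages
        bad = rows[df["TIME"] < 0]
        if len(bad):
            _fail("TIME must be >= 0", list(bad))
        bad = rows[(df["AMT"] > 0) & (df["MDV"] != 1)]
        if len(bad):
            _fail("dose rows (AMT > 0) must set MDV=1", list(bad))
        bad = rows[(df["AMT"] > 0) & (df["DUR"] <= 0)]
        if len(bad):
            _fail("dose rows must have a positive infusion DUR", list(bad))
        bad = rows[~df["DVTYPE"].isin([DV_CONC, DV_PH])]
        if len(bad):
            _fail("DVTYPE must be 1 (concentration) or 2 (pH)", list(bad))
        bad = rows[~df["SEX"].isin([0, 1])]
        if len(bad):
            _fail("SEX must be 0 or 1", list(bad))
        bad = rows[df["WT"] <= 0]
        if len(bad):
            _fail("WT must be positive", list(bad))
        keys = df[["ID", "OCC", "TIME", "DVTYPE", "AMT"]]
        dup = keys.duplicated()
        if dup.any():
            _fail("duplicate (ID, OCC, TIME, DVTYPE, AMT) keys", list(rows[dup]))
        per_subj = df.groupby("ID")[["WT", "SEX"]].nunique()
        if (per_subj > 1).any().any():
            _fail("WT and SEX must be constant within a subject")
        return df.sort_values(["ID", "OCC", "TIME", "DVTYPE"], kind="stable").reset_index(drop=True)

    # -- convenience views ---------------------------------------------------

    @property
    def subject_ids(self) -> list[int]:
        return sorted(self.records["ID"].unique().tolist())

    @property
    def n_subjects(self) -> int:
        return self.records["ID"].nunique()

    def covariates(self) -> pd.DataFrame:
        """One row per subject: WT, SEX."""
        return (
            self.records.groupby("ID")[["WT", "SEX"]].first().sort_index()
        )

    def observations(self, dvtype: int) -> pd.DataFrame:
        r = self.records
        return r[(r["MDV"] == 0) & (r["DVTYPE"] == dvtype)]

    def doses(self) -> pd.DataFrame:
        return self.records[self.records["AMT"] > 0]

    def profiles(self) -> Iterator[tuple[tuple[int, int], pd.DataFrame]]:
        """Iterate (ID, OCC) groups in sorted order."""
        yield from self.records.groupby(["ID", "OCC"], sort=True)

    def n_observations(self, dvtype: int | None = None) -> int:
        r = self.records[self.records["MDV"] == 0]
        if dvtype is not None:
            r = r[r["DVTYPE"] == dvtype]
        return len(r)

    def design_signature(self) -> str:
        """Hash of the design (doses, schedules, covariates), used to refuse
        model comparisons across different datasets."""
        import hashlib

        key = self.records[["ID", "OCC", "TIME", "AMT", "DUR", "DVTYPE", "MDV"]]
        raw = key.to_csv(index=False).encode()
        return hashlib.sha256(raw).hexdigest()[:16]

    def equals(self, other: "StudyDataset") -> bool:
        return self.records.equals(other.records)
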