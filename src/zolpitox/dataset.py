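"""Long-format PK datasets and the synthetic single-dose study generator.

The on-disk dialect is the NONMEM-style CSV with header
``ID,TIME,DV,AMT,EVID,MDV`` (case-insensitive): one dose record per
administration (EVID=1, AMT in mg, DV missing and written as ``.``) and one
observation record per sample (EVID=0, DV in ng/mL).  MDV=1 marks records
excluded from any likelihood (all dose records, plus the pre-dose zero
sample, which a proportional error model cannot describe).

``generate_study`` emulates a single-dose rich-sampling PK study in
healthy volunteers: 10 mg orally at time zero, samples at 0, 0.25, 0.5,
0.75, 1, 1.5, 2, 3, 4, 6, 8 and 12 h, 23 subjects (12 male / 11 female by
default), concentrations drawn from the population model with both
interindividual variability and proportional residual error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .population import PopulationParams, apply_residual_error, sample_individuals
from .simulate import CLINICAL_TIMES, conc_matrix
from .structural import DoseRegimen

__all__ = ["PKDataset", "StudyDesign", "generate_study", "read_dataset", "write_dataset"]

_COLUMNS = ["id", "time", "dv", "amt", "evid", "mdv"]


@dataclass(frozen=True)
class PKDataset:
    """Validated long-format dosing/observation records.

    Wraps a DataFrame with columns id, time, dv, amt, evid, mdv; dv is NaN
    exactly on dose records.  Optional per-subject covariates (e.g. sex)
    live in ``covariates`` indexed by subject id.
    """

    records: pd.DataFrame = field(repr=False)
    covariates: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if not set(df["evid"].unique()) <= {0, 1}:
            raise ValueError("evid must be 0 (observation) or 1 (dose)")
        if not set(df["mdv"].unique()) <= {0, 1}:
            raise ValueError("mdv must be 0 or 1")
        obs = df["evid"] == 0
        if df.loc[~obs, "dv"].notna().any():
            raise ValueError("dose records must not carry dv")
        if df.loc[obs, "dv"].isna().any():
            raise ValueError("observation records must carry dv")
        if (df.loc[~obs, "amt"] <= 0).any():
            raise ValueError("dose records must have amt > 0")
        for sid, grp in df.groupby("id"):
            doses = grp[grp["evid"] == 1]
            if doses.empty:
                raise ValueError(f"subject {sid} has no dose record")
            if (grp.loc[grp["evid"] == 0, "time"] < doses["time"].min()).any():
                raise ValueError(f"subject {sid} has observations before first dose")

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.records["id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def observations(self, likelihood_only: bool = True) -> pd.DataFrame:
        obs = self.records[self.records["evid"] == 0]
        if likelihood_only:
            obs = obs[obs["mdv"] == 0]
        return obs

    def subject(self, sid) -> pd.DataFrame:
        return self.records[self.records["id"] == sid]

    def resample_subjects(self, ids: Sequence, relabel: bool = True) -> "PKDataset":
        """Bootstrap helper: concatenate the given subjects (with repeats)."""
        parts = []
        for new_id, sid in enumerate(ids, start=1):
            block = self.subject(sid).copy()
            if relabel:
                block["id"] = new_id
            parts.append(block)
        cov = None
        if self.covariates is not None:
            cov = self.covariates.loc[list(ids)].reset_index(drop=True)
            cov.index = pd.Index(range(1, len(ids) + 1), name=self.covariates.index.name)
        return PKDataset(pd.concat(parts, ignore_index=True), covariates=cov)


@dataclass(frozen=True)
class StudyDesign:
    """A single-dose rich-sampling study layout.

    ``n_male="auto"`` (default) splits the cohort males-first, giving the
    12 male / 11 female division at the default 23 subjects; ``None``
    omits sex labels entirely.
    """

    n_subjects: int = 23
    dose: float = 10.0
    sampling_times: tuple[float, ...] = CLINICAL_TIMES
    n_male: int | None | str = "auto"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        t = np.asarray(self.sampling_times, dtype=float)
        if t[0] != 0 or not np.all(np.diff(t) > 0):
            raise ValueError("sampling times must start at 0 and strictly increase")
        if self.n_male == "auto":
            object.__setattr__(self, "n_male", (self.n_subjects + 1) // 2)
        if self.n_male is not None and not 0 <= self.n_male <= self.n_subjects:
            raise ValueError("n_male must lie in [0, n_subjects]")


def generate_study(pop: PopulationParams, design: StudyDesign, seed: int) -> PKDataset:
    """Simulate a complete study dataset under the population model.

    Each subject gets one dose record at t=0 and observations at the design
    times with IIV plus proportional residual error.  The pre-dose (t=0)
    sample is recorded as DV=0 with MDV=1.  Negative draws from the
    Gaussian error tail are truncated at zero (concentrations are
    physical); the event is rare at realistic error magnitudes.  Any
    resulting zero concentration (pre-lag samples, truncated draws) is
    flagged MDV=1, mirroring the exclusion of below-quantification records
    — a zero observation is incompatible with a proportional error model.
    """
    rng = np.random.default_rng(seed)
    individuals = sample_individuals(pop, design.n_subjects, rng)
    times = np.asarray(design.sampling_times, dtype=float)
    ipred = conc_matrix(individuals, DoseRegimen.single(design.dose), times)
    dv = np.clip(apply_residual_error(ipred, pop.sigma_prop, rng), 0.0, None)

    rows = []
    for i in range(design.n_subjects):
        sid = i + 1
        rows.append(dict(id=sid, time=0.0, dv=np.nan, amt=design.dose, evid=1, mdv=1))
        for j, t in enumerate(times):
            rows.append(
                dict(id=sid, time=float(t), dv=float(dv[i, j]), amt=np.nan,
                     evid=0, mdv=1 if (t == 0.0 or dv[i, j] <= 0.0) else 0)
            )
    records = pd.DataFrame(rows)
    cov = None
    if design.n_male is not None:
        sex = ["M"] * design.n_male + ["F"] * (design.n_subjects - design.n_male)
        cov = pd.DataFrame({"sex": sex}, index=pd.Index(range(1, design.n_subjects + 1), name="id"))
    return PKDataset(records, covariates=cov)


def read_dataset(path: str | Path) -> PKDataset:
    """Parse a NONMEM-style CSV (``.`` or empty = missing DV/AMT)."""
    df = pd.read_csv(path, na_values=["."], skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} "
                         f"(header must be ID,TIME,DV,AMT,EVID,MDV)")
    for col in ("evid", "mdv"):
        vals = df[col]
        if vals.isna().any() or not np.array_equal(vals, vals.astype(int)):
            bad = df.index[vals.isna() | (vals != vals.astype("Int64"))].tolist()[:5]
            raise ValueError(f"{path}: non-integer {col.upper()} values at rows {bad}")
        df[col] = vals.astype(int)
    extra = [c for c in df.columns if c not in _COLUMNS]
    cov = None
    if extra:
        per_subject = df.groupby("id")[extra].nunique().le(1).all().all()
        if per_subject:
            cov = df.groupby("id")[extra].first()
    return PKDataset(df[_COLUMNS].copy(), covariates=cov)


def write_dataset(data: PKDataset, path: str | Path) -> None:
    """Write the NONMEM-style CSV (missing values as ``.``)."""
    df = data.records.copy()
    if data.covariates is not None:
        for col in data.covariates.columns:
            df[col] = df["id"].map(data.covariates[col])
    df.columns = [c.upper() for c in df.columns]
    df.to_csv(path, index=False, na_rep=".")
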