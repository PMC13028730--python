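"""Long-format concentration–time dataset model and NONMEM-style CSV I/O.

A dataset is a sequence of records, each either a dose event or an
observation, grouped by subject.  Canonical units: time h, concentration
µg/mL, dose mg/kg.  Doses are recorded per kilogram so that body weight
cancels against the per-kg volumes of the kinetic model; weight is kept as
a candidate covariate only.

The canonical CSV header is ``ID,TIME,AMT,DV,EVID,FORM,WT,AGE`` with
comma separation and period decimals.  A column-mapping dialect supports
other NONMEM-style spellings (e.g. MDV files, 0/1-coded formulation).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FREE", "NC", "PKRecord", "PKDataset", "StudyDesign",
    "SchemaError", "ValidationError",
    "read_dataset", "write_dataset", "summarize", "load_dialect",
]

FREE = "FREE"
NC = "NC"

CANONICAL_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "FORM", "WT", "AGE"]

#: mapping canonical -> accepted alternative spellings (case-insensitive)
_DEFAULT_ALIASES = {
    "ID": ["id", "subject", "subject_id"],
    "TIME": ["time"],
    "AMT": ["amt", "amount", "dose"],
    "DV": ["dv", "conc", "concentration"],
    "EVID": ["evid", "is_dose"],
    "FORM": ["form", "formulation", "group", "arm"],
    "WT": ["wt", "weight"],
    "AGE": ["age"],
}


class SchemaError(ValueError):
    """The file does not have the required columns."""


class ValidationError(ValueError):
    """The data violate a dataset invariant; message names the offending
    row or subject."""


@dataclass(frozen=True)
class PKRecord:
    """One row: a dose event (``is_dose``) or an observation, never both."""

    subject_id: int
    time: float
    amount: float | None = None        # mg/kg, dose rows only
    concentration: float | None = None  # µg/mL, observation rows only
    is_dose: bool = False
    formulation: str = FREE
    weight: float = float("nan")       # kg
    age: float = float("nan")          # months

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError(f"subject {self.subject_id}: negative time {self.time}")
        if self.is_dose:
            if self.amount is None or not self.amount > 0:
                raise ValidationError(
                    f"subject {self.subject_id}: dose row requires amount > 0")
            if self.concentration is not None:
                raise ValidationError(
                    f"subject {self.subject_id}: record cannot be both dose and observation")
        else:
            if self.concentration is None or self.concentration < 0:
                raise ValidationError(
                    f"subject {self.subject_id}: observation requires concentration >= 0")
            if self.amount is not None:
                raise ValidationError(
                    f"subject {self.subject_id}: record cannot be both dose and observation")
        if self.formulation not in (FREE, NC):
            raise ValidationError(
                f"subject {self.subject_id}: unknown formulation {self.formulation!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Design metadata of a single-oral-dose parallel-arm study."""

    n_per_arm: int = 9
    dose_per_kg: float = 0.2
    sampling_times: tuple = (0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48, 60)
    weight_range: tuple = (10.5, 16.6)
    age_range: tuple = (9.0, 48.0)

    def __post_init__(self):
        t = np.asarray(self.sampling_times, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("sampling_times must be strictly increasing and > 0")


class PKDataset:
    """Validated long-format dataset.

    Internally a pandas DataFrame in canonical column order, sorted by
    (subject, time) with the dose row first within ties.  Each subject has
    exactly one dose event at time 0 and strictly increasing observation
    times with strictly positive concentrations.
    """

    def __init__(self, df: pd.DataFrame):
        self._df = self._normalise(df)
        self._validate()

    # -- construction ------------------------------------------------------

    @staticmethod
    def _normalise(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = df[CANONICAL_COLUMNS].copy()
        df["ID"] = df["ID"].astype(int)
        df["EVID"] = df["EVID"].astype(int)
        for c in ("TIME", "AMT", "DV", "WT", "AGE"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
        form = df["FORM"]
        if not form.dtype == object:
            form = form.map({0: FREE, 1: NC})
        else:
            form = form.astype(str).str.upper().replace({"0": FREE, "1": NC})
        df["FORM"] = form
        df = df.sort_values(["ID", "TIME", "EVID"],
                            ascending=[True, True, False], kind="stable")
        return df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[PKRecord]) -> "PKDataset":
        rows = [{
            "ID": r.subject_id, "TIME": r.time,
            "AMT": r.amount if r.is_dose else np.nan,
            "DV": r.concentration if not r.is_dose else np.nan,
            "EVID": int(r.is_dose), "FORM": r.formulation,
            "WT": r.weight, "AGE": r.age,
        } for r in records]
        return cls(pd.DataFrame(rows, columns=CANONICAL_COLUMNS))

    def _validate(self) -> None:
        df = self._df
        bad_form = ~df["FORM"].isin([FREE, NC])
        if bad_form.any():
            i = int(np.flatnonzero(bad_form)[0])
            raise ValidationError(f"row {i}: unparseable formulation {df['FORM'].iloc[i]!r}")
        if (df["TIME"] < 0).any():
            i = int(np.flatnonzero(df["TIME"] < 0)[0])
            raise ValidationError(f"row {i}: negative time")
        obs = df["EVID"] == 0
        if (df.loc[obs, "DV"] <= 0).any() or df.loc[obs, "DV"].isna().any():
            i = int(df.index[obs][(df.loc[obs, "DV"] <= 0) | df.loc[obs, "DV"].isna()][0])
            raise ValidationError(
                f"row {i}: observation concentration must be strictly positive")
        if (df.loc[~obs, "AMT"] <= 0).any() or df.loc[~obs, "AMT"].isna().any():
            i = int(df.index[~obs][(df.loc[~obs, "AMT"] <= 0) | df.loc[~obs, "AMT"].isna()][0])
            raise ValidationError(f"row {i}: dose row requires amount > 0")
        for sid, g in df.groupby("ID"):
            doses = g[g["EVID"] == 1]
            if len(doses) != 1:
                raise ValidationError(
                    f"subject {sid}: expected exactly one dose event, found {len(doses)}")
            if doses["TIME"].iloc[0] != 0:
                raise ValidationError(f"subject {sid}: dose event must be at time 0")
            t = g.loc[g["EVID"] == 0, "TIME"].to_numpy()
            if np.any(np.diff(t) <= 0):
                j = int(np.flatnonzero(np.diff(t) <= 0)[0])
                raise ValidationError(
                    f"subject {sid}: duplicate or non-increasing observation time "
                    f"{t[j + 1]}")
            if len(set(g["FORM"])) != 1:
                raise ValidationError(f"subject {sid}: inconsistent formulation")

    # -- access ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def subject_ids(self) -> list[int]:
        return list(dict.fromkeys(self._df["ID"]))

    @property
    def n_subjects(self) -> int:
        return self._df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self._df["EVID"] == 0).sum())

    def subject(self, subject_id: int) -> dict:
        """Per-subject view: dose, observation times/concentrations, covariates."""
        g = self._df[self._df["ID"] == subject_id]
        if g.empty:
            raise KeyError(f"no subject {subject_id}")
        obs = g[g["EVID"] == 0]
        dose = g[g["EVID"] == 1]
        return {
            "subject_id": int(subject_id),
            "dose_per_kg": float(dose["AMT"].iloc[0]),
            "times": obs["TIME"].to_numpy(dtype=float),
            "conc": obs["DV"].to_numpy(dtype=float),
            "formulation": str(g["FORM"].iloc[0]),
            "weight": float(g["WT"].iloc[0]),
            "age": float(g["AGE"].iloc[0]),
        }

    def subjects(self):
        """Iterate per-subject views in id order."""
        for sid in self.subject_ids:
            yield self.subject(sid)

    def subset(self, subject_ids, relabel: bool = False) -> "PKDataset":
        """New dataset with the given subjects (with repetition allowed).

        ``relabel`` assigns fresh consecutive ids, which is required when a
        bootstrap resample draws the same subject more than once.
        """
        parts = []
        for new_id, sid in enumerate(subject_ids, start=1):
            g = self._df[self._df["ID"] == sid].copy()
            if g.empty:
                raise KeyError(f"no subject {sid}")
            if relabel:
                g["ID"] = new_id
            parts.append(g)
        return PKDataset(pd.concat(parts, ignore_index=True))

    def __eq__(self, other) -> bool:
        if not isinstance(other, PKDataset):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return (f"PKDataset(n_subjects={self.n_subjects}, "
                f"n_observations={self.n_observations})")


def load_dialect(path) -> dict:
    """Load a YAML/JSON column-mapping config: canonical name -> file name."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise SchemaError("dialect config must be a mapping")
    return {str(k).upper(): str(v) for k, v in mapping.items()}


def _resolve_columns(columns, dialect=None) -> dict:
    """Map file columns to canonical names using dialect then aliases."""
    resolved = {}
    lower = {c.lower(): c for c in columns}
    dialect = dialect or {}
    for canon in CANONICAL_COLUMNS:
        if canon in dialect and dialect[canon] in columns:
            resolved[canon] = dialect[canon]
            continue
        for alias in [canon.lower()] + _DEFAULT_ALIASES[canon]:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    required = ["ID", "TIME", "AMT", "DV", "EVID", "FORM"]
    missing = [c for c in required if c not in resolved]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    return resolved


def read_dataset(path, dialect: dict | None = None) -> PKDataset:
    """Read and validate a NONMEM-style CSV.

    ``dialect`` maps canonical names to the file's column names; common
    aliases are recognised automatically.  Rows flagged in an ``EXCLUDE``
    column (if the dialect declares one) are dropped.  Comment lines
    starting with ``#`` are ignored.
    """
    df = pd.read_csv(path, comment="#")
    dialect = {k.upper(): v for k, v in (dialect or {}).items()}
    exclude_col = dialect.pop("EXCLUDE", None)
    resolved = _resolve_columns(df.columns, dialect)
    out = pd.DataFrame()
    for canon in CANONICAL_COLUMNS:
        out[canon] = df[resolved[canon]] if canon in resolved else np.nan
    if exclude_col and exclude_col in df.columns:
        keep = ~df[exclude_col].fillna(0).astype(bool)
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(f"dropping {n_drop} row(s) flagged in {exclude_col!r}")
        out = out[keep.to_numpy()]
    # MDV: treat flagged rows as non-observations only if they are doses
    return PKDataset(out)


def write_dataset(data: PKDataset, path, formulation_codes: bool = False) -> None:
    """Write the canonical CSV with full float precision.

    ``formulation_codes`` encodes FORM as 0 (FREE) / 1 (NC) and documents
    the legend in a ``#`` header comment.
    """
    df = data.to_frame()
    buf = io.StringIO()
    if formulation_codes:
        buf.write(f"# FORM codes: 0={FREE}, 1={NC}\n")
        df["FORM"] = df["FORM"].map({FREE: 0, NC: 1})
    df.to_csv(buf, index=False, float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def summarize(data: PKDataset) -> dict:
    """Study summary: per-arm subject counts, observations, covariate ranges."""
    df = data.to_frame()
    subj = df.drop_duplicates("ID")
    obs = df[df["EVID"] == 0]
    per_subject = obs.groupby("ID").size()
    return {
        "n_subjects": int(subj.shape[0]),
        "n_per_arm": {arm: int((subj["FORM"] == arm).sum()) for arm in (FREE, NC)},
        "n_observations": int(obs.shape[0]),
        "obs_per_subject": {int(k): int(v) for k, v in per_subject.items()},
        "weight_range": (float(subj["WT"].min()), float(subj["WT"].max())),
        "age_range": (float(subj["AGE"].min()), float(subj["AGE"].max())),
        "dose_per_kg": sorted(set(df.loc[df["EVID"] == 1, "AMT"].astype(float))),
    }
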