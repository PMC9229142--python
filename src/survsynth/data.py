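"""Data contracts for rectangular time-to-event datasets.

A time-to-event dataset couples a covariate table (categorical factors plus
continuous variables such as age at diagnosis) with calendar-date follow-up
information: a diagnosis date, an exit date, a survival time in whole days
and a vital-status flag.  The contract enforced here is the one the rest of
the package relies on:

* ``exit_date = diagnosis_date + survival_days`` for every record;
* no exit date exceeds the dataset's administrative censoring date (the last
  observed follow-up date in the data);
* records whose follow-up was clamped to the censoring date are recoded as
  alive.

Missing values in categorical covariates can be encoded as an explicit
factor level (so that missingness patterns are themselves modelled and
reproduced) and restored afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import datetime

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSpec",
    "CovariateSchema",
    "TTEDataset",
    "CensoringInfo",
    "load_dataset",
    "write_dataset",
    "derive_censoring",
    "clamp_followup",
    "encode_missing_as_level",
    "restore_missing",
]

DEAD = "dead"
ALIVE = "alive"

_FOLLOWUP_COLUMNS = ("diagnosis_date", "exit_date", "survival_days", "vital_status")


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: its name, kind, level set and modelling position.

    ``model_order`` fixes the covariate's position in the sequential
    conditional modelling chain (1 = modelled first); ``None`` defers to the
    least-to-most-distributional-complexity heuristic.  ``is_year`` marks the
    covariate playing the calendar-year role used for date reconstruction.
    """

    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple[str, ...] = ()
    model_order: int | None = None
    is_year: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 1:
            raise ValueError(f"categorical covariate {self.name!r} needs >=1 level")
        if self.kind == "continuous" and self.levels:
            raise ValueError(f"continuous covariate {self.name!r} must not declare levels")
        if self.model_order is not None and self.model_order < 1:
            raise ValueError("model_order must be a positive integer")


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered collection of covariate declarations."""

    entries: tuple[CovariateSpec, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        if sum(e.is_year for e in self.entries) > 1:
            raise ValueError("at most one covariate may play the calendar-year role")
        orders = [e.model_order for e in self.entries if e.model_order is not None]
        if len(set(orders)) != len(orders):
            raise ValueError("duplicate explicit model_order values")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __getitem__(self, name: str) -> CovariateSpec:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    @property
    def categorical(self) -> list[str]:
        return [e.name for e in self.entries if e.kind == "categorical"]

    @property
    def continuous(self) -> list[str]:
        return [e.name for e in self.entries if e.kind == "continuous"]

    @property
    def year_name(self) -> str | None:
        for e in self.entries:
            if e.is_year:
                return e.name
        return None

    def with_entry(self, entry: CovariateSpec) -> "CovariateSchema":
        new = tuple(entry if e.name == entry.name else e for e in self.entries)
        return CovariateSchema(new)

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "name": e.name,
                    "kind": e.kind,
                    "levels": list(e.levels),
                    "model_order": e.model_order,
                    "is_year": e.is_year,
                }
                for e in self.entries
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSchema":
        return cls(
            tuple(
                CovariateSpec(
                    name=e["name"],
                    kind=e["kind"],
                    levels=tuple(e.get("levels") or ()),
                    model_order=e.get("model_order"),
                    is_year=bool(e.get("is_year", False)),
                )
                for e in d["entries"]
            )
        )


@dataclass(frozen=True)
class CensoringInfo:
    """Administrative censoring metadata derived from a source dataset."""

    admin_censor_date: pd.Timestamp
    last_exit_time_days: int

    def to_dict(self) -> dict:
        return {
            "admin_censor_date": str(pd.Timestamp(self.admin_censor_date).date()),
            "last_exit_time_days": int(self.last_exit_time_days),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CensoringInfo":
        return cls(pd.Timestamp(d["admin_censor_date"]), int(d["last_exit_time_days"]))


class SchemaError(ValueError):
    """A dataset does not satisfy its declared schema."""


@dataclass
class TTEDataset:
    """Validated table of patient records plus its covariate schema."""

    data: pd.DataFrame
    schema: CovariateSchema

    def __post_init__(self) -> None:
        self.data = _validate(self.data, self.schema)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[self.schema.names]

    @property
    def times_days(self) -> np.ndarray:
        return self.data["survival_days"].to_numpy()

    @property
    def events(self) -> np.ndarray:
        return (self.data["vital_status"] == DEAD).to_numpy()


def _parse_dates(series: pd.Series, column: str) -> pd.Series:
    """Parse a date column, accepting ISO (YYYY-MM-DD) and DD/MM/YYYY."""
    if pd.api.types.is_datetime64_any_dtype(series):
        return pd.to_datetime(series)
    s = series.astype("string")
    out = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    bad = out.isna() & s.notna()
    if bad.any():
        retry = pd.to_datetime(s[bad], dayfirst=True, errors="coerce")
        out[bad] = retry
    still = out.isna() & s.notna()
    if still.any():
        row = int(np.flatnonzero(still.to_numpy())[0])
        raise SchemaError(f"unparseable date in column {column!r} at row {row}: {s.iloc[row]!r}")
    return out


def _validate(df: pd.DataFrame, schema: CovariateSchema) -> pd.DataFrame:
    df = df.copy()
    for name in schema.names:
        if name not in df.columns:
            raise SchemaError(f"missing required covariate column {name!r}")
    if "vital_status" not in df.columns:
        raise SchemaError("missing required column 'vital_status'")
    if "diagnosis_date" not in df.columns:
        raise SchemaError("missing required column 'diagnosis_date'")
    if "survival_days" not in df.columns and "exit_date" not in df.columns:
        raise SchemaError("need at least one of 'survival_days' / 'exit_date'")

    df["diagnosis_date"] = _parse_dates(df["diagnosis_date"], "diagnosis_date")
    if "exit_date" in df.columns:
        df["exit_date"] = _parse_dates(df["exit_date"], "exit_date")

    if "survival_days" not in df.columns:
        df["survival_days"] = (df["exit_date"] - df["diagnosis_date"]).dt.days
    sd = pd.to_numeric(df["survival_days"])
    if sd.isna().any():
        raise SchemaError("survival_days contains missing values")
    if (sd < 0).any():
        row = int(np.flatnonzero((sd < 0).to_numpy())[0])
        raise SchemaError(f"negative survival time at row {row}")
    df["survival_days"] = sd.astype(np.int64)
    if "exit_date" not in df.columns:
        df["exit_date"] = df["diagnosis_date"] + pd.to_timedelta(df["survival_days"], unit="D")
    else:
        implied = df["diagnosis_date"] + pd.to_timedelta(df["survival_days"], unit="D")
        if not implied.equals(df["exit_date"]):
            row = int(np.flatnonzero((implied != df["exit_date"]).to_numpy())[0])
            raise SchemaError(
                f"exit_date and diagnosis_date + survival_days disagree at row {row}"
            )

    vs = df["vital_status"].astype("string").str.lower()
    bad = ~vs.isin([DEAD, ALIVE])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"vital_status must be dead/alive (row {row}: {vs.iloc[row]!r})")
    df["vital_status"] = vs.astype(object)

    for e in schema.entries:
        if e.kind == "categorical":
            col = df[e.name]
            vals = col[col.notna()].astype(str)
            unknown = set(vals.unique()) - set(e.levels)
            if unknown:
                raise SchemaError(
                    f"covariate {e.name!r} contains values outside its level set: {sorted(unknown)}"
                )
            df[e.name] = col.where(col.isna(), vals)
        else:
            df[e.name] = pd.to_numeric(df[e.name])

    if "patient_id" not in df.columns:
        df["patient_id"] = [f"P{i:06d}" for i in range(len(df))]
    df["patient_id"] = df["patient_id"].astype(str)

    order = ["patient_id", *schema.names, *_FOLLOWUP_COLUMNS]
    return df[order].reset_index(drop=True)


def load_dataset(path, schema: CovariateSchema) -> TTEDataset:
    """Read a delimited text file and validate it against the schema.

    The file must contain all schema covariates, ``diagnosis_date``,
    ``vital_status`` and at least one of ``survival_days`` / ``exit_date``;
    whichever of the two is absent is derived.
    """
    df = pd.read_csv(path)
    return TTEDataset(df, schema)


def write_dataset(ds: TTEDataset, path) -> None:
    """Write the dataset as UTF-8 CSV with ISO-8601 dates (lossless round trip)."""
    out = ds.data.copy()
    for col in ("diagnosis_date", "exit_date"):
        out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def derive_censoring(ds: TTEDataset) -> CensoringInfo:
    """Administrative censoring date = last observed exit date in the data."""
    if len(ds) == 0:
        raise ValueError("cannot derive censoring from an empty dataset")
    return CensoringInfo(
        admin_censor_date=ds.data["exit_date"].max(),
        last_exit_time_days=int(ds.data["survival_days"].max()),
    )


def clamp_followup(ds: TTEDataset, censor_date) -> TTEDataset:
    """Clamp follow-up beyond a given administrative censoring date.

    Records whose exit date exceeds ``censor_date`` are reassigned to exit at
    the censoring date and recoded as alive (their event, if any, falls
    outside the observation window).
    """
    censor_date = pd.Timestamp(censor_date)
    df = ds.data.copy()
    over = df["exit_date"] > censor_date
    if over.any():
        df.loc[over, "exit_date"] = censor_date
        df.loc[over, "survival_days"] = (censor_date - df.loc[over, "diagnosis_date"]).dt.days
        df.loc[over, "vital_status"] = ALIVE
    return TTEDataset(df, ds.schema)


def encode_missing_as_level(
    ds: TTEDataset, covariate: str, label: str = "Missing"
) -> TTEDataset:
    """Recode absent values of a categorical covariate as an explicit level.

    No-op (level not added) when the covariate has no absent values.
    Inverse of :func:`restore_missing`.
    """
    spec = ds.schema[covariate]
    if spec.kind != "categorical":
        raise ValueError(f"cannot encode missingness as a level for continuous {covariate!r}")
    df = ds.data.copy()
    absent = df[covariate].isna()
    if not absent.any():
        return TTEDataset(df, ds.schema)
    if label in spec.levels:
        raise ValueError(f"level {label!r} already exists for {covariate!r}")
    df.loc[absent, covariate] = label
    schema = ds.schema.with_entry(replace(spec, levels=spec.levels + (label,)))
    return TTEDataset(df, schema)


def restore_missing(ds: TTEDataset, covariate: str, label: str = "Missing") -> TTEDataset:
    """Turn an explicit missing-data level back into truly absent values."""
    spec = ds.schema[covariate]
    if label not in spec.levels:
        raise ValueError(f"{covariate!r} has no level {label!r}")
    df = ds.data.copy()
    df.loc[df[covariate] == label, covariate] = np.nan
    schema = ds.schema.with_entry(
        replace(spec, levels=tuple(l for l in spec.levels if l != label))
    )
    return TTEDataset(df, schema)
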