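"""Cohort container and delimited-text I/O.

A cohort is a per-patient table of observed quantities: a binary tumor
response indicator, an observed follow-up time (minimum of the event and
censoring times), an event indicator, an observed tumor mutation burden
(TMB, mutations/Mb or a simulated scale), zero or more clinical covariates
and an optional subgroup label used by hierarchical misclassification
models.

The on-disk dialect is a plain CSV/TSV with snake_case headers::

    response,time,event,tmb_obs,z1,...,zp[,subgroup]

Extra columns are preserved on read and round-tripped on write.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Cohort", "PatientRecord", "read_cohort", "write_cohort"]

_REQUIRED = ("response", "time", "event", "tmb_obs")
_ZCOL = re.compile(r"^z(\d+)$")


@dataclass
class PatientRecord:
    """A single patient's observed data (row view of a :class:`Cohort`)."""

    response: int
    time: float
    event: int
    tmb_obs: float
    z: np.ndarray
    subgroup: object | None = None


@dataclass
class Cohort:
    """Per-patient observed data backing every model in the package.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain ``response`` (0/1), ``time`` (> 0), ``event`` (0/1) and
        ``tmb_obs`` columns; covariates in columns ``z1..zp``; an optional
        ``subgroup`` column (missing means a single stratum).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        _validate(self.data)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, i: int) -> PatientRecord:
        row = self.data.iloc[i]
        sub = row["subgroup"] if "subgroup" in self.data.columns else None
        return PatientRecord(
            response=int(row["response"]),
            time=float(row["time"]),
            event=int(row["event"]),
            tmb_obs=float(row["tmb_obs"]),
            z=np.asarray([row[c] for c in self.z_columns], dtype=float),
            subgroup=sub,
        )

    # -- column views ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def z_columns(self) -> list[str]:
        cols = [c for c in self.data.columns if _ZCOL.match(c)]
        return sorted(cols, key=lambda c: int(_ZCOL.match(c).group(1)))

    @property
    def response(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=float)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=float)

    @property
    def tmb_obs(self) -> np.ndarray:
        return self.data["tmb_obs"].to_numpy(dtype=float)

    @property
    def z(self) -> np.ndarray:
        """Covariate matrix of shape (n, p); p may be zero."""
        cols = self.z_columns
        if not cols:
            return np.empty((self.n, 0))
        return self.data[cols].to_numpy(dtype=float)

    @property
    def n_covariates(self) -> int:
        return len(self.z_columns)

    @property
    def subgroups(self) -> np.ndarray:
        """Integer subgroup codes (all zero when no subgroup column)."""
        if "subgroup" not in self.data.columns:
            return np.zeros(self.n, dtype=int)
        return pd.Categorical(self.data["subgroup"]).codes.astype(int)

    @property
    def n_subgroups(self) -> int:
        return int(self.subgroups.max()) + 1

    def with_columns(self, **cols: np.ndarray) -> "Cohort":
        """Return a copy with extra/replaced columns (e.g. posterior TMB)."""
        df = self.data.copy()
        for name, values in cols.items():
            df[name] = np.asarray(values)
        return Cohort(df)

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path: str | Path, sep: str | None = None) -> "Cohort":
        return read_cohort(path, sep=sep)


def _validate(df: pd.DataFrame) -> None:
    if len(df) < 1:
        raise ValueError("cohort must contain at least one patient")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
    for col in ("response", "event"):
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"column {col!r} must be 0/1; offending value "
                f"{vals[row]!r} in row {row}"
            )
    t = df["time"].to_numpy(dtype=float)
    bad = ~(t > 0) | ~np.isfinite(t)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"column 'time' must be > 0; row {row} has {t[row]!r}")
    zcols = [c for c in df.columns if _ZCOL.match(c)]
    for col in zcols + ["tmb_obs"]:
        vals = df[col].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            row = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise ValueError(f"column {col!r} has non-finite value in row {row}")


def read_cohort(path: str | Path, sep: str | None = None) -> Cohort:
    """Read a cohort table from CSV/TSV (separator sniffed by default)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return Cohort(df)


def write_cohort(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    cohort.write(path, sep=sep)
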