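"""Domain types and delimited-text I/O for multistate survival records.

The observed unit of an irreversible illness-death study is
``O = (t1, t2, illness, death, treatment, W)`` where ``t1`` is the time of
leaving the initial (healthy) state or censoring, whichever comes first,
``t2`` the terminal-event/censoring time, ``illness`` indicates an observed
1→2 transition (``t1 < t2``), ``death`` indicates that the terminal event was
observed (not censored), ``treatment`` is a binary baseline exposure and
``W`` a vector of baseline covariates.

Times live on an arbitrary continuous scale with origin 0 at study entry;
no calendar-date parsing is attempted.  Exact ties between an event and a
censoring time are resolved event-first, so rounded real-world times remain
usable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: default column names for the six subject-record roles
DEFAULT_SCHEMA = {
    "time1": "time1",
    "time2": "time2",
    "illness": "illness",
    "death": "death",
    "treatment": "treatment",
}

_CORE_ROLES = ("time1", "time2", "illness", "death", "treatment")


class DataError(ValueError):
    """Raised when records violate the illness-death data contract."""


@dataclass
class Dataset:
    """An ordered collection of subject records plus covariate labels.

    Wraps a :class:`pandas.DataFrame` with the five core columns named as in
    :data:`DEFAULT_SCHEMA` and any number of numeric covariate columns.
    """

    df: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    # -- array accessors used throughout the estimation code -------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def t1(self) -> np.ndarray:
        return self.df["time1"].to_numpy(float)

    @property
    def t2(self) -> np.ndarray:
        return self.df["time2"].to_numpy(float)

    @property
    def illness(self) -> np.ndarray:
        return self.df["illness"].to_numpy(int)

    @property
    def death(self) -> np.ndarray:
        return self.df["death"].to_numpy(int)

    @property
    def treatment(self) -> np.ndarray:
        return self.df["treatment"].to_numpy(int)

    @property
    def W(self) -> np.ndarray:
        """Covariate matrix of shape ``(n, d)`` (d may be 0)."""
        if not self.covariates:
            return np.empty((self.n, 0))
        return self.df[self.covariates].to_numpy(float)

    def subset(self, idx) -> "Dataset":
        """Row subset/resample (used by the bootstrap)."""
        return Dataset(self.df.iloc[idx].reset_index(drop=True), list(self.covariates))


def validate_dataset(ds: Dataset) -> Dataset:
    """Verify every subject-record invariant; return the dataset unchanged.

    Derives the ``illness`` flag from the times when the column is absent
    (``illness = I(t1 < t2)``); the ``death`` flag cannot be derived (a
    subject with ``t1 == t2`` may be a direct death or censored in the
    healthy state) and is required.

    Raises
    ------
    DataError
        naming the first offending row index and the violated invariant.
    """
    df = ds.df
    for col in ("time1", "time2", "death", "treatment"):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r}")
    if "illness" not in df.columns:
        df = df.copy()
        df["illness"] = (df["time1"].to_numpy(float) < df["time2"].to_numpy(float)).astype(int)
        ds = Dataset(df, list(ds.covariates))
    if len(df) == 0:
        raise DataError("dataset is empty")

    for col in _CORE_ROLES:
        vals = df[col].to_numpy()
        if not np.issubdtype(np.asarray(vals).dtype, np.number):
            raise DataError(f"column {col!r} is not numeric")
        bad = np.flatnonzero(~np.isfinite(vals.astype(float)))
        if bad.size:
            raise DataError(f"row {bad[0]}: non-finite value in column {col!r}")
    for col in ds.covariates:
        if col not in df.columns:
            raise DataError(f"missing covariate column {col!r}")
        vals = df[col].to_numpy(float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise DataError(f"row {bad[0]}: missing/non-finite covariate {col!r}")

    t1, t2 = ds.t1, ds.t2
    ill, dead, a = ds.illness, ds.death, ds.treatment

    def _first(mask: np.ndarray, msg: str) -> None:
        bad = np.flatnonzero(mask)
        if bad.size:
            raise DataError(f"row {bad[0]}: {msg}")

    _first(t1 <= 0, "times must be strictly positive (time1 <= 0)")
    _first(t2 <= 0, "times must be strictly positive (time2 <= 0)")
    _first(t1 > t2, "t1_obs > t2_obs")
    _first(~np.isin(a, (0, 1)), "treatment not in {0, 1}")
    _first(~np.isin(ill, (0, 1)), "illness not in {0, 1}")
    _first(~np.isin(dead, (0, 1)), "death not in {0, 1}")
    _first((ill == 1) & (t1 >= t2), "illness=1 requires t1_obs < t2_obs")
    _first((ill == 0) & (t1 != t2), "illness=0 requires t1_obs = t2_obs")
    return ds


def read_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    covariates: Sequence[str] | None = None,
) -> Dataset:
    """Read a delimited text file (CSV, or TSV by ``.tsv`` extension).

    Parameters
    ----------
    path
        file with a header row.
    schema
        mapping from the five roles (``time1 .. treatment``) to the column
        names used in the file; defaults to the role names themselves.
    covariates
        explicit covariate column list; by default every remaining numeric
        column is treated as a covariate.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    rename = {}
    for role in _CORE_ROLES:
        src = colmap[role]
        if src not in raw.columns:
            if role == "illness":
                continue  # derivable
            raise DataError(f"missing column {src!r} (role {role!r})")
        rename[src] = role
    df = raw.rename(columns=rename)
    if covariates is None:
        covs = [
            c for c in df.columns
            if c not in _CORE_ROLES and np.issubdtype(df[c].dtype, np.number)
        ]
    else:
        covs = list(covariates)
    return validate_dataset(Dataset(df, covs))


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write to delimited text at full double precision (round-trip safe)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cols = list(_CORE_ROLES) + list(ds.covariates)
    ds.df[cols].to_csv(path, sep=sep, index=False, float_format="%.17g")


@dataclass
class EstimandResult:
    """Counterfactual risks and effect contrasts on a time grid.

    ``psi[(tau, aD, aI)]`` is the estimated risk of the terminal event by
    ``tau`` under interventions setting the direct treatment component to
    ``aD`` and the indirect (illness-mediated) component to ``aI``.
    The separable direct effect ``sde[(tau, aI)]`` contrasts ``aD=1`` vs
    ``aD=0``; the separable indirect effect ``sie[(tau, aD)]`` contrasts
    ``aI=1`` vs ``aI=0``; ``te[tau]`` is the total effect, which satisfies
    ``te = sde(·, a) + sie(·, 1−a)`` exactly for either ``a``.
    """

    tau_grid: np.ndarray
    psi: dict
    sde: dict
    sie: dict
    te: dict
    estimator: str
    se: dict | None = None
    ci: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: tau, estimand, level, estimate, se, ci bounds."""
        rows = []

        def _se_ci(key):
            se = self.se.get(key) if self.se else None
            ci = self.ci.get(key) if self.ci else None
            lo, hi = (ci if ci is not None else (None, None))
            return se, lo, hi

        for (tau, ad, ai), val in sorted(self.psi.items()):
            se, lo, hi = _se_ci(("psi", tau, ad, ai))
            rows.append(("psi", tau, f"aD={ad},aI={ai}", val, se, lo, hi))
        for (tau, ai), val in sorted(self.sde.items()):
            se, lo, hi = _se_ci(("sde", tau, ai))
            rows.append(("sde", tau, f"aI={ai}", val, se, lo, hi))
        for (tau, ad), val in sorted(self.sie.items()):
            se, lo, hi = _se_ci(("sie", tau, ad))
            rows.append(("sie", tau, f"aD={ad}", val, se, lo, hi))
        for tau, val in sorted(self.te.items()):
            se, lo, hi = _se_ci(("te", tau))
            rows.append(("te", tau, "", val, se, lo, hi))
        out = pd.DataFrame(
            rows,
            columns=["estimand", "tau", "level", "estimate", "se", "ci_low", "ci_high"],
        )
        out["estimator"] = self.estimator
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = self.to_frame().to_dict(orient="records")
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text
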