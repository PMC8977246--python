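"""Survival data containers and delimited-text I/O.

The central object is :class:`SurvivalDataset`: right-censored survival data
with a fixed, finite number of strata and a covariate matrix in which some
entries may be missing.  Missingness is carried as an explicit boolean mask;
the per-subject *response indicator* ``xi`` (1 iff every covariate is
observed) is always derived from the mask, never stored independently.

:class:`PatternDataset` extends this for the two-covariate multiple-pattern
setting, where each of two designated missingness-prone covariates has its
own observation indicator (eta1, eta2) and subjects fall into one of four
observation categories 11/10/01/00.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "PatternDataset",
    "read_dataset",
    "write_dataset",
    "complete_cases",
]

#: strings treated as missing cells in delimited files
NA_STRINGS = ("", "NA")


@dataclass
class SurvivalDataset:
    """Right-censored stratified survival data with a missingness mask.

    Parameters
    ----------
    time : (n,) float array
        Observed time ``X = min(T, C)``, nonnegative.
    event : (n,) int array
        Event indicator ``Delta = I(T <= C)`` in {0, 1}.
    stratum : (n,) int array
        Stratum codes ``0 .. L-1``.  Original labels are kept in
        ``stratum_labels`` (first-appearance order); code 0 is the
        reference stratum for response-model intercepts.
    Z : (n, p) float array
        Covariate matrix; entries with ``mask`` False are not interpretable
        (stored as NaN).
    mask : (n, p) bool array
        True where the covariate value is observed.
    covariate_names : list of str
    stratum_labels : list
        Original stratum labels, index = code.
    horizon : float
        Administrative end of study ``tau``; defaults to ``max(time)`` so
        every event time is covered by the score integrals.
    """

    time: np.ndarray
    event: np.ndarray
    stratum: np.ndarray
    Z: np.ndarray
    mask: np.ndarray
    covariate_names: list = field(default_factory=list)
    stratum_labels: list = field(default_factory=list)
    horizon: float = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.stratum = np.asarray(self.stratum, dtype=int)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.shape[0] != self.time.shape[0]:
            self.Z = self.Z.T
        self.mask = np.asarray(self.mask, dtype=bool).reshape(self.Z.shape)
        _validate_core(self.time, self.event, self.stratum)
        if not self.covariate_names:
            self.covariate_names = [f"z{j+1}" for j in range(self.Z.shape[1])]
        if not self.stratum_labels:
            self.stratum_labels = list(range(1, self.n_strata + 1))
        if self.horizon is None:
            self.horizon = float(self.time.max()) if len(self.time) else 0.0
        if self.horizon <= 0:
            raise ValueError("horizon tau must be positive")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    @property
    def n_strata(self) -> int:
        return int(self.stratum.max()) + 1 if len(self.stratum) else 0

    @property
    def xi(self) -> np.ndarray:
        """Response indicator: 1 iff all covariates observed (derived)."""
        return self.mask.all(axis=1).astype(int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time": self.time,
            "status": self.event,
            "stratum": [self.stratum_labels[s] for s in self.stratum],
        })
        for j, name in enumerate(self.covariate_names):
            col = self.Z[:, j].copy()
            col[~self.mask[:, j]] = np.nan
            df[name] = col
        return df

    def check_events_per_stratum(self, min_events: int = 2) -> None:
        """Refuse fitting when any stratum has fewer than ``min_events`` events."""
        for code in range(self.n_strata):
            n_ev = int(self.event[self.stratum == code].sum())
            if n_ev < min_events:
                raise ValueError(
                    f"stratum {self.stratum_labels[code]!r} has {n_ev} events; "
                    f"need at least {min_events} to fit"
                )


@dataclass
class PatternDataset(SurvivalDataset):
    """Survival data with two designated missingness-prone covariates.

    ``missing_idx`` gives the column indices (into ``Z``) of the two
    covariates subject to missingness; every other column must be fully
    observed.  Observation indicators eta1, eta2 and the four-category label
    are derived from the mask.
    """

    missing_idx: tuple = (0, 1)

    def __post_init__(self):
        super().__post_init__()
        j1, j2 = self.missing_idx
        others = [j for j in range(self.p) if j not in (j1, j2)]
        if others and not self.mask[:, others].all():
            raise ValueError("covariates outside missing_idx must be fully observed")

    @property
    def eta1(self) -> np.ndarray:
        return self.mask[:, self.missing_idx[0]].astype(int)

    @property
    def eta2(self) -> np.ndarray:
        return self.mask[:, self.missing_idx[1]].astype(int)

    @property
    def category(self) -> np.ndarray:
        """Observation category per subject: 0='11', 1='10', 2='01', 3='00'."""
        return (1 - self.eta1) * 2 + (1 - self.eta2)

    def category_counts(self) -> np.ndarray:
        """N_ab for ab in (11, 10, 01, 00); sums to n."""
        return np.bincount(self.category, minlength=4)


def _validate_core(time, event, stratum):
    if np.any(~np.isfinite(time)):
        bad = int(np.flatnonzero(~np.isfinite(time))[0])
        raise ValueError(f"non-finite time in row {bad}")
    if np.any(time < 0):
        bad = int(np.flatnonzero(time < 0)[0])
        raise ValueError(f"negative time in row {bad}")
    if not np.isin(event, (0, 1)).all():
        bad = int(np.flatnonzero(~np.isin(event, (0, 1)))[0])
        raise ValueError(f"non-binary event indicator in row {bad}")


def _encode_strata(raw) -> tuple[np.ndarray, list]:
    labels: list = []
    codes = np.empty(len(raw), dtype=int)
    lookup: dict = {}
    for i, lab in enumerate(raw):
        if lab not in lookup:
            lookup[lab] = len(labels)
            labels.append(lab)
        codes[i] = lookup[lab]
    return codes, labels


def read_dataset(
    path,
    *,
    time: str = "time",
    event: str = "status",
    stratum: str = "stratum",
    covariates: list | None = None,
    sep: str | None = None,
    horizon: float | None = None,
) -> SurvivalDataset:
    """Read a delimited text file (CSV/TSV with header) into a dataset.

    Empty cells and the literal string ``NA`` in covariate columns become
    unobserved entries (mask False).  The time/event/stratum columns must be
    fully observed.  Row order is preserved.
    """
    df = pd.read_csv(path, sep=sep, engine="python", na_values=list(NA_STRINGS),
                     keep_default_na=False)
    for col in (time, event, stratum):
        if col not in df.columns:
            raise ValueError(f"unknown column {col!r}; file has {list(df.columns)}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in (time, event, stratum)]
    for col in covariates:
        if col not in df.columns:
            raise ValueError(f"unknown covariate column {col!r}")
    for col in (time, event, stratum):
        if df[col].isna().any():
            bad = int(df.index[df[col].isna()][0])
            raise ValueError(f"missing value in required column {col!r}, row {bad}")
    codes, labels = _encode_strata(df[stratum].tolist())
    Z = df[covariates].to_numpy(dtype=float)
    mask = ~np.isnan(Z)
    Zf = np.where(mask, Z, np.nan)
    return SurvivalDataset(
        time=df[time].to_numpy(dtype=float),
        event=df[event].to_numpy(),
        stratum=codes,
        Z=Zf,
        mask=mask,
        covariate_names=list(covariates),
        stratum_labels=labels,
        horizon=horizon,
    )


def write_dataset(d: SurvivalDataset, path, sep: str = ",") -> None:
    """Write a dataset back to delimited text; unobserved cells become NA."""
    d.to_frame().to_csv(path, sep=sep, index=False, na_rep="NA")


def complete_cases(d: SurvivalDataset) -> SurvivalDataset:
    """Subset to subjects with all covariates observed (xi = 1).

    Stratum labels and codes are retained.  Raises if a stratum loses all
    its events, in which case a stratified fit would be degenerate.
    """
    keep = d.mask.all(axis=1)
    if not keep.any():
        raise ValueError("no complete cases in dataset")
    sub = SurvivalDataset(
        time=d.time[keep],
        event=d.event[keep],
        stratum=d.stratum[keep],
        Z=d.Z[keep],
        mask=d.mask[keep],
        covariate_names=list(d.covariate_names),
        stratum_labels=list(d.stratum_labels),
        horizon=d.horizon,
    )
    for code in range(d.n_strata):
        if sub.event[sub.stratum == code].sum() == 0:
            raise ValueError(
                f"stratum {d.stratum_labels[code]!r} has no events among complete cases"
            )
    return sub
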