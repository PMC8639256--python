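"""Force-plate / COP input-output and cohort organisation.

A trial is one quiet-standing recording of a subject under one of four
conditions — eyes Closed or Open on a Rigid surface or Foam mat (CR, OR,
CF, OF) — stored either as the six raw plate channels (Fx, Fy, Fz, Mx,
My, Mz) or as a pre-computed pair of COP displacement series.  ``C4``
denotes the pool of all four conditions, each trial remaining one
analysis unit.

COP displacement is obtained from the plate channels by the standard
plate equations

    COPx = (-My - Fx * h) / Fz        (anterior-posterior)
    COPy = ( Mx - Fy * h) / Fz        (mediolateral)

with ``h`` the height of the plate origin above its surface (0 for a
surface-origin plate or pre-reduced data).  Every COP series is
mean-centered once at load time so that displacement is sway about the
stance point; downstream RMSD is then the root-mean-square sway.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("CR", "OR", "CF", "OF")
POOLED = "C4"
VIEWS = CONDITIONS + (POOLED,)
GROUPS = ("fall", "nonfall")

FORCE_COLUMNS = ("fx", "fy", "fz", "mx", "my", "mz")
COP_COLUMNS = ("cop_x", "cop_y")

#: float format that round-trips IEEE doubles through text exactly
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A data file does not conform to the expected dialect."""


class UnstableLoadError(ValueError):
    """Vertical force too close to zero for a stable COP quotient."""


def _as_series(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise FormatError(f"channel {name!r} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ForcePlateRecord:
    """One trial's six force/moment channels plus its metadata."""

    subject_id: str
    group_label: str
    condition: str
    trial_index: int
    sampling_rate: float
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray

    def __post_init__(self):
        for name in FORCE_COLUMNS:
            object.__setattr__(self, name, _as_series(name, getattr(self, name)))
        lengths = {len(getattr(self, name)) for name in FORCE_COLUMNS}
        if len(lengths) != 1:
            raise FormatError(f"unequal channel lengths: {sorted(lengths)}")
        if lengths.pop() < 2:
            raise FormatError("channels must hold at least 2 samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.group_label not in GROUPS:
            raise ValueError(f"group_label must be one of {GROUPS}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.fx)


@dataclass(frozen=True)
class CopTrace:
    """Paired COPx (anterior-posterior) / COPy (mediolateral) series."""

    subject_id: str
    group_label: str
    condition: str
    trial_index: int
    sampling_rate: float
    cop_x: np.ndarray
    cop_y: np.ndarray

    def __post_init__(self):
        for name in COP_COLUMNS:
            object.__setattr__(self, name, _as_series(name, getattr(self, name)))
        if len(self.cop_x) != len(self.cop_y):
            raise FormatError("cop_x and cop_y must have equal length")
        if not (np.isfinite(self.cop_x).all() and np.isfinite(self.cop_y).all()):
            raise FormatError("COP series must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.group_label not in GROUPS:
            raise ValueError(f"group_label must be one of {GROUPS}")

    @property
    def n_samples(self) -> int:
        return len(self.cop_x)

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.condition, self.trial_index)

    def axis(self, which: str) -> np.ndarray:
        if which == "x":
            return self.cop_x
        if which == "y":
            return self.cop_y
        raise ValueError("axis must be 'x' or 'y'")

    def truncated(self, duration: float) -> "CopTrace":
        """Return a copy restricted to the first ``duration`` seconds."""
        n = int(round(duration * self.sampling_rate))
        if n >= self.n_samples:
            return self
        cx = self.cop_x[:n]
        cy = self.cop_y[:n]
        return replace(self, cop_x=cx - cx.mean(), cop_y=cy - cy.mean())


@dataclass(frozen=True)
class CohortDataset:
    """A collection of CopTrace records under a condition view.

    The view selects trials by recording condition; ``C4`` is the union
    of the four conditions (every trial stays one analysis unit — no
    concatenation).
    """

    records: tuple
    condition_view: str = POOLED

    def __post_init__(self):
        if self.condition_view not in VIEWS:
            raise ValueError(
                f"unknown condition view {self.condition_view!r}; expected one of {VIEWS}"
            )
        if len(self.records) == 0:
            raise ValueError("a cohort dataset cannot be empty")

    @property
    def traces(self) -> tuple:
        if self.condition_view == POOLED:
            return self.records
        return tuple(r for r in self.records if r.condition == self.condition_view)

    def __len__(self) -> int:
        return len(self.traces)

    def view(self, selector: str) -> "CohortDataset":
        return CohortDataset(self.records, selector)


def compute_cop(
    record: ForcePlateRecord,
    plate_origin_height: float = 0.0,
    fz_floor: float = 1.0,
    center: bool = True,
) -> CopTrace:
    """Derive the COP trace from force/moment channels.

    Raises :class:`UnstableLoadError` if any |Fz| sample is at or below
    ``fz_floor`` (default 1 N), where the quotient becomes meaningless.
    By default the resulting series are mean-centered (sway about the
    stance point).
    """
    h = float(plate_origin_height)
    bad = np.flatnonzero(np.abs(record.fz) <= fz_floor)
    if bad.size:
        raise UnstableLoadError(
            f"|fz| <= {fz_floor} N at sample index {int(bad[0])}"
        )
    cop_x = (-record.my - record.fx * h) / record.fz
    cop_y = (record.mx - record.fy * h) / record.fz
    if center:
        cop_x = cop_x - cop_x.mean()
        cop_y = cop_y - cop_y.mean()
    return CopTrace(
        subject_id=record.subject_id,
        group_label=record.group_label,
        condition=record.condition,
        trial_index=record.trial_index,
        sampling_rate=record.sampling_rate,
        cop_x=cop_x,
        cop_y=cop_y,
    )


def pool_conditions(records: Iterable[CopTrace], view: str) -> CohortDataset:
    """Organise traces under a condition view (C4 = union of all four)."""
    records = tuple(records)
    if not records:
        raise ValueError("no records to pool")
    return CohortDataset(records, view)


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if len(df) < 2:
        raise FormatError(f"{path}: needs at least 2 data rows, found {len(df)}")
    return df


def read_force_plate(
    path,
    subject_id: str,
    group_label: str,
    condition: str,
    trial_index: int,
    sampling_rate: float,
) -> ForcePlateRecord:
    """Read a six-channel force-plate CSV (header ``fx,fy,fz,mx,my,mz``)."""
    df = _read_table(path, FORCE_COLUMNS)
    return ForcePlateRecord(
        subject_id=subject_id,
        group_label=group_label,
        condition=condition,
        trial_index=int(trial_index),
        sampling_rate=float(sampling_rate),
        **{c: df[c].to_numpy(float) for c in FORCE_COLUMNS},
    )


def read_cop(
    path,
    subject_id: str,
    group_label: str,
    condition: str,
    trial_index: int,
    sampling_rate: float,
    center: bool = True,
) -> CopTrace:
    """Read a pre-computed COP CSV (header ``cop_x,cop_y``)."""
    df = _read_table(path, COP_COLUMNS)
    cop_x = df["cop_x"].to_numpy(float)
    cop_y = df["cop_y"].to_numpy(float)
    if center:
        cop_x = cop_x - cop_x.mean()
        cop_y = cop_y - cop_y.mean()
    return CopTrace(
        subject_id=subject_id,
        group_label=group_label,
        condition=condition,
        trial_index=int(trial_index),
        sampling_rate=float(sampling_rate),
        cop_x=cop_x,
        cop_y=cop_y,
    )


def write_cop(trace: CopTrace, path) -> None:
    """Write a COP CSV preserving full double precision."""
    df = pd.DataFrame({"cop_x": trace.cop_x, "cop_y": trace.cop_y})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_manifest(traces: Sequence[CopTrace], directory, manifest_name="manifest.csv"):
    """Write per-trial COP CSVs plus the sidecar manifest into a directory."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for tr in traces:
        fname = f"{tr.subject_id}_{tr.condition}_{tr.trial_index}.csv"
        write_cop(tr, os.path.join(directory, fname))
        rows.append(
            dict(
                path=fname,
                subject_id=tr.subject_id,
                group=tr.group_label,
                condition=tr.condition,
                trial=tr.trial_index,
                sampling_rate=tr.sampling_rate,
            )
        )
    mpath = os.path.join(directory, manifest_name)
    pd.DataFrame(rows).to_csv(mpath, index=False, float_format=_FLOAT_FMT)
    return mpath


def read_manifest(manifest_path, center: bool = True) -> list:
    """Load all trials listed in a manifest CSV.

    Each referenced file may be in the COP dialect (``cop_x,cop_y``) or
    the raw force-plate dialect (``fx,...,mz``); the latter is run
    through :func:`compute_cop` with default settings.
    """
    man = _read_table_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    traces = []
    for row in man.itertuples(index=False):
        fpath = row.path
        if not os.path.isabs(fpath):
            fpath = os.path.join(base, fpath)
        header = pd.read_csv(fpath, nrows=0)
        cols = {c.strip().lower() for c in header.columns}
        meta = dict(
            subject_id=str(row.subject_id),
            group_label=str(row.group),
            condition=str(row.condition),
            trial_index=int(row.trial),
            sampling_rate=float(row.sampling_rate),
        )
        if set(COP_COLUMNS) <= cols:
            traces.append(read_cop(fpath, center=center, **meta))
        elif set(FORCE_COLUMNS) <= cols:
            traces.append(compute_cop(read_force_plate(fpath, **meta), center=center))
        else:
            raise FormatError(f"{fpath}: neither COP nor force-plate dialect")
    return traces


def _read_table_manifest(path) -> pd.DataFrame:
    required = ("path", "subject_id", "group", "condition", "trial", "sampling_rate")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {missing}")
    return df
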