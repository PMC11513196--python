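"""Core data containers: subject-level tables and trial-level ERP epochs.

A :class:`DataTable` is a thin wrapper around a pandas DataFrame that adds a
role label per variable (``trait``, ``erp_amplitude``, ``erp_latency``,
``covariate``).  Roles drive which variables enter which network recipe.

An :class:`EpochSet` holds per-subject trial x time-sample arrays on a shared
response-locked time axis, the way averaged single-channel EEG epochs are
handled after preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_ROLES = ("trait", "erp_amplitude", "erp_latency", "covariate")


@dataclass
class DataTable:
    """Subjects x variables matrix with per-variable role labels.

    Parameters
    ----------
    data : pandas.DataFrame
        Numeric matrix, one row per subject.  The index holds subject IDs.
    roles : dict
        Maps every column name to one of ``trait``, ``erp_amplitude``,
        ``erp_latency``, ``covariate``.
    """

    data: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate column names: {dupes}")
        missing = [c for c in cols if c not in self.roles]
        if missing:
            raise ValueError(f"missing role for column(s): {missing}")
        bad = {c: r for c, r in self.roles.items() if r not in VALID_ROLES}
        if bad:
            raise ValueError(f"invalid roles {bad}; valid roles are {VALID_ROLES}")
        non_numeric = [
            c for c in cols if not np.issubdtype(self.data[c].dtype, np.number)
        ]
        if non_numeric:
            raise ValueError(f"non-numeric column(s): {non_numeric}")
        # keep roles restricted to present columns, in column order
        self.roles = {c: self.roles[c] for c in cols}

    # -- convenience -------------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def columns_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] in roles]

    def select(self, columns: list[str]) -> "DataTable":
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise KeyError(f"columns not in table: {missing}")
        return DataTable(self.data[columns].copy(), {c: self.roles[c] for c in columns})

    # -- IO ----------------------------------------------------------------
    def write(self, csv_path: str | Path, roles_path: str | Path | None = None) -> None:
        """Write values as CSV (header row, subject-ID index) plus a JSON role map."""
        csv_path = Path(csv_path)
        if roles_path is None:
            roles_path = csv_path.with_suffix(".roles.json")
        self.data.to_csv(csv_path, index_label="subject_id")
        Path(roles_path).write_text(json.dumps(self.roles, indent=1))

    @classmethod
    def read(cls, csv_path: str | Path, roles_path: str | Path | None = None) -> "DataTable":
        csv_path = Path(csv_path)
        if roles_path is None:
            roles_path = csv_path.with_suffix(".roles.json")
        df = pd.read_csv(csv_path, index_col="subject_id", float_precision="round_trip")
        for j, c in enumerate(df.columns):
            if not np.issubdtype(df[c].dtype, np.number):
                bad_rows = df.index[pd.to_numeric(df[c], errors="coerce").isna()][:5]
                raise ValueError(
                    f"non-numeric cells in column {c!r} (index {j}), rows {list(bad_rows)}"
                )
        roles = json.loads(Path(roles_path).read_text())
        return cls(df, roles)


@dataclass
class EpochSet:
    """Per-subject single-channel epochs on a shared response-locked axis.

    ``epochs[i]`` is an (n_trials_i, n_samples) array in microvolts for subject
    ``subject_ids[i]``; ``times`` is the axis in milliseconds relative to the
    response.  ``truth`` optionally carries the generating per-subject
    amplitudes/latencies when the set is synthetic.
    """

    subject_ids: list[str]
    epochs: list[np.ndarray]
    times: np.ndarray  # ms, response-locked
    sampling_rate: float  # Hz
    condition: str = "error"
    truth: dict | None = None

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(self.epochs):
            raise ValueError("subject_ids and epochs length mismatch")
        n = len(self.times)
        for sid, ep in zip(self.subject_ids, self.epochs):
            if ep.ndim != 2 or ep.shape[1] != n:
                raise ValueError(f"subject {sid}: epochs must be (trials, {n})")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def n_trials(self) -> dict[str, int]:
        return {sid: ep.shape[0] for sid, ep in zip(self.subject_ids, self.epochs)}

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        if lo < self.times[0] or hi > self.times[-1]:
            raise ValueError(
                f"window {window} outside epoch axis "
                f"[{self.times[0]}, {self.times[-1]}] ms"
            )
        return (self.times >= lo) & (self.times <= hi)

    # -- IO: one array file per subject plus a JSON manifest ----------------
    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "sampling_rate": self.sampling_rate,
            "condition": self.condition,
            "times_ms": self.times.tolist(),
            "subjects": [],
        }
        for sid, ep in zip(self.subject_ids, self.epochs):
            fname = f"epochs_{sid}.csv"
            np.savetxt(directory / fname, ep, delimiter=",", fmt="%.10g")
            manifest["subjects"].append({"id": sid, "file": fname, "n_trials": ep.shape[0]})
        if self.truth is not None:
            manifest["truth"] = {k: np.asarray(v).tolist() for k, v in self.truth.items()}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def read(cls, directory: str | Path) -> "EpochSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        ids, eps = [], []
        for entry in manifest["subjects"]:
            ids.append(entry["id"])
            arr = np.loadtxt(directory / entry["file"], delimiter=",", ndmin=2)
            eps.append(arr)
        truth = manifest.get("truth")
        if truth is not None:
            truth = {k: np.asarray(v) for k, v in truth.items()}
        return cls(
            subject_ids=ids,
            epochs=eps,
            times=np.asarray(manifest["times_ms"], dtype=float),
            sampling_rate=manifest["sampling_rate"],
            condition=manifest["condition"],
            truth=truth,
        )
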