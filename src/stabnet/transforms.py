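"""Variable normalization ahead of Gaussian network estimation.

Fixed pipeline order: fit/apply Box-Cox per variable -> screen out variables
that remain severely non-normal -> standardize columns to mean 0, SD 1.  A
pipeline fitted on the training split is applied unchanged to the test split
so hold-out evaluation never peeks at test data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import DataTable

LAMBDA_BOUNDS = (-5.0, 5.0)
LAMBDA_TOL = 1e-4
DEFAULT_SKEW_LIMIT = 2.0


@dataclass
class TransformRecord:
    """Fitted Box-Cox parameters for one variable."""

    variable: str
    shift: float  # additive offset making the minimum exactly 1 (if needed)
    lam: float  # Box-Cox exponent
    pre_skewness: float
    post_skewness: float
    kept: bool = True


def boxcox_fit(x: np.ndarray, variable: str = "") -> TransformRecord:
    """Profile-likelihood Box-Cox fit with an automatic positivity shift.

    The shift is ``1 - min(x)`` when the minimum is non-positive (so the
    shifted minimum is exactly 1, which keeps the lambda likelihood
    well-behaved for ERP amplitudes that can be negative), else 0.  Lambda
    maximizes the Box-Cox profile log-likelihood over [-5, 5].
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("need >= 10 finite values to fit Box-Cox")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: Box-Cox undefined")
    shift = 1.0 - float(x.min()) if x.min() <= 0 else 0.0
    xs = x + shift
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, xs),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": LAMBDA_TOL},
    )
    lam = float(res.x)
    rec = TransformRecord(
        variable=variable,
        shift=shift,
        lam=lam,
        pre_skewness=float(stats.skew(x)),
        post_skewness=0.0,
    )
    rec.post_skewness = float(stats.skew(boxcox_apply(x, rec)))
    return rec


def boxcox_apply(x: np.ndarray, record: TransformRecord, clip: bool = False) -> np.ndarray:
    """Apply a fitted Box-Cox transform; strictly increasing in x.

    With ``clip=True`` values that fall at or below the positivity boundary
    (possible when a training-fitted shift is applied to a test split whose
    minimum undercuts the training minimum) are clipped to a small positive
    floor instead of raising.
    """
    x = np.asarray(x, dtype=float)
    xs = x + record.shift
    if np.any(xs <= 0):
        if not clip:
            raise ValueError(
                f"non-positive values after shift {record.shift} "
                f"(min {xs.min():.3g}); cannot Box-Cox"
            )
        xs = np.maximum(xs, 1e-3)
    if abs(record.lam) < 1e-12:
        return np.log(xs)
    return (xs ** record.lam - 1.0) / record.lam


def normality_screen(
    table: DataTable,
    records: dict[str, TransformRecord] | None = None,
    skew_limit: float = DEFAULT_SKEW_LIMIT,
) -> tuple[DataTable, list[str]]:
    """Drop variables whose post-transform |skewness| exceeds ``skew_limit``.

    Mirrors the practice of excluding irreparably non-normal scales before
    Gaussian network estimation; the threshold is a configurable stand-in for
    that judgment call.
    """
    dropped = []
    for col in table.columns:
        sk = float(stats.skew(table.data[col].to_numpy(dtype=float)))
        if abs(sk) > skew_limit:
            dropped.append(col)
            if records is not None and col in records:
                records[col].kept = False
    kept_cols = [c for c in table.columns if c not in dropped]
    return table.select(kept_cols), dropped


@dataclass
class StandardizeRecord:
    mean: float
    sd: float


def standardize(
    table: DataTable, params: dict[str, StandardizeRecord] | None = None
) -> tuple[DataTable, dict[str, StandardizeRecord]]:
    """Scale each column to mean 0, SD 1 (population SD, matching the 1/n
    covariance used downstream).  Pass fitted ``params`` to reuse a training
    scaling on the test split; returns the parameters for inverse mapping.
    """
    df = table.data.copy()
    out_params = {}
    for col in table.columns:
        x = df[col].to_numpy(dtype=float)
        if params is not None:
            rec = params[col]
        else:
            sd = float(x.std(ddof=0))
            if sd == 0:
                raise ValueError(f"zero-variance column: {col!r}")
            rec = StandardizeRecord(mean=float(x.mean()), sd=sd)
        df[col] = (x - rec.mean) / rec.sd
        out_params[col] = rec
    return DataTable(df, dict(table.roles)), out_params


class TransformPipeline:
    """Box-Cox -> screen -> standardize, fitted on training data only."""

    def __init__(self, skew_limit: float = DEFAULT_SKEW_LIMIT):
        self.skew_limit = skew_limit
        self.records: dict[str, TransformRecord] = {}
        self.dropped: list[str] = []
        self.scale_params: dict[str, StandardizeRecord] = {}
        self._fitted = False

    def fit_transform(self, train: DataTable) -> DataTable:
        df = train.data.copy()
        for col in train.columns:
            rec = boxcox_fit(df[col].to_numpy(dtype=float), variable=col)
            self.records[col] = rec
            df[col] = boxcox_apply(df[col].to_numpy(dtype=float), rec)
        transformed = DataTable(df, dict(train.roles))
        screened, self.dropped = normality_screen(
            transformed, self.records, self.skew_limit
        )
        standardized, self.scale_params = standardize(screened)
        self._fitted = True
        return standardized

    def transform(self, table: DataTable) -> DataTable:
        """Apply the training-fitted transform unchanged (e.g. to a test split)."""
        if not self._fitted:
            raise RuntimeError("pipeline not fitted")
        keep = [c for c in table.columns if c not in self.dropped]
        df = table.data[keep].copy()
        for col in keep:
            df[col] = boxcox_apply(
                df[col].to_numpy(dtype=float), self.records[col], clip=True
            )
        screened = DataTable(df, {c: table.roles[c] for c in keep})
        out, _ = standardize(screened, params=self.scale_params)
        return out

    # -- serialization so a fitted transform can be reused exactly ----------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "skew_limit": self.skew_limit,
            "dropped": self.dropped,
            "records": {k: asdict(v) for k, v in self.records.items()},
            "scale_params": {k: asdict(v) for k, v in self.scale_params.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransformPipeline":
        payload = json.loads(Path(path).read_text())
        pipe = cls(skew_limit=payload["skew_limit"])
        pipe.records = {
            k: TransformRecord(**v) for k, v in payload["records"].items()
        }
        pipe.dropped = payload["dropped"]
        pipe.scale_params = {
            k: StandardizeRecord(**v) for k, v in payload["scale_params"].items()
        }
        pipe._fitted = True
        return pipe
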