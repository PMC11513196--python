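"""Per-subject ERP quantification: amplitude, latency, variability, reliability.

The component of interest is a response-locked negative deflection quantified
as the mean amplitude inside a fixed post-response window (0-100 ms for the
error- and correct-related negativities).  Component latency is measured as
fractional-area latency; reliability as a generalizability-theory
dependability coefficient; subjects with too few trials or unreliable signals
are excluded.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EpochSet

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (0.0, 100.0)  # ms post-response
MIN_TRIALS = 5
MIN_DEPENDABILITY = 0.70


@dataclass
class ErpMetrics:
    """One subject's windowed ERP summary."""

    subject_id: str
    mean_amplitude: float  # microvolts
    latency: float  # ms; NaN when undefined (zero component area)
    n_trials: int
    within_sd: float  # microvolts; NaN with a single trial
    dependability: float  # in [0, 1]


class EmptyTrialSetError(ValueError):
    """Subject has no trials; the subject must be excluded upstream."""


def trial_amplitudes(epochs: EpochSet, window: tuple[float, float] = DEFAULT_WINDOW) -> list[np.ndarray]:
    """Per-subject vectors of trial-level windowed mean amplitudes."""
    mask = epochs.window_mask(window)
    out = []
    for sid, ep in zip(epochs.subject_ids, epochs.epochs):
        if ep.shape[0] == 0:
            raise EmptyTrialSetError(f"subject {sid} has no trials")
        out.append(ep[:, mask].mean(axis=1))
    return out


def mean_amplitude(epochs: EpochSet, window: tuple[float, float] = DEFAULT_WINDOW) -> pd.Series:
    """Subject-level mean windowed amplitude (mean over trials of trial means)."""
    per_trial = trial_amplitudes(epochs, window)
    return pd.Series(
        [float(t.mean()) for t in per_trial], index=epochs.subject_ids, name="mean_amplitude"
    )


def fractional_area_latency(
    waveform: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    fraction: float = 0.5,
    polarity: str = "negative",
) -> float:
    """Earliest time at which `fraction` of the rectified area has accumulated.

    Only samples matching the declared polarity contribute to the area
    (rectification), so a negative component's positive overshoot does not
    shift the latency.  The cumulative trapezoid area is interpolated linearly
    between samples.  Returns NaN (and logs) when the windowed area is zero.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    waveform = np.asarray(waveform, dtype=float)
    times = np.asarray(times, dtype=float)
    lo, hi = window
    if lo < times[0] or hi > times[-1]:
        raise ValueError(f"window {window} outside the time axis")
    mask = (times >= lo) & (times <= hi)
    t = times[mask]
    x = waveform[mask]
    rect = np.maximum(-x, 0.0) if polarity == "negative" else np.maximum(x, 0.0)
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    # cumulative trapezoid area at each sample
    seg = 0.5 * (rect[1:] + rect[:-1]) * np.diff(t)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        logger.info("zero rectified area in window %s; latency undefined", window)
        return float("nan")
    target = fraction * total
    k = int(np.searchsorted(cum, target))
    if k == 0:
        return float(t[0])
    frac_seg = (target - cum[k - 1]) / (cum[k] - cum[k - 1])
    return float(t[k - 1] + frac_seg * (t[k] - t[k - 1]))


def subject_latencies(
    epochs: EpochSet,
    window: tuple[float, float] = DEFAULT_WINDOW,
    fraction: float = 0.5,
    polarity: str = "negative",
) -> pd.Series:
    """Fractional-area latency of each subject's trial-average waveform."""
    vals = []
    for ep in epochs.epochs:
        avg = ep.mean(axis=0)
        vals.append(fractional_area_latency(avg, epochs.times, window, fraction, polarity))
    return pd.Series(vals, index=epochs.subject_ids, name="latency")


def trial_variability(
    epochs: EpochSet, window: tuple[float, float] = DEFAULT_WINDOW
) -> tuple[pd.Series, float]:
    """Within-subject SD of trial amplitudes, and between-subject SD of means.

    Within-SD is NaN for single-trial subjects; both use the sample (n-1) SD.
    """
    per_trial = trial_amplitudes(epochs, window)
    within = pd.Series(
        [float(t.std(ddof=1)) if len(t) >= 2 else float("nan") for t in per_trial],
        index=epochs.subject_ids,
        name="within_sd",
    )
    means = np.array([t.mean() for t in per_trial])
    between = float(means.std(ddof=1)) if len(means) >= 2 else float("nan")
    return within, between


def dependability(
    epochs: EpochSet, window: tuple[float, float] = DEFAULT_WINDOW
) -> pd.Series:
    """Subject-level dependability of the windowed mean amplitude.

    One-way random-effects variance decomposition: the between-subject
    variance sigma2_b is the variance of subject means minus the mean
    error-variance contribution (sigma2_wi / n_i); each subject's coefficient
    is sigma2_b / (sigma2_b + sigma2_wi / n_i), clipped to [0, 1] — the
    reliability of that subject's n_i-trial average.
    """
    per_trial = trial_amplitudes(epochs, window)
    for sid, t in zip(epochs.subject_ids, per_trial):
        if len(t) < 2:
            raise ValueError(f"subject {sid}: need >= 2 trials for dependability")
    means = np.array([t.mean() for t in per_trial])
    n_i = np.array([len(t) for t in per_trial], dtype=float)
    s2_wi = np.array([t.var(ddof=1) for t in per_trial])
    s2_b = means.var(ddof=1) - float(np.mean(s2_wi / n_i))
    if s2_b <= 0:
        warnings.warn("non-positive between-subject variance estimate; dependability set to 0")
        return pd.Series(0.0, index=epochs.subject_ids, name="dependability")
    dep = s2_b / (s2_b + s2_wi / n_i)
    return pd.Series(np.clip(dep, 0.0, 1.0), index=epochs.subject_ids, name="dependability")


def compute_metrics(
    epochs: EpochSet,
    window: tuple[float, float] = DEFAULT_WINDOW,
    fraction: float = 0.5,
    polarity: str = "negative",
) -> list[ErpMetrics]:
    """Full per-subject metric set for one epoch collection."""
    amp = mean_amplitude(epochs, window)
    lat = subject_latencies(epochs, window, fraction, polarity)
    within, _between = trial_variability(epochs, window)
    dep = dependability(epochs, window)
    counts = epochs.n_trials()
    return [
        ErpMetrics(
            subject_id=sid,
            mean_amplitude=float(amp[sid]),
            latency=float(lat[sid]),
            n_trials=counts[sid],
            within_sd=float(within[sid]),
            dependability=float(dep[sid]),
        )
        for sid in epochs.subject_ids
    ]


def apply_exclusions(
    metrics: list[ErpMetrics],
    min_trials: int = MIN_TRIALS,
    min_dependability: float = MIN_DEPENDABILITY,
) -> tuple[list[ErpMetrics], list[dict]]:
    """Drop subjects with too few trials or unreliable signal.

    Both rules are strict inequalities — fewer than ``min_trials`` trials, or
    dependability lower than ``min_dependability`` — so subjects exactly at a
    boundary are kept.
    """
    kept, log = [], []
    for m in metrics:
        if m.n_trials < min_trials:
            log.append(
                {"subject_id": m.subject_id, "rule": "min_trials", "value": m.n_trials}
            )
        elif m.dependability < min_dependability:
            log.append(
                {
                    "subject_id": m.subject_id,
                    "rule": "min_dependability",
                    "value": m.dependability,
                }
            )
        else:
            kept.append(m)
    return kept, log


def metrics_frame(metrics: list[ErpMetrics]) -> pd.DataFrame:
    cols = ["subject_id", "mean_amplitude", "latency", "n_trials", "within_sd",
            "dependability"]
    return pd.DataFrame([asdict(m) for m in metrics], columns=cols).set_index("subject_id")


def write_metrics(
    metrics: list[ErpMetrics], csv_path: str | Path, exclusion_log: list[dict] | None = None
) -> None:
    """Metrics table as CSV; exclusion log as JSON lines next to it."""
    csv_path = Path(csv_path)
    metrics_frame(metrics).to_csv(csv_path)
    if exclusion_log is not None:
        log_path = csv_path.with_suffix(".exclusions.jsonl")
        log_path.write_text("".join(json.dumps(e) + "\n" for e in exclusion_log))
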