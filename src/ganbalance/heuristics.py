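"""Automated training-control heuristics for Wasserstein critic loss traces.

Critic losses are sampled every ``rate_save`` epochs during training.  The
functions here post-process such traces to (a) discard the divergent tail,
(b) score oscillation amplitude (instability) and net decline (speed),
(c) pick learning rates for the two-phase schedule, and (d) pick a stopping
epoch as the knee of a fitted exponential decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LossTrace", "truncate_trace", "instability_score", "speed_score",
    "select_lr1", "select_lr2", "select_epoch",
]


@dataclass
class LossTrace:
    """Per-epoch critic/generator losses sampled at regular intervals."""

    epochs: np.ndarray
    critic_loss: np.ndarray
    generator_loss: np.ndarray = None

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=int)
        self.critic_loss = np.asarray(self.critic_loss, dtype=float)
        if self.generator_loss is None:
            self.generator_loss = np.zeros_like(self.critic_loss)
        self.generator_loss = np.asarray(self.generator_loss, dtype=float)
        if not (len(self.epochs) == len(self.critic_loss) == len(self.generator_loss)):
            raise ValueError("epochs and loss series must have equal length")
        if len(self.epochs) > 1 and np.any(np.diff(self.epochs) <= 0):
            raise ValueError("epochs must be strictly increasing")

    def __len__(self) -> int:
        return len(self.epochs)

    def slice(self, idx) -> "LossTrace":
        return LossTrace(self.epochs[idx], self.critic_loss[idx],
                         self.generator_loss[idx])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"epoch": self.epochs,
                             "critic_loss": self.critic_loss,
                             "generator_loss": self.generator_loss})


def truncate_trace(trace: LossTrace, upper: float = 15.0,
                   lower: float = -10.0) -> LossTrace:
    """Keep the prefix strictly before the first out-of-bounds critic loss.

    The offending entry itself is dropped (it is already out of bounds).
    """
    if upper <= lower:
        raise ValueError("upper bound must exceed lower bound")
    bad = (trace.critic_loss > upper) | (trace.critic_loss < lower)
    if not bad.any():
        return trace
    return trace.slice(slice(0, int(np.argmax(bad))))


def _apex_values(series: np.ndarray) -> np.ndarray:
    """Values of the local extrema of a series, endpoints included.

    Plateaus are collapsed to a single point first, so a flat stretch
    contributes at most one apex.
    """
    if len(series) == 0:
        return np.array([])
    keep = np.concatenate([[True], np.diff(series) != 0.0])
    s = series[keep]
    if len(s) < 3:
        return s  # endpoints only (or fewer)
    d = np.sign(np.diff(s))
    interior = d[:-1] != d[1:]
    mask = np.concatenate([[True], interior, [True]])
    return s[mask]


def instability_score(trace: LossTrace, top_k: int = 50) -> float:
    """Mean of the ``top_k`` greatest absolute differences between
    consecutive apexes of the critic-loss series (oscillation amplitude)."""
    apexes = _apex_values(trace.critic_loss)
    if len(apexes) < 2:
        return 0.0
    diffs = np.abs(np.diff(apexes))
    top = np.sort(diffs)[::-1][:top_k]
    return float(top.mean())


def speed_score(trace: LossTrace, window: int = 500) -> float:
    """Mean critic loss over the first ``window`` epochs minus the mean over
    the last ``window`` epochs (positive = the loss came down)."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    span = int(trace.epochs[-1] - trace.epochs[0])
    if span < 2 * window:
        raise ValueError(
            f"trace spans {span} epochs; needs >= {2 * window} for window {window}")
    first = trace.critic_loss[trace.epochs < trace.epochs[0] + window]
    last = trace.critic_loss[trace.epochs > trace.epochs[-1] - window]
    return float(first.mean() - last.mean())


def _safe_speed(trace: LossTrace, window: int) -> float:
    span = int(trace.epochs[-1] - trace.epochs[0]) if len(trace) else 0
    if span < 2 * window:
        reduced = max(span // 2, 1)
        warnings.warn(f"trace too short for speed window {window}; using {reduced}")
        window = reduced
    return speed_score(trace, window)


def select_lr1(candidate_traces: dict, floor: float = 3.0) -> float:
    """First-phase learning rate: smallest critic loss that is still above
    ``floor``.  Candidates that never exceed the floor are ineligible unless
    every candidate is, in which case the smallest final loss wins."""
    if not candidate_traces:
        raise ValueError("no candidate traces")
    best_lr, best_val = None, np.inf
    for lr in sorted(candidate_traces):
        trace = candidate_traces[lr]
        above = trace.critic_loss[trace.critic_loss > floor]
        if len(above) == 0:
            continue
        val = float(above.min())
        if val < best_val:
            best_lr, best_val = lr, val
    if best_lr is None:
        warnings.warn("no lr_1 candidate exceeded the loss floor; "
                      "falling back to smallest final critic loss")
        finals = {lr: (float(t.critic_loss[-1]) if len(t) else np.inf)
                  for lr, t in candidate_traces.items()}
        best_lr = min(sorted(finals), key=lambda lr: finals[lr])
    return best_lr


def select_lr2(candidate_traces: dict, instab_constant: float = 3.0,
               top_k: int = 50, window: int = 500,
               upper: float = 15.0, lower: float = -10.0) -> float:
    """Second-phase learning rate: argmin of
    ``instab_constant * instability - speed`` over truncated traces.
    Ties resolve to the smaller learning rate."""
    if not candidate_traces:
        raise ValueError("no candidate traces")
    best_lr, best_obj = None, np.inf
    for lr in sorted(candidate_traces):
        trace = truncate_trace(candidate_traces[lr], upper, lower)
        if len(trace) == 0:
            continue
        obj = instab_constant * instability_score(trace, top_k) - _safe_speed(trace, window)
        if obj < best_obj:
            best_lr, best_obj = lr, obj
    if best_lr is None:
        raise ValueError("all candidate traces empty after truncation")
    return best_lr


def _decay(t, a, b, c):
    return a * np.exp(-b * t) + c


def _knee_index(x: np.ndarray, y: np.ndarray) -> int | None:
    """Index of maximum deviation from the chord after min-max normalisation
    (the Kneedle criterion on a smooth curve); None when the curve is flat or
    effectively linear."""
    if len(x) < 3:
        return None
    xr = np.ptp(x)
    yr = np.ptp(y)
    if xr == 0 or yr == 0:
        return None
    xn = (x - x.min()) / xr
    yn = (y - y.min()) / yr
    chord = yn[0] + (yn[-1] - yn[0]) * xn
    dev = np.abs(yn - chord)
    # a knee shallower than 1% of the normalised range is indistinguishable
    # from a straight line (e.g. an exponential fitted to linear data)
    if dev.max() < 1e-2:
        return None
    return int(np.argmax(dev))


def select_epoch(trace: LossTrace) -> int:
    """Stopping epoch: knee of an exponential decay ``a*exp(-b*t)+c`` fitted
    to the critic-loss series.  Falls back to the epoch of minimum critic
    loss when the fit fails or the fitted curve has no knee."""
    if len(trace) < 4:
        raise ValueError("need at least 4 trace points to select an epoch")
    t = trace.epochs.astype(float)
    y = trace.critic_loss
    span = max(t[-1] - t[0], 1.0)
    ts = (t - t[0]) / span
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _decay, ts, y,
                p0=[max(y[0] - y[-1], 1e-3), 1.0, y[-1]],
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10000)
        fitted = _decay(ts, *popt)
        idx = _knee_index(ts, fitted)
    except (RuntimeError, ValueError):
        idx = None
    if idx is None:
        warnings.warn("no knee found on the fitted loss curve; "
                      "falling back to the minimum-loss epoch")
        idx = int(np.argmin(y))
    return int(trace.epochs[idx])
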