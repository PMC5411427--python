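"""Breath-by-breath respiratory-mechanics estimation.

Each breath is fitted by multiple linear least squares to the equation of
motion of the respiratory system in two nested forms:

* linear:            Paw = R_RS*V' + E_RS*V + P0
* volume-dependent:  Paw = R_RS*V' + E1_RS*V + E2_RS*V^2 + P0

From the volume-dependent fit the elastance nonlinearity index is

    %E2 = 100 * E2*V_T / (E1 + E2*V_T),

the volume-dependent share of the total tidal elastance. %E2 near zero
means linear behaviour; large positive values indicate overdistension and
negative values tidal recruitment, so negative E2 estimates are reported,
never clipped.

Fits use the full cycle (inspiration + expiration) by default; an
inspiratory-only span is available. Window summaries average the last 30 s
of breaths, one value per animal per time point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    IllConditionedFitError,
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedIndexError,
    UnidentifiableFitError,
)
from .lung_sim import BreathCycle, Recording

__all__ = [
    "FitResult",
    "WindowSummary",
    "segment_breaths",
    "fit_linear_eom",
    "fit_volume_dependent_eom",
    "percent_e2",
    "summarize_window",
    "fits_to_frame",
]

MAX_CONDITION = 1e8


@dataclass(frozen=True)
class FitResult:
    breath_index: int
    model: str                      # "linear" | "volume_dependent"
    r_rs: float
    p0: float
    rms_residual: float
    vt_measured: float
    e_rs: float | None = None       # linear model
    e1_rs: float | None = None      # volume-dependent model
    e2_rs: float | None = None
    pct_e2: float | None = None


@dataclass(frozen=True)
class WindowSummary:
    label: str
    n_breaths: int
    params: dict            # name -> (mean, sd)
    negative_e2_fraction: float = 0.0
    flagged: bool = False   # True when >20% of breaths have e2 < 0


def percent_e2(e1: float, e2: float, vt: float) -> float:
    """Nonlinearity index 100*E2*V_T/(E1 + E2*V_T); negative when E2 < 0."""
    denom = e1 + e2 * vt
    if denom == 0:
        raise UndefinedIndexError("total tidal elastance is zero")
    return 100.0 * e2 * vt / denom


def segment_breaths(rec, rr: float | None = None) -> list[BreathCycle]:
    """Split a recording into breath cycles at inspiratory-flow onset.

    Accepts a Recording or a waveform DataFrame (time_s, flow_ml_s,
    volume_ml, paw_cmh2o). Onsets are upward crossings of a positive flow
    threshold (5% of the median positive flow, a scale robust to the wide
    breath-to-breath flow range of variable ventilation), armed only after
    flow has returned below zero (hysteresis); candidate cycles shorter
    than a quarter of the nominal cycle duration are merged forward.
    Leading samples before the first onset and a trailing fragment shorter
    than half the median cycle are discarded; each cycle's volume and time
    are re-zeroed at its boundary.
    """
    if isinstance(rec, Recording):
        df = rec.to_frame()
        if rr is None:
            rr = rec.settings.rr
    else:
        df = rec
    time = df["time_s"].to_numpy()
    flow = df["flow_ml_s"].to_numpy()
    volume = df["volume_ml"].to_numpy()
    paw = df["paw_cmh2o"].to_numpy()
    if len(time) < 2:
        warnings.warn("recording too short to segment")
        return []

    dt = float(np.median(np.diff(time)))
    positive = flow[flow > 0]
    if positive.size == 0:
        warnings.warn("no flow activity detected")
        return []
    thr = 0.05 * float(np.median(positive))

    onsets: list[int] = []
    armed = True
    for i in range(len(flow)):
        if armed and flow[i] >= thr and (i == 0 or flow[i - 1] < thr):
            onsets.append(i)
            armed = False
        elif not armed and flow[i] < 0:
            armed = True
    if not onsets:
        warnings.warn("no inspiratory onsets detected")
        return []

    # merge onsets closer than a quarter cycle
    min_sep = 0.25 * (60.0 / rr) / dt if rr else 0.0
    merged = [onsets[0]]
    for o in onsets[1:]:
        if o - merged[-1] >= min_sep:
            merged.append(o)
    bounds = merged + [len(flow)]

    lengths = np.diff(bounds)
    median_len = float(np.median(lengths[:-1])) if len(lengths) > 1 else float(lengths[0])
    cycles: list[BreathCycle] = []
    for k in range(len(bounds) - 1):
        i0, i1 = bounds[k], bounds[k + 1]
        if k == len(bounds) - 2 and (i1 - i0) < 0.5 * median_len:
            break  # trailing partial cycle
        v = volume[i0:i1] - volume[i0]
        cycles.append(
            BreathCycle(
                time=time[i0:i1] - time[i0],
                flow=flow[i0:i1].copy(),
                volume=v,
                paw=paw[i0:i1].copy(),
                insp_end_index=int(np.argmax(v)),
            )
        )
    return cycles


def _select_span(cycle: BreathCycle, span: str):
    if span == "inspiratory":
        sl = slice(0, cycle.insp_end_index + 1)
    elif span == "full_cycle":
        sl = slice(None)
    else:
        raise InvalidArgumentError(f"unknown fit span {span!r}")
    return cycle.flow[sl], cycle.volume[sl], cycle.paw[sl]


def _lstsq(design: np.ndarray, y: np.ndarray, breath_index: int):
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise IllConditionedFitError(
            f"breath {breath_index}: design condition number {cond:.3g} exceeds {MAX_CONDITION:.0e}"
        )
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(np.sqrt(np.mean(resid**2)))


def fit_linear_eom(
    cycle: BreathCycle, breath_index: int = 0, span: str = "full_cycle"
) -> FitResult:
    """Least-squares fit of Paw against [flow, volume, 1]."""
    flow, volume, paw = _select_span(cycle, span)
    if len(paw) < 10:
        raise InvalidArgumentError("cycle must have at least 10 samples")
    design = np.column_stack([flow, volume, np.ones_like(flow)])
    coef, rms = _lstsq(design, paw, breath_index)
    return FitResult(
        breath_index=breath_index,
        model="linear",
        r_rs=float(coef[0]),
        e_rs=float(coef[1]),
        p0=float(coef[2]),
        rms_residual=rms,
        vt_measured=float(np.max(cycle.volume)),
    )


def fit_volume_dependent_eom(
    cycle: BreathCycle, breath_index: int = 0, span: str = "full_cycle"
) -> FitResult:
    """Least-squares fit of Paw against [flow, volume, volume^2, 1] with %E2."""
    flow, volume, paw = _select_span(cycle, span)
    if len(paw) < 10:
        raise InvalidArgumentError("cycle must have at least 10 samples")
    vt = float(np.max(cycle.volume))
    if vt <= 0 or (np.max(volume) - np.min(volume)) < 0.5 * vt:
        raise UnidentifiableFitError(
            f"breath {breath_index}: volume excursion below half the tidal volume; E2 unidentifiable"
        )
    design = np.column_stack([flow, volume, volume**2, np.ones_like(flow)])
    coef, rms = _lstsq(design, paw, breath_index)
    e1, e2 = float(coef[1]), float(coef[2])
    denom = e1 + e2 * vt
    pct = percent_e2(e1, e2, vt) if denom != 0 else math.nan
    return FitResult(
        breath_index=breath_index,
        model="volume_dependent",
        r_rs=float(coef[0]),
        e1_rs=e1,
        e2_rs=e2,
        p0=float(coef[3]),
        pct_e2=pct,
        rms_residual=rms,
        vt_measured=vt,
    )


def summarize_window(
    fits: list[FitResult],
    label: str,
    window_last_s: float | None = 30.0,
    breath_duration_s: float | None = None,
) -> WindowSummary:
    """Mean +/- SD of fitted parameters over the last ``window_last_s`` of breaths.

    When ``breath_duration_s`` is given the last ceil(window/duration)
    breaths are used; otherwise all fits enter the summary. Windows where
    more than 20% of breaths have E2 < 0 are flagged (tidal recruitment).
    """
    if not fits:
        raise InsufficientDataError("no fits to summarize")
    if window_last_s is not None and breath_duration_s is not None:
        k = max(1, math.ceil(window_last_s / breath_duration_s))
        fits = fits[-k:]

    fields = ["r_rs", "e_rs", "e1_rs", "e2_rs", "p0", "pct_e2", "vt_measured", "rms_residual"]
    params = {}
    for name in fields:
        vals = np.array([getattr(f, name) for f in fits if getattr(f, name) is not None], dtype=float)
        if vals.size:
            params[name] = (float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
    e2_vals = np.array([f.e2_rs for f in fits if f.e2_rs is not None], dtype=float)
    neg_frac = float(np.mean(e2_vals < 0)) if e2_vals.size else 0.0
    return WindowSummary(
        label=label,
        n_breaths=len(fits),
        params=params,
        negative_e2_fraction=neg_frac,
        flagged=neg_frac > 0.20,
    )


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    """Tidy per-breath fit table, one row per breath per model."""
    return pd.DataFrame([f.__dict__ for f in fits])
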