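"""Single-compartment lung simulator with volume-dependent elastance.

The model is the classic equation of motion of the respiratory system,

    Paw(t) = R_RS * V'(t) + [E1_RS + E2_RS * V(t)] * V(t) + P0,

where airway pressure Paw is in cmH2O, flow V' in mL/s, volume V in mL above
the end-expiratory level, R_RS is resistance (cmH2O.s/mL), E1_RS the
volume-independent elastance (cmH2O/mL), E2_RS the volume-dependent
elastance (cmH2O/mL^2) and P0 the airway pressure at end-expiration
(absorbing PEEP).

Inspiration is a square (constant-flow) profile, the standard for rodent
volume-controlled ventilation; expiration is passive relaxation of the
compartment against R_RS and the total elastance, integrated on the
sampling grid (implicit trapezoidal steps at 1/fs, so the stored volume is
exactly the trapezoidal running integral of the stored flow). A one-sample
zero-flow instant marks the inspiration/expiration switch. Signals are
sampled at 200 Hz by default, the acquisition rate of small-animal
ventilator rigs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .vt_pattern import VTSequence

__all__ = [
    "VentSettings",
    "MechParams",
    "BreathCycle",
    "Recording",
    "airway_pressure",
    "simulate_breath",
    "simulate_run",
    "write_recording_csv",
    "read_recording_csv",
]


@dataclass(frozen=True)
class VentSettings:
    """Ventilator settings. ie_ratio is inspiratory:expiratory time (1:2 -> 0.5)."""

    vt_nominal: float = 6.0      # mL/kg
    body_weight: float = 0.526   # kg
    rr: float = 40.0             # breaths/min
    peep: float = 2.0            # cmH2O
    fio2: float = 0.4
    ie_ratio: float = 0.5
    fs: float = 200.0            # Hz

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise InvalidArgumentError("rr must be positive")
        if not (0 < self.fio2 <= 1):
            raise InvalidArgumentError("fio2 must lie in (0, 1]")
        if self.ie_ratio <= 0:
            raise InvalidArgumentError("ie_ratio must be positive")
        if self.fs < 4 * self.rr / 60.0:
            raise InvalidArgumentError("fs too low for the respiratory rate")

    @property
    def cycle_duration(self) -> float:
        return 60.0 / self.rr

    @property
    def insp_duration(self) -> float:
        return self.cycle_duration * self.ie_ratio / (1.0 + self.ie_ratio)


@dataclass(frozen=True)
class MechParams:
    """Single-compartment mechanics: R_RS, E1_RS, E2_RS, P0."""

    r_rs: float
    e1_rs: float
    e2_rs: float = 0.0
    p0: float = 0.0

    def __post_init__(self) -> None:
        if self.r_rs <= 0:
            raise InvalidArgumentError("r_rs must be positive")

    def total_elastance(self, volume: float) -> float:
        """Tidal elastance E1 + E2*V at the given volume (cmH2O/mL)."""
        return self.e1_rs + self.e2_rs * volume

    def check_positive_elastance(self, vt: float) -> None:
        v = np.linspace(0.0, vt, 32)
        if np.any(self.e1_rs + self.e2_rs * v <= 0):
            raise InvalidArgumentError("total elastance non-positive over the tidal range")


def airway_pressure(params: MechParams, flow, volume):
    """Pointwise equation of motion: R*V' + (E1 + E2*V)*V + P0."""
    flow = np.asarray(flow, dtype=float)
    volume = np.asarray(volume, dtype=float)
    return params.r_rs * flow + (params.e1_rs + params.e2_rs * volume) * volume + params.p0


@dataclass
class BreathCycle:
    """One sampled breath: uniform time grid, flow, volume and Paw."""

    time: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    paw: np.ndarray
    insp_end_index: int
    vt_delivered: float | None = None
    incomplete_exhalation: bool = False
    truth: MechParams | None = None

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass
class Recording:
    """An ordered run of breaths with settings, optional truth and seeds."""

    cycles: list[BreathCycle]
    settings: VentSettings
    truth: list[MechParams] | None = None   # per-breath ground truth
    noise_sd: float = 0.0
    seed: int = 0
    delivered_vt: np.ndarray | None = None  # mL, per breath

    @property
    def n_breaths(self) -> int:
        return len(self.cycles)

    def to_frame(self) -> pd.DataFrame:
        """Concatenate cycles into the standard waveform table."""
        frames = []
        t0 = 0.0
        for i, c in enumerate(self.cycles):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": c.time + t0,
                        "flow_ml_s": c.flow,
                        "volume_ml": c.volume,
                        "paw_cmh2o": c.paw,
                        "breath_index": i,
                    }
                )
            )
            t0 += c.time[-1] + 1.0 / self.settings.fs
        return pd.concat(frames, ignore_index=True)

    def regenerate_paw(self, breath_index: int) -> np.ndarray:
        """Noiseless Paw rebuilt from stored flow/volume and truth params."""
        if self.truth is None:
            raise InvalidArgumentError("recording carries no ground-truth parameters")
        c = self.cycles[breath_index]
        return airway_pressure(self.truth[breath_index], c.flow, c.volume)


def simulate_breath(params: MechParams, settings: VentSettings, vt: float) -> BreathCycle:
    """Simulate one breath at tidal volume ``vt`` (mL/kg).

    Constant inspiratory flow delivers vt*body_weight mL over the
    inspiratory time; expiration relaxes passively with flow
    -(E1*V + E2*V^2)/R, stepped implicitly (trapezoidal) at 1/fs so the
    stored volume equals the trapezoidal integral of the stored flow to
    machine precision. Paw is evaluated pointwise from the equation of
    motion. If the end-expiratory volume has not fallen below 1% of the
    delivered volume by cycle end the cycle is flagged, mirroring
    incomplete exhalation.
    """
    if vt <= 0:
        raise InvalidArgumentError("vt must be positive")
    vd = vt * settings.body_weight  # delivered volume, mL
    params.check_positive_elastance(vd)

    fs = settings.fs
    dt = 1.0 / fs
    n = int(round(settings.cycle_duration * fs))
    n_insp = int(round(settings.insp_duration * fs))
    if n_insp < 2 or n - n_insp < 2:
        raise InvalidArgumentError("sampling too coarse for the breath phases")

    flow = np.zeros(n)
    volume = np.zeros(n)

    # square inspiratory flow over samples [0, n_insp); sample n_insp is the
    # zero-flow switch instant, so the trapezoid over inspiration is
    # F*dt*(n_insp - 1/2) and F is chosen to deliver vd exactly
    f_insp = vd / (dt * (n_insp - 0.5))
    flow[:n_insp] = f_insp
    flow[n_insp] = 0.0
    volume[1:n_insp] = f_insp * dt * np.arange(1, n_insp)
    volume[n_insp] = vd

    # passive expiration: implicit trapezoidal step of dV/dt = -(e1 V + e2 V^2)/r
    r, e1, e2 = params.r_rs, params.e1_rs, params.e2_rs
    a = dt * e2 / (2.0 * r)
    b = 1.0 + dt * e1 / (2.0 * r)
    v = vd
    f = 0.0
    for i in range(n_insp + 1, n):
        rhs = v + 0.5 * dt * f
        if e2 == 0.0:
            v_new = rhs / b
        else:
            disc = b * b + 4.0 * a * rhs
            if disc < 0:
                raise InvalidArgumentError("expiratory step lost positivity (check E1/E2)")
            v_new = (-b + np.sqrt(disc)) / (2.0 * a)
        f_new = -(e1 * v_new + e2 * v_new * v_new) / r
        volume[i] = v_new
        flow[i] = f_new
        v, f = v_new, f_new

    time = np.arange(n) * dt
    paw = airway_pressure(params, flow, volume)
    return BreathCycle(
        time=time,
        flow=flow,
        volume=volume,
        paw=np.asarray(paw),
        insp_end_index=n_insp,
        vt_delivered=vd,
        incomplete_exhalation=bool(volume[-1] > 0.01 * vd),
        truth=params,
    )


def _expand_timeline(
    params_timeline, duration: int
) -> list[MechParams]:
    """Accept a single MechParams or [(n_breaths, MechParams), ...]."""
    if isinstance(params_timeline, MechParams):
        return [params_timeline] * duration
    out: list[MechParams] = []
    for n_b, p in params_timeline:
        out.extend([p] * int(n_b))
    if len(out) < duration:
        out.extend([out[-1]] * (duration - len(out)))
    return out[:duration]


def simulate_run(
    params_timeline,
    settings: VentSettings,
    vt_source,
    duration: int,
    noise_sd: float = 0.2,
    delivery_cv: float = 0.0,
    seed: int = 0,
) -> Recording:
    """Simulate ``duration`` breaths.

    ``vt_source`` is a VTSequence (VV; cycled from the start if the run is
    longer than the pattern) or a constant in mL/kg (VCV). Per-breath
    delivered V_T optionally receives multiplicative Gaussian delivery noise
    of CV ``delivery_cv`` percent; additive Gaussian noise of SD
    ``noise_sd`` cmH2O is applied to Paw only (flow and volume are
    ventilator-commanded). Mechanics may change between scheduled segments
    but are constant within a breath.
    """
    if duration < 1:
        raise InvalidArgumentError("duration must be >= 1")
    if isinstance(vt_source, VTSequence):
        base_vt = np.asarray(vt_source.values)
    elif np.isscalar(vt_source):
        base_vt = np.array([float(vt_source)])
    else:
        base_vt = np.asarray(vt_source, dtype=float)
    if base_vt.size == 0:
        raise InvalidArgumentError("empty vt_source")

    params_per_breath = _expand_timeline(params_timeline, duration)
    rng = np.random.default_rng(seed)
    vts = base_vt[np.arange(duration) % base_vt.size].copy()
    if delivery_cv > 0:
        vts *= 1.0 + rng.normal(0.0, delivery_cv / 100.0, size=duration)

    cycles: list[BreathCycle] = []
    delivered = np.empty(duration)
    for i in range(duration):
        c = simulate_breath(params_per_breath[i], settings, vts[i])
        if noise_sd > 0:
            c.paw = c.paw + rng.normal(0.0, noise_sd, size=c.n_samples)
        delivered[i] = c.vt_delivered
        cycles.append(c)
    return Recording(
        cycles=cycles,
        settings=settings,
        truth=params_per_breath,
        noise_sd=float(noise_sd),
        seed=int(seed),
        delivered_vt=delivered,
    )


def write_recording_csv(rec: Recording, path) -> None:
    """Waveform CSV plus a ``<path>.meta`` key=value sidecar."""
    rec.to_frame().to_csv(path, index=False)
    s = rec.settings
    with open(f"{path}.meta", "w") as fh:
        for k, v in (
            ("vt_nominal", s.vt_nominal),
            ("body_weight", s.body_weight),
            ("rr", s.rr),
            ("peep", s.peep),
            ("fio2", s.fio2),
            ("ie_ratio", s.ie_ratio),
            ("fs", s.fs),
            ("noise_sd", rec.noise_sd),
            ("seed", rec.seed),
            ("n_breaths", rec.n_breaths),
        ):
            fh.write(f"{k}={v}\n")


def read_recording_csv(path) -> pd.DataFrame:
    """Read any waveform CSV with the four named signal columns."""
    df = pd.read_csv(path, comment="#")
    required = {"time_s", "flow_ml_s", "volume_ml", "paw_cmh2o"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"waveform CSV missing columns: {sorted(missing)}")
    return df
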