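"""Variable-ventilation tidal-volume pattern generation.

Variable ventilation (VV) delivers a different tidal volume (V_T) on every
breath, drawn from a Gaussian distribution around the protective setting
(6 mL/kg) with a prescribed coefficient of variation (CV, typically 30%).
This module generates, normalizes, characterizes and serializes such
sequences.

Draws falling outside mean +/- 3 SD (or at/below zero) are rejected and
redrawn, which keeps every delivered volume physiological; the truncation
shrinks the realized SD of a raw sequence by a factor of ~0.9866 at +/-3 SD.
With ``normalize=True`` (the default) the finished sequence is affinely
rescaled so that its sample mean and sample CV (n-1 convention) hit the
nominal values exactly, mimicking a ventilator that replays a stored,
calibrated pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "VTSequence",
    "SequenceStats",
    "generate_vt_sequence",
    "sequence_stats",
    "write_sequence_csv",
    "read_sequence_csv",
]


@dataclass(frozen=True)
class VTSequence:
    """An ordered tidal-volume pattern in mL/kg with generation metadata."""

    values: np.ndarray
    nominal_mean: float
    nominal_cv: float
    n: int
    seed: int
    truncation_bounds: tuple[float, float]
    normalized: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        self.validate()

    def validate(self) -> None:
        lo, hi = self.truncation_bounds
        v = self.values
        if len(v) != self.n:
            raise InvalidArgumentError(f"sequence length {len(v)} != n {self.n}")
        if np.any(v <= 0):
            raise InvalidArgumentError("tidal volumes must be positive")
        # numerical slack for the affine normalization map
        tol = 1e-9 * max(abs(lo), abs(hi), 1.0)
        if np.any(v < lo - tol) or np.any(v > hi + tol):
            raise InvalidArgumentError("values outside truncation bounds")
        if self.normalized and self.n >= 2:
            s = sequence_stats(self)
            if abs(s.mean - self.nominal_mean) > 1e-9 or abs(s.cv - self.nominal_cv) > 1e-9:
                raise InvalidArgumentError("normalized sequence does not match nominal moments")

    def __len__(self) -> int:
        return self.n

    def stats(self) -> "SequenceStats":
        return sequence_stats(self)


@dataclass(frozen=True)
class SequenceStats:
    mean: float
    sd: float
    cv: float
    min: float
    max: float
    n: int


def generate_vt_sequence(
    nominal_mean: float = 6.0,
    nominal_cv: float = 30.0,
    n: int = 1200,
    seed: int = 0,
    normalize: bool = True,
) -> VTSequence:
    """Generate a Gaussian V_T pattern with rejection at mean +/- 3 SD.

    Parameters
    ----------
    nominal_mean : float
        Target mean tidal volume, mL/kg.
    nominal_cv : float
        Target coefficient of variation, percent (0 <= cv < 100).
    n : int
        Number of breaths in the pattern.
    seed : int
        Seed for the sequence's private generator; identical seed and
        parameters reproduce the sequence bit for bit.
    normalize : bool
        Affinely rescale the finished draw so sample mean and sample CV
        (n-1 convention) equal the nominals exactly.
    """
    if nominal_mean <= 0:
        raise InvalidArgumentError("nominal_mean must be positive")
    if not (0 <= nominal_cv < 100):
        raise InvalidArgumentError("nominal_cv must lie in [0, 100)")
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")

    sd = nominal_mean * nominal_cv / 100.0
    lo = nominal_mean - 3.0 * sd
    hi = nominal_mean + 3.0 * sd

    rng = np.random.default_rng(seed)
    values = rng.normal(nominal_mean, sd, size=n)
    bad = (values < lo) | (values > hi) | (values <= 0)
    while bad.any():
        values[bad] = rng.normal(nominal_mean, sd, size=int(bad.sum()))
        bad = (values < lo) | (values > hi) | (values <= 0)

    if normalize and n >= 2 and sd > 0:
        m = values.mean()
        s = values.std(ddof=1)
        scale = sd / s
        values = nominal_mean + (values - m) * scale
        # map the rejection bounds through the same affine transform so the
        # in-bounds invariant is preserved exactly
        lo = nominal_mean + (lo - m) * scale
        hi = nominal_mean + (hi - m) * scale
    elif sd == 0:
        lo = hi = nominal_mean

    return VTSequence(
        values=values,
        nominal_mean=float(nominal_mean),
        nominal_cv=float(nominal_cv),
        n=int(n),
        seed=int(seed),
        truncation_bounds=(float(lo), float(hi)),
        normalized=bool(normalize and n >= 2),
    )


def sequence_stats(seq: VTSequence | np.ndarray) -> SequenceStats:
    """Sample mean, SD, CV (100*SD/mean, n-1 convention), min and max."""
    values = seq.values if isinstance(seq, VTSequence) else np.asarray(seq, dtype=float)
    if len(values) < 2:
        raise InsufficientDataError("need at least 2 values for sample statistics")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return SequenceStats(
        mean=mean,
        sd=sd,
        cv=100.0 * sd / mean,
        min=float(values.min()),
        max=float(values.max()),
        n=len(values),
    )


def write_sequence_csv(seq: VTSequence, path) -> None:
    """Single-column CSV with a comment line carrying generation metadata."""
    with open(path, "w") as fh:
        fh.write(
            f"# nominal_mean={seq.nominal_mean} nominal_cv={seq.nominal_cv} "
            f"n={seq.n} seed={seq.seed} normalized={seq.normalized} "
            f"truncation_lo={seq.truncation_bounds[0]} "
            f"truncation_hi={seq.truncation_bounds[1]}\n"
        )
        pd.Series(seq.values, name="vt_ml_kg").to_csv(fh, index=False)


def read_sequence_csv(path) -> VTSequence:
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        values = pd.read_csv(fh)["vt_ml_kg"].to_numpy()
    return VTSequence(
        values=values,
        nominal_mean=float(meta.get("nominal_mean", values.mean())),
        nominal_cv=float(meta.get("nominal_cv", 0.0)),
        n=len(values),
        seed=int(meta.get("seed", 0)),
        truncation_bounds=(
            float(meta["truncation_lo"]) if "truncation_lo" in meta else float(values.min()),
            float(meta["truncation_hi"]) if "truncation_hi" in meta else float(values.max()),
        ),
        normalized=meta.get("normalized", "False") == "True",
    )
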