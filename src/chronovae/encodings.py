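"""Continuous sinusoidal time embedding and one-hot factor encodings.

Time is embedded transformer-style: a ladder of ``d/2`` angular frequencies
``w_i = 2*pi / 10000**(2*i/d)`` (radians per rescaled day), each contributing a
sine and a cosine coordinate.  The tunable minimum wavelength rescales time,
``t' = t / min_wavelength``, so that the fastest coordinate has period exactly
``min_wavelength`` days while the ladder shape stays fixed.  With the default
``min_wavelength = 1`` day the fastest pair repeats daily, matching a circadian
scale, and the slowest pair has period ``10000**((d-2)/d)`` days — effectively
monotone over any developmental window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TimeEncodingSpec:
    """Dimension and frequency ladder of the sinusoidal time embedding.

    Parameters
    ----------
    d : int
        Embedding dimension; must be even (each frequency yields sin + cos).
    min_wavelength : float
        Period, in days, of the fastest sinusoid.
    """

    d: int = 50
    min_wavelength: float = 1.0
    frequencies: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.d % 2 != 0 or self.d <= 0:
            raise ValueError(f"time-encoding dimension must be a positive even "
                             f"integer, got {self.d}")
        if self.min_wavelength <= 0:
            raise ValueError("min_wavelength must be positive")
        i = np.arange(self.d // 2)
        object.__setattr__(
            self, "frequencies", 2.0 * np.pi / 10000.0 ** (2.0 * i / self.d)
        )


def sinusoidal_encode(t, spec: TimeEncodingSpec) -> np.ndarray:
    """Embed time ``t`` (days; scalar or array) as a length-``d`` vector.

    Returns ``[sin(w_0 t'), cos(w_0 t'), ..., sin(w_{d/2-1} t'),
    cos(w_{d/2-1} t')]`` with ``t' = t / min_wavelength``; every entry lies in
    ``[-1, 1]``.  For array input the encoding is stacked along the last axis.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    phase = t[..., None] / spec.min_wavelength * spec.frequencies
    out = np.empty(t.shape + (spec.d,))
    out[..., 0::2] = np.sin(phase)
    out[..., 1::2] = np.cos(phase)
    return out


@dataclass(frozen=True)
class FactorEncoding:
    """One-hot encoding of a discrete factor (condition, batch, ...)."""

    levels: tuple

    @classmethod
    def from_values(cls, values) -> "FactorEncoding":
        levels = tuple(dict.fromkeys(values))  # first-appearance order
        return cls(levels=levels)

    @property
    def matrix(self) -> np.ndarray:
        return np.eye(len(self.levels))

    def encode(self, values) -> np.ndarray:
        index = {lev: i for i, lev in enumerate(self.levels)}
        try:
            rows = [index[v] for v in values]
        except KeyError as exc:
            raise ValueError(
                f"unseen factor level {exc.args[0]!r}; known levels: "
                f"{list(self.levels)}"
            ) from None
        return np.eye(len(self.levels))[rows]

    def __len__(self) -> int:
        return len(self.levels)
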