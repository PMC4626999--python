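"""Recursive first-difference derivatives of the PPG signal.

The order-i derivative is the scaled backward difference

    S_i[n] = (S_{i-1}[n] - S_{i-1}[n-1]) / T,

applied recursively up to order 20 to both the unfiltered and the
band-passed signal. Each application shortens the signal by one sample --
the difference is undefined at the first sample, and padding would inject
discontinuities that explode after 20 differentiations. The 1/T scaling
(T = 1/fs, the sampling interval) is applied at every step; it is uniform
across subjects and therefore irrelevant to rank statistics, but it keeps
the values on the scale the formula defines.

For a pure sinusoid at frequency f the per-step amplitude gain is
|2 sin(pi f / fs)| / T, which is the frequency-domain oracle the tests use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import PPGRecording

__all__ = ["DerivativeStack", "differentiate_once", "derivative_cascade"]


class NumericOverflowError(FloatingPointError):
    """Cascade produced non-finite values; message names the order reached."""


def differentiate_once(signal: np.ndarray, T: float) -> np.ndarray:
    """One backward-difference step, ``(x[k+1] - x[k]) / T``.

    Output is one sample shorter than the input.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    if T <= 0:
        raise ValueError("sampling interval T must be positive")
    return np.diff(x) / T


@dataclass
class DerivativeStack:
    """Ordered derivative family S_0..S_max for one recording.

    ``signals[i]`` has length ``len(signals[0]) - i`` and units
    input-units x s^-i.
    """

    signals: list[np.ndarray]
    fs: float
    filtered: bool
    subject_id: str = ""
    condition: str = ""
    T: float = field(init=False)

    def __post_init__(self) -> None:
        self.T = 1.0 / self.fs

    @property
    def max_order(self) -> int:
        return len(self.signals) - 1

    def __getitem__(self, order: int) -> np.ndarray:
        return self.signals[order]

    def __len__(self) -> int:
        return len(self.signals)

    def dump_csv(self, order: int, path) -> None:
        """Debug dump of S_order as a one-column CSV."""
        np.savetxt(path, self.signals[order], fmt="%.12g",
                   header=f"S_{order} fs={self.fs}", comments="# ")


def derivative_cascade(recording: PPGRecording, max_order: int = 20) -> DerivativeStack:
    """Recursively differentiate a recording up to ``max_order``.

    Raises
    ------
    NumericOverflowError
        If any order produces non-finite values (names the failing order).
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    x = np.asarray(recording.samples, dtype=float)
    if x.size <= max_order + 1:
        raise ValueError(
            f"recording too short ({x.size} samples) for order {max_order}")
    T = 1.0 / recording.fs
    signals = [x]
    for i in range(1, max_order + 1):
        x = differentiate_once(x, T)
        if not np.all(np.isfinite(x)):
            raise NumericOverflowError(
                f"non-finite values at derivative order {i}")
        signals.append(x)
    return DerivativeStack(signals=signals, fs=recording.fs,
                           filtered=recording.filtered,
                           subject_id=recording.subject_id,
                           condition=recording.condition)
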