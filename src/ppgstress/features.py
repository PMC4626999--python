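"""Whole-recording features: normalized energy and normalized Shannon entropy.

For the order-j derivative signal S_j of length N:

    E_j = (1/N) * sum S_j[n]^2
    P_j = -(1/N) * sum S_j[n]^2 * ln(S_j[n]^2)        (0 * ln 0 := 0)

"Normalized" refers to the 1/N factor; no amplitude pre-normalization is
applied by default (an optional per-recording unit-variance flag exists for
cross-device use). N is the length of the order-j signal, which shrinks by
one sample per derivative order. P_j is a signal-randomness functional, not
a probability entropy, and can be negative when squared amplitudes above 1
dominate.

The full grid per recording is 2 features x 2 filtering statuses x orders
0..20 = 84 cells.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .derivatives import DerivativeStack, derivative_cascade
from .preprocess import FilterSpec, bandpass

__all__ = [
    "energy", "entropy", "extract_features",
    "compute_feature_table", "write_feature_table", "read_feature_table",
]

FEATURES = ("energy", "entropy")
STATUSES = ("unfiltered", "filtered")


def energy(signal: np.ndarray) -> float:
    """Normalized energy: mean squared amplitude."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(np.mean(x * x))


def entropy(signal: np.ndarray) -> float:
    """Normalized Shannon entropy: -mean of S^2 ln(S^2), natural log."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    s2 = x * x
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(s2 > 0.0, s2 * np.log(s2), 0.0)
    out = -float(np.mean(terms))
    if not np.isfinite(out):
        raise FloatingPointError("entropy overflowed to a non-finite value")
    return out


def extract_features(stack_unfiltered: DerivativeStack,
                     stack_filtered: DerivativeStack) -> pd.DataFrame:
    """All 84 feature cells for one recording, as a tidy frame.

    Columns: ``feature``, ``status``, ``order``, ``value``.
    """
    rows = []
    for status, stack in (("unfiltered", stack_unfiltered),
                          ("filtered", stack_filtered)):
        for order in range(stack.max_order + 1):
            s = stack[order]
            rows.append((("energy"), status, order, energy(s)))
            rows.append((("entropy"), status, order, entropy(s)))
    return pd.DataFrame(rows, columns=["feature", "status", "order", "value"])


def compute_feature_table(dataset: CohortDataset, *,
                          filter_spec: FilterSpec | None = None,
                          max_order: int = 20,
                          unit_variance: bool = False) -> pd.DataFrame:
    """Energy/entropy grid for every recording in a cohort.

    Returns a tidy frame with columns ``subject_id``, ``condition``,
    ``feature``, ``status``, ``order``, ``value``. ``unit_variance``
    rescales each raw recording to unit standard deviation first (off by
    default; useful when amplitude calibration differs across devices).
    """
    frames = []
    for rec in dataset:
        if unit_variance:
            sd = rec.samples.std()
            rec = rec.with_samples(rec.samples / sd if sd > 0 else rec.samples)
        stack_u = derivative_cascade(rec, max_order)
        stack_f = derivative_cascade(bandpass(rec, filter_spec), max_order)
        rows = extract_features(stack_u, stack_f)
        rows.insert(0, "condition", rec.condition)
        rows.insert(0, "subject_id", rec.subject_id)
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})
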