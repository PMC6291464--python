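"""Instantaneous phase via the analytic signal, and the phase lag index (PLI).

For a pair of phase series the PLI is

    PLI = | < sign(sin(phi_a(t) - phi_b(t))) > |

with sign(0) = 0, so identical signals (zero phase difference everywhere)
give exactly 0 and a constant non-zero lag gives exactly 1.  The estimator
is insensitive to zero-lag (common-source / volume-conduction) coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "AnalyticPhaseSeries",
    "PLIMatrix",
    "analytic_phase",
    "pli_pair",
    "pli_matrix",
    "average_pli",
    "condition_average",
]


@dataclass
class AnalyticPhaseSeries:
    """Channels x samples instantaneous phases in radians, wrapped to (-pi, pi]."""

    phases: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim not in (1, 2):
            raise ValueError("phases must be 1-D or 2-D")
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases contain non-finite values")


@dataclass
class PLIMatrix:
    """Symmetric, zero-diagonal channel-pair synchronization matrix in [0, 1]."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLI matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("PLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("PLI matrix diagonal must be zero")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("PLI values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def analytic_phase(segment: np.ndarray) -> AnalyticPhaseSeries:
    """Instantaneous phase of each channel from the Hilbert analytic signal."""
    seg = np.asarray(segment, dtype=float)
    if seg.shape[-1] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(seg)):
        raise ValueError("segment contains non-finite values")
    return AnalyticPhaseSeries(np.angle(hilbert(seg, axis=-1)))


def _phases_array(phases) -> np.ndarray:
    if isinstance(phases, AnalyticPhaseSeries):
        return phases.phases
    return np.asarray(phases, dtype=float)


def pli_pair(phase_a, phase_b) -> float:
    """PLI between two equal-length phase series (sign(0) counts as 0)."""
    a = _phases_array(phase_a).ravel()
    b = _phases_array(phase_b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ValueError("need at least one sample")
    return float(np.abs(np.mean(np.sign(np.sin(a - b)))))


def pli_matrix(phases, labels: list[str] | None = None) -> PLIMatrix:
    """All-pairs PLI for a channels x samples phase array."""
    p = _phases_array(phases)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("need a 2-D phase array with >= 2 channels")
    n = p.shape[0]
    out = np.zeros((n, n))
    for i in range(n - 1):
        # sign(sin(-x)) = -sign(sin(x)), so |mean| is symmetric by construction
        rows = np.abs(np.mean(np.sign(np.sin(p[i] - p[i + 1:])), axis=-1))
        out[i, i + 1:] = rows
        out[i + 1:, i] = rows
    if labels is None:
        labels = [f"ch{i:02d}" for i in range(n)]
    return PLIMatrix(values=out, labels=list(labels))


def average_pli(matrix: PLIMatrix) -> float:
    """Mean over the n(n-1)/2 distinct node pairs (upper triangle)."""
    if matrix.n < 2:
        raise ValueError("need at least 2 nodes")
    iu = np.triu_indices(matrix.n, k=1)
    return float(matrix.values[iu].mean())


def condition_average(matrices: list[PLIMatrix]) -> PLIMatrix:
    """Entrywise mean of per-segment PLI matrices for one condition."""
    if not matrices:
        raise ValueError("cannot average an empty list of matrices")
    n = matrices[0].n
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.n != n:
            raise ValueError("inconsistent matrix sizes")
    stacked = np.stack([m.values for m in matrices])
    return PLIMatrix(values=stacked.mean(axis=0), labels=list(labels))
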