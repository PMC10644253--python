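"""Phase-locking-value (PLV) functional connectivity.

The PLV between channels x and y over a window of T samples is the modulus
of the time-averaged unit phasor of their phase difference,

    PLV = | (1/T) sum_t exp(i (phi_x(t) - phi_y(t))) |  in [0, 1],

where phases come from the analytic signal (Hilbert transform) of each
channel. 1 means strict phase coupling, values near 0 mean independent
phases. All n(n-1)/2 channel pairs form a symmetric matrix with unit
diagonal, which is then sparsified by a threshold or a target edge density.

Phase extraction is broadband by default: the raw (mean-removed) window is
analytically extended without any band-pass, matching a pipeline that uses
unpreprocessed data. A band-limit can be applied upstream via
``windowing.bandpass``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .windowing import Epoch

__all__ = [
    "PLVMatrix",
    "SparsePLV",
    "instantaneous_phase",
    "plv_pair",
    "plv_matrix",
    "plv_matrix_from_phases",
    "sparsify",
]


@dataclass(frozen=True)
class PLVMatrix:
    """Symmetric n x n matrix of pairwise PLVs, unit diagonal, values in [0,1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SparsePLV:
    """Thresholded PLV matrix: entries below the effective threshold are zero."""

    values: np.ndarray
    threshold: float  # effective (realised) threshold
    density: float  # surviving off-diagonal edge fraction

    @property
    def n(self) -> int:
        return self.values.shape[0]


def instantaneous_phase(epoch: "Epoch | np.ndarray") -> np.ndarray:
    """Per-channel instantaneous phase via the analytic-signal angle.

    Each channel is mean-removed and extended to its analytic signal; the
    returned phases are wrapped to (-pi, pi]. Phase is amplitude-invariant,
    so channel scaling does not change the result.

    Raises if any channel is (numerically) all-zero — its phase is undefined.
    """
    data = epoch.data if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected channels x samples")
    if data.shape[1] < 8:
        raise ValueError("need at least 8 samples for a meaningful phase")
    centered = data - data.mean(axis=1, keepdims=True)
    flat = np.ptp(centered, axis=1) < 1e-12 * max(1.0, float(np.abs(data).max()))
    if np.any(flat):
        bad = np.nonzero(flat)[0].tolist()
        raise ValueError(f"phase undefined for constant/all-zero channels {bad}")
    analytic = hilbert(centered, axis=1)
    phases = np.angle(analytic)
    # np.angle returns (-pi, pi]; make the closed endpoint explicit
    phases[phases <= -np.pi] = np.pi
    return phases


def plv_pair(phix: np.ndarray, phiy: np.ndarray) -> float:
    """PLV of two phase sequences: |mean exp(i(phix - phiy))|."""
    phix = np.asarray(phix, dtype=float).ravel()
    phiy = np.asarray(phiy, dtype=float).ravel()
    if phix.shape != phiy.shape:
        raise ValueError("phase sequences must have equal length")
    if phix.size < 1:
        raise ValueError("empty phase sequence")
    return float(np.abs(np.mean(np.exp(1j * (phix - phiy)))))


def plv_matrix_from_phases(phases: np.ndarray) -> PLVMatrix:
    """PLV matrix from a channels x samples phase array.

    Uses the phasor identity PLV_xy = |Z Z^H|/T with Z = exp(i phi), which
    evaluates all n(n-1)/2 distinct pairs in one product.
    """
    phases = np.asarray(phases, dtype=float)
    n, T = phases.shape
    if n < 2:
        raise ValueError("need at least 2 channels")
    Z = np.exp(1j * phases)
    vals = np.abs(Z @ Z.conj().T) / T
    vals = np.minimum(vals, 1.0)
    vals = 0.5 * (vals + vals.T)  # enforce exact symmetry
    np.fill_diagonal(vals, 1.0)
    return PLVMatrix(values=vals)


def plv_matrix(epoch: "Epoch | np.ndarray") -> PLVMatrix:
    """Full pairwise PLV matrix of one epoch (phases extracted internally)."""
    return plv_matrix_from_phases(instantaneous_phase(epoch))


def sparsify(
    plv: PLVMatrix,
    threshold: "float | None" = None,
    density: "float | None" = None,
) -> SparsePLV:
    """Zero out weak edges of a PLV matrix.

    Exactly one rule applies: a fixed threshold tau in [0, 1] keeps entries
    strictly larger than tau ("larger than" read strictly, so tau = 1 keeps
    only exact-1.0 off-diagonal entries and tau = 0 keeps everything
    positive); or a target density q in (0, 1] keeps the top q fraction of
    the n(n-1)/2 off-diagonal values. The diagonal is excluded from
    sparsification and zeroed in the output — self-loops enter the graph
    convolution only through the renormalisation's A + I.
    """
    if (threshold is None) == (density is None):
        raise ValueError("specify exactly one of threshold= or density=")
    vals = plv.values.copy()
    n = plv.n
    np.fill_diagonal(vals, 0.0)
    iu = np.triu_indices(n, k=1)
    upper = vals[iu]

    if threshold is not None:
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        tau = float(threshold)
    else:
        if not 0.0 < density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        m_keep = int(round(density * upper.size))
        if m_keep >= upper.size:
            tau = -np.inf  # keep all
        elif m_keep == 0:
            tau = np.inf
        else:
            # strict '>' against the (m_keep+1)-th largest keeps m_keep edges
            tau = float(np.partition(upper, upper.size - m_keep - 1)[upper.size - m_keep - 1])

    keep = vals > tau
    out = np.where(keep, vals, 0.0)
    out = np.maximum(out, out.T)  # symmetry is preserved; cheap guard
    realised = float(np.count_nonzero(out[iu]) / upper.size)
    return SparsePLV(values=out, threshold=(0.0 if tau == -np.inf else tau), density=realised)
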