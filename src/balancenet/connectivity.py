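"""Phase-lag-based functional connectivity: PLI and wPLI.

Both indices read phase relations off the analytic signal (Hilbert
transform) of band-limited epochs. The phase-lag index (PLI) is the
absolute mean sign of the phase difference, blind to zero-lag
(volume-conducted) coupling. The weighted PLI (wPLI) additionally weights
each sample by the magnitude of the imaginary cross-spectral component,
maximizing sensitivity near +/-90 degree lags and further suppressing
instantaneously mixed sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import signal

from .core import DataError, EpochSet

__all__ = [
    "PhaseSeries",
    "ConnectivityMatrix",
    "instantaneous_phase",
    "pli",
    "wpli",
    "connectivity_matrix",
]

#: Fraction of samples discarded at each end before taking expectations,
#: to bound Hilbert edge transients on short epochs.
EDGE_FRACTION = 0.10

#: Denominator below this is treated as exactly zero lag -> index 0.
_DENOM_TOL = 1e-12


@dataclass
class PhaseSeries:
    """Instantaneous phase (radians, wrapped to (-pi, pi]) per channel.

    ``valid`` flags channels with well-defined phase (non-degenerate
    amplitude); ``interior`` is the slice excluding edge transients.
    """

    phi: np.ndarray            # (n_channels, n_samples)
    valid: np.ndarray          # (n_channels,) bool
    interior: slice

    @property
    def n_samples(self) -> int:
        return self.phi.shape[1]


def instantaneous_phase(epoch: np.ndarray) -> PhaseSeries:
    """Analytic-signal phase of each channel of one band-limited epoch.

    All-zero (or constant) channels have no defined phase and are flagged
    invalid. The first and last 10% of samples are marked for exclusion
    from any expectation taken downstream.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if not np.all(np.isfinite(epoch)):
        raise DataError("epoch contains non-finite samples")
    n = epoch.shape[1]
    z = signal.hilbert(epoch, axis=-1)
    phi = np.angle(z)
    valid = epoch.std(axis=-1) > 0
    edge = int(np.floor(EDGE_FRACTION * n))
    return PhaseSeries(phi=phi, valid=valid, interior=slice(edge, n - edge))


def pli(phix: np.ndarray, phiy: np.ndarray) -> float:
    """Phase-lag index ``|E{sgn(dphi)}|`` of two phase series.

    ``dphi`` is wrapped to (-pi, pi] before taking the sign, so the index
    measures the asymmetry of the phase-difference distribution about zero.
    """
    phix = np.asarray(phix, dtype=float)
    phiy = np.asarray(phiy, dtype=float)
    if phix.shape != phiy.shape or phix.size == 0:
        raise DataError("phase series must be equal-length and non-empty")
    dphi = np.angle(np.exp(1j * (phix - phiy)))
    return float(abs(np.mean(np.sign(dphi))))


def wpli(
    epoch_x: np.ndarray,
    epoch_y: np.ndarray,
    variant: str = "cross-spectrum",
    exclude_edges: bool = True,
) -> float:
    """Weighted phase-lag index of two band-limited series.

    variant="cross-spectrum" (default)
        The imaginary-cross-spectrum estimator
        ``|E{Im Z}| / E{|Im Z|}`` with ``Z = z_x * conj(z_y)`` the
        analytic cross-signal; weights each sample by the magnitude of
        the imaginary component, i.e. by amplitude times |sin dphi|.
    variant="phase-lag"
        Amplitude-free sensitivity variant weighting purely by the wrapped
        phase difference: ``|E{dphi}| / E{|dphi|}``.

    Both lie in [0, 1]; a vanishing denominator (exactly zero-lag pair)
    returns 0, the "no phase synchronization" convention.
    """
    x = np.asarray(epoch_x, dtype=float)
    y = np.asarray(epoch_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("wpli expects two equal-length 1-D series")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("non-finite input")
    zx = signal.hilbert(x)
    zy = signal.hilbert(y)
    if exclude_edges:
        edge = int(np.floor(EDGE_FRACTION * x.size))
        sl = slice(edge, x.size - edge)
        zx, zy = zx[sl], zy[sl]
    if variant == "cross-spectrum":
        im = np.imag(zx * np.conj(zy))
        denom = np.mean(np.abs(im))
        if denom < _DENOM_TOL:
            return 0.0
        return float(abs(np.mean(im)) / denom)
    if variant == "phase-lag":
        dphi = np.angle(zx) - np.angle(zy)
        dphi = np.angle(np.exp(1j * dphi))
        denom = np.mean(np.abs(dphi))
        if denom < _DENOM_TOL:
            return 0.0
        return float(abs(np.mean(dphi)) / denom)
    raise DataError(f"unknown wPLI variant {variant!r}")


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node synchrony weights in [0, 1] for one epoch."""

    w: np.ndarray
    labels: tuple[str, ...]
    method: str = "wPLI"
    band_label: str = "none"
    epoch_id: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = self.w.shape[0]
        if self.w.shape != (n, n):
            raise DataError("connectivity matrix must be square")
        if not np.allclose(self.w, self.w.T, equal_nan=True):
            raise DataError("connectivity matrix must be symmetric")
        self.labels = tuple(self.labels)

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]


def _epoch_matrix(
    epoch: np.ndarray, method: str, variant: str
) -> np.ndarray:
    n_ch, n = epoch.shape
    w = np.zeros((n_ch, n_ch))
    if method == "PLI":
        ps = instantaneous_phase(epoch)
        phi = ps.phi[:, ps.interior]
        for i, j in combinations(range(n_ch), 2):
            if ps.valid[i] and ps.valid[j]:
                w[i, j] = w[j, i] = pli(phi[i], phi[j])
            else:
                w[i, j] = w[j, i] = np.nan
        return w
    # wPLI: one Hilbert pass for all channels, then pairwise cross-terms
    z = signal.hilbert(epoch, axis=-1)
    edge = int(np.floor(EDGE_FRACTION * n))
    z = z[:, edge:n - edge]
    valid = epoch.std(axis=-1) > 0
    if variant == "cross-spectrum":
        for i, j in combinations(range(n_ch), 2):
            if not (valid[i] and valid[j]):
                w[i, j] = w[j, i] = np.nan
                continue
            im = np.imag(z[i] * np.conj(z[j]))
            denom = np.mean(np.abs(im))
            w[i, j] = w[j, i] = (
                0.0 if denom < _DENOM_TOL else abs(np.mean(im)) / denom
            )
    else:
        phi = np.angle(z)
        for i, j in combinations(range(n_ch), 2):
            if not (valid[i] and valid[j]):
                w[i, j] = w[j, i] = np.nan
                continue
            dphi = np.angle(np.exp(1j * (phi[i] - phi[j])))
            denom = np.mean(np.abs(dphi))
            w[i, j] = w[j, i] = (
                0.0 if denom < _DENOM_TOL else abs(np.mean(dphi)) / denom
            )
    return w


def connectivity_matrix(
    eps: EpochSet, method: str = "wPLI", variant: str = "cross-spectrum"
) -> list[ConnectivityMatrix]:
    """Per-epoch all-pairs connectivity for every kept epoch.

    Entries involving a degenerate (flat) channel are NaN; the diagonal is
    zero. Expectations are taken over time samples within each epoch.
    """
    if method not in ("PLI", "wPLI"):
        raise DataError(f"method must be 'PLI' or 'wPLI', got {method!r}")
    kept_idx = np.flatnonzero(eps.kept)
    if kept_idx.size == 0:
        raise DataError("no kept epochs to compute connectivity from")
    out = []
    for eid in kept_idx:
        w = _epoch_matrix(eps.epochs[eid], method, variant)
        out.append(
            ConnectivityMatrix(
                w, eps.labels, method=method,
                band_label=eps.band_label, epoch_id=int(eid),
            )
        )
    return out
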