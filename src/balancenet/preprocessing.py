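"""EEG preprocessing: broadband filtering, ocular regression, epoching.

Fixed stage order: broadband FIR filter -> bipolar EOG derivation ->
regression-based ocular correction -> 2 s epoching -> amplitude-based
artifact rejection -> sub-band filtering. Each stage is a pure function on
:class:`~balancenet.core.EegRecording` / :class:`~balancenet.core.EpochSet`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .core import DataError, EegRecording, EpochSet, ParameterError

__all__ = [
    "BANDS",
    "broadband_filter",
    "derive_eog",
    "regress_out_ocular",
    "epoch",
    "reject_artifacts",
    "band_filter",
    "preprocess",
]

#: Analysis sub-bands in Hz. Oscillations below 4 Hz and above 20 Hz are
#: excluded as likely ocular / muscle artifact.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 20.0),
}


def _fir_bandpass(band: tuple[float, float], fs: float) -> np.ndarray:
    """Linear-phase FIR band-pass with a steep (>= 60 dB) low-frequency skirt.

    The transition width is half the low edge, i.e. the stop band is reached
    one octave below the passband edge, giving >= 60 dB/octave roll-off there.
    """
    lo, hi = band
    width = lo / 2.0 / (fs / 2.0)  # normalized transition width
    numtaps, beta = signal.kaiserord(ripple=65.0, width=width)
    numtaps |= 1  # odd length -> exactly linear phase, integer group delay
    return signal.firwin(
        numtaps, [lo, hi], window=("kaiser", beta), pass_zero=False, fs=fs
    )


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR along the last axis with zero net delay."""
    delay = (taps.size - 1) // 2
    pad = taps.size  # reflect-pad to suppress edge transients
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    y = signal.fftconvolve(xp, taps[np.newaxis, :] if x.ndim == 2 else taps,
                           mode="full", axes=-1)
    start = pad + delay
    return y[..., start:start + x.shape[-1]]


def broadband_filter(
    rec: EegRecording, band: tuple[float, float] = (1.0, 60.0)
) -> EegRecording:
    """Zero-phase FIR band-pass (default 1-60 Hz) removing DC and HF noise.

    EOG channels are filtered with the same kernel so that the subsequent
    regression sees time-aligned, identically conditioned signals.
    """
    if band[1] >= rec.fs / 2.0:
        raise ParameterError(
            f"band edge {band[1]} Hz not below Nyquist {rec.fs / 2} Hz"
        )
    if rec.fs <= 2 * band[1]:
        raise ParameterError("sampling rate too low for the requested band")
    taps = _fir_bandpass(band, rec.fs)
    out = rec.copy()
    out.data = _zero_phase_fir(rec.data, taps)
    if rec.eog is not None:
        out.eog = _zero_phase_fir(rec.eog, taps)
    return out


def derive_eog(rec: EegRecording) -> tuple[np.ndarray, np.ndarray]:
    """Bipolar VEOG / HEOG traces from the four periocular channels.

    VEOG = supraorbital - infraorbital (blinks deflect positively at the
    supraorbital site); HEOG = right canthus - left canthus.
    """
    if rec.eog is None:
        raise DataError(
            "recording has no periocular channels; cannot derive VEOG/HEOG"
        )
    supra, infra, left, right = rec.eog
    return supra - infra, right - left


def regress_out_ocular(
    rec: EegRecording, veog: np.ndarray, heog: np.ndarray
) -> tuple[EegRecording, np.ndarray]:
    """Subtract ocular activity from every scalp channel by OLS regression.

    Each channel is regressed on (VEOG, HEOG, intercept); the fitted ocular
    part ``b_v * veog + b_h * heog`` is removed. Returns the corrected
    recording and the (n_channels, 2) coefficient matrix ``[b_v, b_h]``.
    """
    veog = np.asarray(veog, dtype=float)
    heog = np.asarray(heog, dtype=float)
    if veog.shape != (rec.n_samples,) or heog.shape != (rec.n_samples,):
        raise DataError("EOG regressors must be time-aligned with the EEG")
    x = np.column_stack([veog, heog, np.ones(rec.n_samples)])
    vs, hs = veog.std(), heog.std()
    if vs > 0 and hs > 0:
        rho = abs(np.corrcoef(veog, heog)[0, 1])
        if rho > 0.999:
            warnings.warn(
                "VEOG and HEOG nearly collinear; ocular coefficients are "
                "not separately identifiable (pseudo-inverse fit)",
                stacklevel=2,
            )
    beta, *_ = np.linalg.lstsq(x, rec.data.T, rcond=None)  # (3, n_channels)
    out = rec.copy()
    out.data = rec.data - beta[0][:, None] * veog - beta[1][:, None] * heog
    return out, beta[:2].T.copy()


def epoch(
    rec: EegRecording, length_s: float = 2.0, discard_head_s: float = 2.0
) -> EpochSet:
    """Cut contiguous non-overlapping epochs, skipping the unstable head.

    The first ``discard_head_s`` seconds are never epoched; a partial tail
    is dropped. Segmentation is exact sample-index arithmetic.
    """
    head = int(round(discard_head_s * rec.fs))
    ln = int(round(length_s * rec.fs))
    n_ep = (rec.n_samples - head) // ln
    if n_ep < 1:
        raise DataError(
            f"recording of {rec.duration_s:.1f} s too short for one "
            f"{length_s} s epoch after discarding {discard_head_s} s"
        )
    usable = rec.data[:, head:head + n_ep * ln]
    eps = usable.reshape(rec.n_channels, n_ep, ln).transpose(1, 0, 2).copy()
    return EpochSet(eps, rec.fs, rec.labels)


def reject_artifacts(eps: EpochSet, amp_threshold_uv: float = 100.0) -> EpochSet:
    """Drop every epoch in which any scalp channel exceeds the threshold.

    The amplitude criterion (default +/-100 microvolts) is the standard
    automated rejection rule; the mask records a reason per dropped epoch.
    """
    if eps.n_epochs == 0:
        raise DataError("no epochs to reject from")
    out = eps.copy()
    peak = np.abs(eps.epochs).max(axis=(1, 2))
    over = peak > amp_threshold_uv
    out.kept = eps.kept & ~over
    out.reasons = [
        f"amplitude {p:.1f} uV exceeds {amp_threshold_uv:.0f} uV" if o else r
        for p, o, r in zip(peak, over, eps.reasons)
    ]
    if out.n_kept == 0:
        raise DataError(
            "all epochs rejected; review the amplitude threshold "
            f"({amp_threshold_uv} uV) against the data scale"
        )
    return out


def band_filter(
    eps: EpochSet, band_label: str, order: int = 4, pad_s: float = 0.5
) -> EpochSet:
    """Zero-phase Butterworth band-pass of every epoch at the named band.

    Each 2 s epoch is reflection-padded by ``pad_s`` seconds per side before
    forward-backward filtering, then trimmed, bounding filter transients on
    epochs that are short relative to the theta period.
    """
    if band_label not in BANDS:
        raise ParameterError(
            f"unknown band {band_label!r}; expected one of {sorted(BANDS)}"
        )
    lo, hi = BANDS[band_label]
    sos = signal.butter(order, [lo, hi], btype="band", fs=eps.fs, output="sos")
    padlen = min(int(round(pad_s * eps.fs)), eps.epochs.shape[-1] - 1)
    out = eps.copy()
    out.epochs = signal.sosfiltfilt(sos, eps.epochs, axis=-1, padlen=padlen)
    out.band_label = band_label
    return out


def preprocess(
    rec: EegRecording,
    band_label: str | None = None,
    epoch_length_s: float = 2.0,
    discard_head_s: float = 2.0,
    amp_threshold_uv: float = 100.0,
    broadband: tuple[float, float] = (1.0, 60.0),
) -> EpochSet:
    """Full raw-to-epochs chain for one recording (one band if requested)."""
    rec = broadband_filter(rec, broadband)
    if rec.eog is not None:
        veog, heog = derive_eog(rec)
        rec, _ = regress_out_ocular(rec, veog, heog)
    eps = epoch(rec, epoch_length_s, discard_head_s)
    eps = reject_artifacts(eps, amp_threshold_uv)
    if band_label is not None:
        eps = band_filter(eps, band_label)
    return eps
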