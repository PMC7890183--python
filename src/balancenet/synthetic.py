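"""Synthetic EEG, EOG, COP and p-value generators with known ground truth.

Every downstream stage of the pipeline is exercised against data whose
generative parameters are known exactly: narrowband cortical sources with
programmable inter-channel phase lags and coupling strengths, zero-lag
(volume-conduction-like) instantaneous mixing, blink/saccade artifacts
with per-channel propagation gains, COP trajectories with specified
covariance, spectral centroid and regularity, and i.i.d. uniform null
p-values for multiple-testing calibration.

Narrowband sources are band-pass-filtered Gaussian noise; a lagged copy of
a source is produced by rotating its analytic signal, which pins the
instantaneous phase difference at the requested lag. Partial coupling
mixes the lagged copy with an independent narrowband source, so the phase
difference acquires zero-mean jitter that grows as coupling weakens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import (
    EOG_LABELS,
    CopTrial,
    DataError,
    EegRecording,
    MONTAGE_30,
    ParameterError,
)

__all__ = [
    "CouplingSpec",
    "MixingModel",
    "CopSpec",
    "ArtifactResult",
    "gen_coupled_eeg",
    "gen_eog_artifacts",
    "gen_cop",
    "gen_null_pvalues",
    "narrowband_noise",
]

#: Default RMS of a clean synthetic scalp channel, microvolts.
_CHANNEL_RMS_UV = 20.0


@dataclass(frozen=True)
class CouplingSpec:
    """Which channel pairs are phase-coupled, and how strongly.

    node_pairs : (i, j) channel-index pairs receiving a lagged common
        rhythm. The first index carries the source, the second the lagged
        copy.
    band : (lo, hi) Hz of the narrowband rhythm.
    phase_lag : radians by which channel j trails channel i at band center.
    coupling_strength : 1 = perfect lock, 0 = independent.
    snr_db : sensor signal-to-noise ratio; ``inf`` for noiseless.
    """

    node_pairs: tuple[tuple[int, int], ...] = ((0, 1),)
    band: tuple[float, float] = (8.0, 13.0)
    phase_lag: float = np.pi / 2
    coupling_strength: float = 1.0
    snr_db: float = np.inf

    def validate(self, n_channels: int, fs: float) -> None:
        for i, j in self.node_pairs:
            if i == j:
                raise ParameterError(f"coupled pair ({i}, {j}) is degenerate")
            if not (0 <= i < n_channels and 0 <= j < n_channels):
                raise ParameterError(
                    f"pair ({i}, {j}) outside the {n_channels}-channel montage"
                )
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ParameterError("coupling_strength must lie in [0, 1]")
        lo, hi = self.band
        if not 0.0 < lo < hi < fs / 2.0:
            raise ParameterError(
                f"band {self.band} must lie within (0, {fs / 2}) Hz"
            )


@dataclass(frozen=True)
class MixingModel:
    """Instantaneous (zero-lag) source mixing plus artifact propagation.

    mixing_matrix : channels x sources gains; each source spreads to all
        channels with no delay, mimicking volume conduction.
    artifact_propagation : per-channel blink/saccade gain.
    """

    mixing_matrix: np.ndarray | None = None
    artifact_propagation: np.ndarray | None = None

    def validate(self, n_channels: int) -> None:
        if self.mixing_matrix is not None:
            mm = np.asarray(self.mixing_matrix, dtype=float)
            if mm.ndim != 2 or mm.shape[0] != n_channels:
                raise DataError(
                    f"mixing matrix rows ({mm.shape[0] if mm.ndim == 2 else '?'}) "
                    f"must equal channel count ({n_channels})"
                )
            if not np.all(np.isfinite(mm)):
                raise DataError("mixing matrix must be finite")


@dataclass(frozen=True)
class CopSpec:
    """Ground-truth parameters of a synthetic COP trial.

    covariance : 2x2 AP/ML covariance in cm^2 (symmetric PSD).
    spectral_centroid_hz : target power-spectrum centroid; a scalar applies
        to both axes, a pair sets (AP, ML) separately.
    regularity : in [0, 1); controls how template-self-similar the sway is
        (higher = more regular = lower SampEn). Scalar or (AP, ML) pair.
    """

    duration_s: float = 60.0
    fs: float = 1000.0
    covariance: tuple[tuple[float, float], tuple[float, float]] = (
        (0.36, 0.0), (0.0, 0.20),
    )
    spectral_centroid_hz: float | tuple[float, float] = 0.3
    regularity: float | tuple[float, float] = 0.0

    def cov_array(self) -> np.ndarray:
        return np.asarray(self.covariance, dtype=float)

    def centroids(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.spectral_centroid_hz, dtype=float), (2,)
        ).copy()

    def regularities(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.regularity, dtype=float), (2,)
        ).copy()

    def validate(self) -> None:
        cov = self.cov_array()
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ParameterError("covariance must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ParameterError("covariance must be positive semi-definite")
        if np.any(self.fs <= 2.0 * self.centroids()):
            raise ParameterError("fs must exceed twice the spectral centroid")
        reg = self.regularities()
        if np.any(reg < 0.0) or np.any(reg >= 1.0):
            raise ParameterError("regularity must lie in [0, 1)")
        if self.duration_s <= 0:
            raise ParameterError("duration must be positive")


def narrowband_noise(
    rng: np.random.Generator,
    n_samples: int,
    band: tuple[float, float],
    fs: float,
    order: int = 4,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (Butterworth)."""
    sos = signal.butter(order, band, btype="band", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    return x / sd if sd > 0 else x


def _orthonormal_pair(a: np.ndarray, b: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Demean, decorrelate (Gram-Schmidt) and unit-scale two same-band series.

    Mixing two signals of the same spectral class leaves the class
    unchanged, so this removes chance sample correlation without
    distorting the spectrum.
    """
    a = a - a.mean()
    b = b - b.mean()
    a = a / a.std()
    b = b - (a @ b / a.size) * a
    return a, b / b.std()


def _lagged_copy(x: np.ndarray, phase_lag: float) -> np.ndarray:
    """Copy of a narrowband signal trailing it by ``phase_lag`` radians."""
    z = signal.hilbert(x)
    return np.real(z * np.exp(-1j * phase_lag))


def gen_coupled_eeg(
    spec: CouplingSpec,
    mixing: MixingModel | None = None,
    n_channels: int = 30,
    fs: float = 1000.0,
    duration_s: float = 60.0,
    seed: int = 0,
    source_mode: str = "per-pair",
) -> EegRecording:
    """Multichannel EEG whose pairwise phase coupling is known exactly.

    Each coupled pair shares a narrowband rhythm: channel i carries the
    source, channel j a mixture ``c * lagged + sqrt(1 - c^2) * independent``
    of the phase-rotated copy and an independent narrowband process, so
    coupling_strength c tunes the phase-difference jitter continuously
    between perfect lock (c=1) and independence (c=0). Channels in no pair
    carry independent narrowband noise. Optional instantaneous mixing adds
    zero-lag common sources; sensor noise is set by ``spec.snr_db``.

    ``source_mode="per-pair"`` (default) draws a fresh source for every
    pair. ``"shared-first-node"`` draws one source per distinct first node
    and reuses it for all of that node's pairs — a hub rhythm radiating to
    its spokes, whose spoke-to-spoke phase lag is then zero (suppressed by
    wPLI), producing a star-shaped synchrony skeleton.
    """
    spec.validate(n_channels, fs)
    if mixing is not None:
        mixing.validate(n_channels)
    if source_mode not in ("per-pair", "shared-first-node"):
        raise ParameterError(f"unknown source_mode {source_mode!r}")
    n = int(round(duration_s * fs))
    lo = spec.band[0]
    if duration_s * lo < 2.0:
        raise ParameterError(
            f"{duration_s} s covers fewer than 2 cycles of {lo} Hz"
        )
    rng = np.random.default_rng(seed)
    data = np.zeros((n_channels, n))
    in_pair = np.zeros(n_channels, dtype=bool)
    c = spec.coupling_strength
    shared: dict[int, np.ndarray] = {}
    src_added: set[int] = set()
    for i, j in spec.node_pairs:
        if source_mode == "shared-first-node":
            if i not in shared:
                shared[i] = narrowband_noise(rng, n, spec.band, fs)
            src = shared[i]
            if i not in src_added:
                data[i] += src
                src_added.add(i)
        else:
            src = narrowband_noise(rng, n, spec.band, fs)
            data[i] += src
        lag = _lagged_copy(src, spec.phase_lag)
        indep = narrowband_noise(rng, n, spec.band, fs)
        data[j] += c * lag + np.sqrt(max(0.0, 1.0 - c * c)) * indep
        in_pair[i] = in_pair[j] = True
    for ch in np.flatnonzero(~in_pair):
        data[ch] = narrowband_noise(rng, n, spec.band, fs)
    data *= _CHANNEL_RMS_UV
    if mixing is not None and mixing.mixing_matrix is not None:
        mm = np.asarray(mixing.mixing_matrix, dtype=float)
        n_src = mm.shape[1]
        sources = np.vstack(
            [narrowband_noise(rng, n, spec.band, fs) for _ in range(n_src)]
        )
        data += _CHANNEL_RMS_UV * mm @ sources
    if np.isfinite(spec.snr_db):
        sig_pow = np.mean(data ** 2, axis=1, keepdims=True)
        noise_pow = sig_pow / (10.0 ** (spec.snr_db / 10.0))
        data += np.sqrt(noise_pow) * rng.standard_normal(data.shape)
    labels = (
        MONTAGE_30 if n_channels == 30
        else tuple(f"ch{i:02d}" for i in range(n_channels))
    )
    return EegRecording(data, fs, labels)


def _place_pulses(
    trace: np.ndarray, starts: np.ndarray, template: np.ndarray
) -> None:
    for s in starts:
        e = min(s + template.size, trace.size)
        trace[s:e] += template[: e - s]


def blink_template(fs: float, amplitude_uv: float, width_s: float = 0.2
                   ) -> np.ndarray:
    """200 ms raised-cosine pulse, the canonical blink shape."""
    t = np.arange(int(round(width_s * fs)))
    return amplitude_uv * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / t.size))


def saccade_template(fs: float, amplitude_uv: float, ramp_s: float = 0.05,
                     hold_s: float = 0.2) -> np.ndarray:
    """Step-ramp: 50 ms linear ramp, a plateau, and a symmetric return."""
    nr = int(round(ramp_s * fs))
    nh = int(round(hold_s * fs))
    up = np.linspace(0.0, amplitude_uv, nr, endpoint=False)
    hold = np.full(nh, amplitude_uv)
    return np.concatenate([up, hold, up[::-1]])


@dataclass
class ArtifactResult:
    """Contaminated recording plus everything needed to score correction."""

    contaminated: EegRecording
    clean: EegRecording
    veog_true: np.ndarray
    heog_true: np.ndarray
    propagation: np.ndarray = field(default=None)  # type: ignore[assignment]


def gen_eog_artifacts(
    rec: EegRecording,
    blink_rate_hz: float = 0.25,
    amplitude_uv: float = 200.0,
    propagation: np.ndarray | None = None,
    seed: int = 0,
    saccade_rate_hz: float = 0.1,
    saccade_amplitude_uv: float = 100.0,
    saccade_propagation: np.ndarray | None = None,
) -> ArtifactResult:
    """Superimpose blink/saccade artifacts with known propagation gains.

    Scalp channel c receives ``propagation[c] *`` the true VEOG trace (and
    ``saccade_propagation[c] *`` the true HEOG trace); the periocular
    channels are populated so that the bipolar derivations recover the
    true traces. The uncontaminated recording is returned alongside so
    correction error can be measured sample-by-sample.
    """
    if blink_rate_hz < 0 or saccade_rate_hz < 0:
        raise ParameterError("artifact rates must be non-negative")
    nc, n = rec.n_channels, rec.n_samples
    propagation = (
        np.zeros(nc) if propagation is None
        else np.asarray(propagation, dtype=float)
    )
    if propagation.shape != (nc,):
        raise DataError(
            f"propagation vector length {propagation.size} != {nc} channels"
        )
    if saccade_propagation is None:
        saccade_propagation = np.zeros(nc)
    saccade_propagation = np.asarray(saccade_propagation, dtype=float)
    if saccade_propagation.shape != (nc,):
        raise DataError("saccade propagation length must equal channel count")
    rng = np.random.default_rng(seed)

    veog = np.zeros(n)
    n_blinks = rng.poisson(blink_rate_hz * rec.duration_s)
    tmpl = blink_template(rec.fs, amplitude_uv)
    starts = np.sort(rng.integers(0, max(1, n - tmpl.size), size=n_blinks))
    _place_pulses(veog, starts, tmpl)

    heog = np.zeros(n)
    n_sac = rng.poisson(saccade_rate_hz * rec.duration_s)
    stmpl = saccade_template(rec.fs, saccade_amplitude_uv)
    sstarts = np.sort(rng.integers(0, max(1, n - stmpl.size), size=n_sac))
    signs = rng.choice([-1.0, 1.0], size=n_sac)
    for s, sg in zip(sstarts, signs):
        e = min(s + stmpl.size, n)
        heog[s:e] += sg * stmpl[: e - s]

    clean = rec.copy()
    out = rec.copy()
    out.data = out.data + propagation[:, None] * veog \
        + saccade_propagation[:, None] * heog
    # periocular montage: blinks deflect supra (+) and infra (-) with a
    # 70/30 split; saccades split symmetrically across the canthi
    out.eog = np.vstack([
        0.7 * veog, -0.3 * veog, -0.5 * heog, 0.5 * heog,
    ])
    return ArtifactResult(out, clean, veog, heog, propagation)


#: Broadband "postural correction" noise band (Hz); a small admixture of
#: this component is what makes low-regularity sway less
#: template-self-similar (higher SampEn).
_COP_NOISE_BAND = (0.5, 5.0)
#: Noise variance fraction at regularity 0.
_COP_NOISE_MAX_FRACTION = 0.04


def _random_phase_signal(rng: np.random.Generator, n: int,
                         power: np.ndarray) -> np.ndarray:
    """Unit-variance series with the given one-sided power profile.

    The amplitude spectrum is deterministic (only phases are random), so
    the realized power split between spectral components is exact in every
    draw — the property the mean-frequency ground truth relies on.
    """
    amp = np.sqrt(power)
    ph = rng.uniform(0.0, 2.0 * np.pi, amp.size)
    spec = amp * np.exp(1j * ph)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    return x / x.std()


def _slow_power(f: np.ndarray, f_nb: float) -> np.ndarray:
    sigma = 0.3 * f_nb
    g = np.exp(-0.5 * ((f - f_nb) / sigma) ** 2)
    g[f <= 0] = 0.0
    return g


def _fast_power(f: np.ndarray) -> np.ndarray:
    lo, hi = _COP_NOISE_BAND
    taper = 0.25
    g = np.zeros_like(f)
    core = (f >= lo) & (f <= hi)
    g[core] = 1.0
    rise = (f > lo - taper) & (f < lo)
    g[rise] = 0.5 * (1 + np.cos(np.pi * (lo - f[rise]) / taper))
    fall = (f > hi) & (f < hi + taper)
    g[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - hi) / taper))
    return g


def _centroid(f: np.ndarray, g: np.ndarray) -> float:
    return float((f * g).sum() / g.sum())


def gen_cop(spec: CopSpec, seed: int = 0) -> CopTrial:
    """Synthetic AP/ML COP trial matching the spec's ground truth.

    Each axis is built in the frequency domain with a deterministic
    amplitude spectrum and random phases: a narrow Gaussian bump of slow
    sway plus a broadband 0.5-5 Hz component whose exact variance share is
    ``0.04 * (1 - regularity)`` — more of it makes the trace less
    self-similar and raises SampEn. The bump center is solved so the total
    power-spectrum centroid equals ``spectral_centroid_hz``. The two axes
    are decorrelated exactly and colored by the requested covariance, so
    the sample covariance of the produced trial equals ``spec.covariance``
    and the ellipse area is recoverable downstream.
    """
    spec.validate()
    n = int(round(spec.duration_s * spec.fs))
    cov = spec.cov_array()
    if np.allclose(cov, 0.0):
        z = np.zeros(n)
        return CopTrial(z, z.copy(), spec.fs)
    rng = np.random.default_rng(seed)
    f = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    gf = _fast_power(f)
    gf /= gf.sum()
    c_fast = _centroid(f, gf)
    axes = []
    for centroid, regularity in zip(spec.centroids(), spec.regularities()):
        q = _COP_NOISE_MAX_FRACTION * (1.0 - regularity)
        c_slow_target = (centroid - q * c_fast) / (1.0 - q)
        if c_slow_target <= 0:
            raise ParameterError(
                f"spectral centroid {centroid} Hz too low to offset the "
                f"broadband component at regularity {regularity}"
            )
        # fixed-point solve for the bump center whose truncated-Gaussian
        # centroid hits the slow-component target (2-3 steps suffice)
        f_nb = c_slow_target
        for _ in range(4):
            gs = _slow_power(f, f_nb)
            f_nb += c_slow_target - _centroid(f, gs)
            if f_nb <= 0:
                raise ParameterError(
                    "cannot realize the requested spectral centroid"
                )
        gs = _slow_power(f, f_nb)
        gs /= gs.sum()
        x = np.sqrt(1.0 - q) * _random_phase_signal(rng, n, gs)
        if q > 0:
            x = x + np.sqrt(q) * _random_phase_signal(rng, n, gf)
        axes.append(x)
    # exact decorrelation of the two axes (mixing shifts < ~1% of power
    # between the axis spectra), then coloring; the eigenbasis
    # square root tolerates semi-definite targets (frozen axis)
    xy = np.vstack(_orthonormal_pair(*axes))
    tv, tvec = np.linalg.eigh(cov)
    tv = np.clip(tv, 0.0, None)
    color = tvec @ np.diag(np.sqrt(tv)) @ tvec.T
    ap, ml = color @ xy
    return CopTrial(ap, ml, spec.fs)


def gen_null_pvalues(m: int, n_sim: int, seed: int = 0) -> np.ndarray:
    """``n_sim x m`` matrix of i.i.d. Uniform(0, 1) null p-values."""
    if m < 1 or n_sim < 1:
        raise ParameterError("m and n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.random((n_sim, m))
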