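"""Center-of-pressure and stabilometer outcome measures.

Implements the behavioral layer of the analysis: low-pass conditioning of
COP / plate-angle traces, root-mean-square sway amplitude, the 95%
confidence-ellipse sway area (CEA), Welch-based mean frequency, sample
entropy (SampEn), and stabilometer task errors with round-wise
standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .core import CopTrial, DataError, ParameterError

__all__ = [
    "SampEnConfig",
    "SwayMetrics",
    "lowpass_cop",
    "rms_sway",
    "confidence_ellipse_area",
    "mean_frequency",
    "sample_entropy",
    "sway_metrics",
    "task_error",
    "standardized_errors",
]


@dataclass(frozen=True)
class SampEnConfig:
    """Sample-entropy settings.

    m : template length in samples (default 2).
    r_fraction : tolerance as a fraction of the SD of the (decimated)
        series (default 0.20).
    target_fs : sampling rate the series is decimated to before template
        matching (default 100 Hz); anti-alias filtered decimation.
    """

    m: int = 2
    r_fraction: float = 0.20
    target_fs: float = 100.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError(f"template length m must be >= 1, got {self.m}")
        if not 0.0 < self.r_fraction < 1.0:
            raise ParameterError("r_fraction must be in (0, 1)")
        if self.target_fs <= 0:
            raise ParameterError("target_fs must be positive")


@dataclass(frozen=True)
class SwayMetrics:
    """Per-trial scalar sway outcomes (cm, cm^2, Hz, unitless)."""

    rms_ap: float
    rms_ml: float
    cea: float
    mf_ap: float
    mf_ml: float
    sampen_ap: float
    sampen_ml: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rms_ap": self.rms_ap, "rms_ml": self.rms_ml, "cea": self.cea,
            "mf_ap": self.mf_ap, "mf_ml": self.mf_ml,
            "sampen_ap": self.sampen_ap, "sampen_ml": self.sampen_ml,
        }


def lowpass_cop(trial: CopTrial, cutoff: float = 6.0, order: int = 4) -> CopTrial:
    """Zero-phase 4th-order Butterworth low-pass of both COP axes.

    Applied forward-backward so slow sway is not phase-distorted; DC gain
    is exactly 1, so stance offset is preserved.
    """
    nyq = trial.fs / 2.0
    if cutoff >= nyq:
        raise ParameterError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {nyq} Hz"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=trial.fs, output="sos")
    ap = signal.sosfiltfilt(sos, trial.ap)
    ml = signal.sosfiltfilt(sos, trial.ml)
    return trial.with_data(ap, ml)


def rms_sway(x: np.ndarray) -> float:
    """RMS amplitude of the mean-removed series (cm in, cm out)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DataError("rms_sway requires at least 2 samples")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def confidence_ellipse_area(
    ap: np.ndarray, ml: np.ndarray, coverage: float = 0.95
) -> float:
    """95% confidence-ellipse sway area in cm^2.

    Under a stationary bivariate Gaussian sway model the ellipse covering
    ``coverage`` of the distribution has area::

        CEA = pi * chi2(2, coverage) * sqrt(det(S))

    with S the sample covariance of (AP, ML). A degenerate covariance
    (motion confined to a line or point) yields area 0.
    """
    ap = np.asarray(ap, dtype=float)
    ml = np.asarray(ml, dtype=float)
    if ap.shape != ml.shape or ap.size < 3:
        raise DataError("confidence_ellipse_area needs equal-length series, n >= 3")
    cov = np.cov(np.vstack([ap, ml]))
    det = float(np.linalg.det(cov))
    if det <= 0:
        import warnings

        warnings.warn("degenerate sway covariance; ellipse area set to 0",
                      stacklevel=2)
        return 0.0
    k = stats.chi2.ppf(coverage, df=2)
    return float(np.pi * k * np.sqrt(det))


def mean_frequency(
    x: np.ndarray,
    fs: float,
    window_s: float = 15.0,
    overlap_fraction: float = 0.25,
    band: tuple[float, float] = (0.0, 6.0),
    resolution_hz: float = 0.02,
) -> float:
    """Power-weighted mean frequency of the Welch spectrum, in Hz.

    Hanning-tapered Welch segments of ``window_s`` seconds with
    ``overlap_fraction`` x window overlap; segments are zero-padded so the
    spectral bin spacing reaches ``resolution_hz``. The centroid
    ``sum(f * P) / sum(P)`` is taken over bins strictly above ``band[0]``
    and at most ``band[1]`` (DC excluded: it encodes stance offset, not
    sway).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise DataError(
            f"series of {x.size} samples shorter than one {window_s} s window"
        )
    nfft = max(nperseg, int(np.ceil(fs / resolution_hz)))
    f, p = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap_fraction * nperseg)), nfft=nfft,
        detrend="constant",
    )
    sel = (f > band[0]) & (f <= band[1])
    ptot = p[sel].sum()
    if ptot <= 0 or not np.isfinite(ptot):
        raise DataError("signal has no in-band power; mean frequency undefined")
    return float((f[sel] * p[sel]).sum() / ptot)


class UndefinedEntropyError(DataError):
    """No template matches of length m+1: SampEn is undefined."""


def _decimate_to(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    if target_fs > fs:
        raise ParameterError("target_fs must not exceed the source rate")
    factor = fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ParameterError(
            f"decimation from {fs} to {target_fs} Hz is not an integer factor"
        )
    factor = int(round(factor))
    if factor == 1:
        return x
    # IIR anti-alias + zero-phase, scipy's standard decimator
    return signal.decimate(x, factor, ftype="iir", zero_phase=True)


def sample_entropy(
    x: np.ndarray, cfg: SampEnConfig = SampEnConfig(), fs: float | None = None
) -> float:
    """Sample entropy ``-log(sum A_i / sum B_i)`` of a 1-D series.

    ``B_i`` counts templates of length ``m`` within Chebyshev distance
    ``r`` of template ``i``; ``A_i`` the same for length ``m + 1``;
    self-matches are excluded and ``r = r_fraction x SD`` of the
    (decimated) series. If ``fs`` is given the series is first decimated
    to ``cfg.target_fs`` through an anti-aliasing filter.
    """
    x = np.asarray(x, dtype=float)
    if fs is not None:
        x = _decimate_to(x, fs, cfg.target_fs)
    n = x.size
    m = cfg.m
    if n <= m + 1:
        raise DataError(f"need more than m+1={m + 1} samples, got {n}")
    sd = x.std()
    if sd == 0:
        raise DataError("zero-variance series; SampEn undefined")
    r = cfg.r_fraction * sd

    # n - m templates of length m and of length m+1, both anchored at the
    # first n - m starting points; unordered template pairs within
    # Chebyshev distance r counted via KD-trees (exact: the metric is a
    # max of absolute differences, no accumulation error)
    from scipy.spatial import cKDTree

    nt = n - m
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    tree_m = cKDTree(tm)
    tree_m1 = cKDTree(tm1)
    b = int((tree_m.count_neighbors(tree_m, r, p=np.inf) - nt) // 2)
    a = int((tree_m1.count_neighbors(tree_m1, r, p=np.inf) - nt) // 2)
    if b == 0 or a == 0:
        raise UndefinedEntropyError(
            "no template matches; SampEn undefined for this series"
        )
    return float(-np.log(a / b))


def sway_metrics(
    trial: CopTrial,
    sampen_cfg: SampEnConfig = SampEnConfig(),
    mf_kwargs: dict | None = None,
) -> SwayMetrics:
    """All scalar sway outcomes of one (already low-passed) COP trial."""
    kw = mf_kwargs or {}
    return SwayMetrics(
        rms_ap=rms_sway(trial.ap),
        rms_ml=rms_sway(trial.ml),
        cea=confidence_ellipse_area(trial.ap, trial.ml),
        mf_ap=mean_frequency(trial.ap, trial.fs, **kw),
        mf_ml=mean_frequency(trial.ml, trial.fs, **kw),
        sampen_ap=sample_entropy(trial.ap, sampen_cfg, fs=trial.fs),
        sampen_ml=sample_entropy(trial.ml, sampen_cfg, fs=trial.fs),
    )


def task_error(
    plate_angle: np.ndarray,
    target: np.ndarray,
    fs: float,
    keep: tuple[float, float] = (3.0, 42.0),
) -> float:
    """RMS plate-vs-target mismatch (degrees) over the kept interval.

    The mismatch is *not* demeaned: a constant offset from the target is
    real tracking error. The first and last seconds outside ``keep`` are
    discarded as unstable.
    """
    plate_angle = np.asarray(plate_angle, dtype=float)
    target = np.asarray(target, dtype=float)
    if plate_angle.shape != target.shape:
        raise DataError("plate and target series must have equal length")
    i0, i1 = int(round(keep[0] * fs)), int(round(keep[1] * fs))
    if plate_angle.size < i1:
        raise DataError(
            f"series of {plate_angle.size / fs:.1f} s does not cover the "
            f"{keep[1]} s analysis window"
        )
    d = plate_angle[i0:i1] - target[i0:i1]
    return float(np.sqrt(np.mean(d ** 2)))


def standardized_errors(per_round_errors: np.ndarray) -> np.ndarray:
    """Per-round task errors as percent of round 1."""
    e = np.asarray(per_round_errors, dtype=float)
    if e.size < 1:
        raise DataError("need at least one round")
    if e[0] <= 0:
        raise DataError("round-1 error must be positive for standardization")
    return 100.0 * e / e[0]
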