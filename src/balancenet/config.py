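"""Study configuration: every tunable of the pipeline in one place.

Defaults reproduce the analysis settings of the study design this package
models: 6 Hz 4th-order low-pass for COP, SampEn(m=2, r=0.2 SD) at 100 Hz,
15 s Hanning Welch windows with 25% overlap zero-padded to 0.02 Hz
resolution, 1-60 Hz broadband FIR, 2 s epochs after a 2 s discard,
+/-100 uV rejection, theta/alpha/beta sub-bands, the imaginary
cross-spectrum wPLI estimator, and [0, 1]-normalized MST metrics. The
synthetic-cohort block defines the ground-truth generative parameters for
simulated pre/post groups of 16 subjects x 3 trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ParameterError

__all__ = ["StudyConfig", "load_config", "save_config"]


def _default_groups() -> dict[str, int]:
    return {"SV": 16, "control": 16}


def _default_cov() -> list[list[float]]:
    # baseline AP variance 0.42 cm^2 (~0.65 cm RMS), ML 0.20 cm^2 (~0.44 cm)
    return [[0.42, 0.0], [0.0, 0.20]]


def _default_behavior_effects() -> dict:
    # multiplicative/additive pre->post shifts per group: the control group
    # shrinks AP sway and becomes less regular (higher SampEn); the SV group
    # keeps its sway size but raises sway frequency and SampEn
    return {
        "control": {"ap_std_scale": 0.93, "centroid_scale": 1.14,
                    "regularity_delta": -0.10},
        "SV": {"ap_std_scale": 0.99, "centroid_scale": 1.25,
               "regularity_delta": -0.12},
    }


def _default_topology() -> dict:
    # pre-test: distributed chain coupling in both groups; post-test: the
    # control group's network concentrates on a hub, the SV group's does not
    return {
        "pre": {"SV": "path", "control": "path"},
        "post": {"SV": "path", "control": "hub"},
    }


def _default_coupling_strength() -> dict:
    return {
        "pre": {"SV": 0.45, "control": 0.45},
        "post": {"SV": 0.45, "control": 0.70},
    }


@dataclass
class StudyConfig:
    """All tunables of the behavioral + connectome replica pipeline."""

    seed: int = 0
    groups: dict[str, int] = field(default_factory=_default_groups)
    sessions: tuple[str, ...] = ("pre", "post")
    n_trials: int = 3
    alpha: float = 0.05

    # --- COP analysis ---
    cop_fs: float = 1000.0
    cop_duration_s: float = 60.0
    cop_lowpass_hz: float = 6.0
    cop_lowpass_order: int = 4
    sampen_m: int = 2
    sampen_r_fraction: float = 0.20
    sampen_target_fs: float = 100.0
    welch_window_s: float = 15.0
    welch_overlap: float = 0.25
    welch_resolution_hz: float = 0.02
    mf_band: tuple[float, float] = (0.0, 6.0)

    # --- behavioral synthetic cohort ground truth ---
    cop_base_covariance: list[list[float]] = field(default_factory=_default_cov)
    cop_centroid_hz: float = 0.27
    cop_regularity: float = 0.15
    subject_cv: float = 0.12           # inter-subject coefficient of variation
    session_cv: float = 0.08           # day-to-day within-subject variation
    centroid_session_cv: float = 0.28  # day-to-day variation of sway frequency
    behavior_effects: dict = field(default_factory=_default_behavior_effects)

    # --- EEG preprocessing ---
    eeg_fs: float = 1000.0
    eeg_duration_s: float = 60.0
    eeg_n_channels: int = 30
    broadband: tuple[float, float] = (1.0, 60.0)
    epoch_length_s: float = 2.0
    discard_head_s: float = 2.0
    amp_threshold_uv: float = 100.0
    bands: tuple[str, ...] = ("theta", "alpha", "beta")

    # --- connectivity / MST ---
    wpli_variant: str = "cross-spectrum"   # or "phase-lag"
    mst_normalize: bool = True

    # --- connectome synthetic cohort ground truth ---
    coupling_topology: dict = field(default_factory=_default_topology)
    coupling_strength: dict = field(default_factory=_default_coupling_strength)
    coupling_phase_lag: float = 1.5707963267948966  # pi/2
    eeg_snr_db: float = 10.0
    eeg_blink_rate_hz: float = 0.0
    eeg_blink_amplitude_uv: float = 150.0

    def __post_init__(self) -> None:
        if self.wpli_variant not in ("cross-spectrum", "phase-lag"):
            raise ParameterError(
                f"unknown wPLI variant {self.wpli_variant!r}"
            )
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")
        self.sessions = tuple(self.sessions)
        self.bands = tuple(self.bands)
        self.mf_band = tuple(self.mf_band)
        self.broadband = tuple(self.broadband)

    # -- lossless round-trip to/from YAML ------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("sessions", "bands", "mf_band", "broadband"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        return StudyConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
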