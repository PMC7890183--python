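"""Core data containers shared across the pipeline.

The containers mirror the experimental record: a multichannel scalp EEG
recording with periocular (EOG) channels, the epoch sets produced by
segmentation, and force-plate center-of-pressure (COP) trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: 30-site scalp montage (10-20 system extension) used throughout.
MONTAGE_30 = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "FT7", "FT8", "FCz", "FC3", "FC4",
    "Cz", "C3", "C4", "CPz", "CP3", "CP4",
    "Pz", "P3", "P4", "T3", "T4", "T5", "T6",
    "TP7", "TP8", "Oz", "O1", "O2",
)

#: Periocular channel order: supra-/infra-orbital (vertical), left/right canthus.
EOG_LABELS = ("supraorbital", "infraorbital", "left_canthus", "right_canthus")


class BalanceNetError(Exception):
    """Base class for pipeline errors."""


class ParameterError(BalanceNetError, ValueError):
    """Invalid parameter or configuration value."""


class DataError(BalanceNetError, ValueError):
    """Input data violates a structural precondition."""


@dataclass
class EegRecording:
    """Labeled channels x samples EEG matrix in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Scalp potentials in microvolts.
    fs : float
        Sampling rate in Hz. Nominally 1000 Hz but arbitrary rates are
        accepted.
    labels : sequence of str
        Montage site names, one per scalp channel; must be unique.
    eog : ndarray, shape (4, n_samples), optional
        Periocular channels in :data:`EOG_LABELS` order.
    """

    data: np.ndarray
    fs: float
    labels: Sequence[str] = MONTAGE_30
    eog: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise DataError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise DataError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise DataError("EEG data contains non-finite samples")
        if self.eog is not None:
            self.eog = np.asarray(self.eog, dtype=float)
            if self.eog.shape != (4, self.data.shape[1]):
                raise DataError(
                    "eog must have shape (4, n_samples) time-aligned with data"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EegRecording":
        return EegRecording(
            self.data.copy(), self.fs, self.labels,
            None if self.eog is None else self.eog.copy(),
        )


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one recording.

    ``epochs`` holds every segmented epoch; ``kept`` flags the ones that
    survived artifact rejection, with ``reasons`` recording why an epoch
    was dropped (empty string = kept).
    """

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    fs: float
    labels: Sequence[str]
    band_label: str = "none"
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise DataError("epochs must be (n_epochs, n_channels, n_samples)")
        self.labels = tuple(self.labels)
        if self.kept is None:
            self.kept = np.ones(self.epochs.shape[0], dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        if not self.reasons:
            self.reasons = [""] * self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_epochs(self) -> np.ndarray:
        return self.epochs[self.kept]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.epochs.copy(), self.fs, self.labels, self.band_label,
            self.kept.copy(), list(self.reasons),
        )


@dataclass
class CopTrial:
    """Anteroposterior / mediolateral center-of-pressure trajectory (cm)."""

    ap: np.ndarray
    ml: np.ndarray
    fs: float
    trial_id: str = ""
    subject_id: str = ""
    session: str = ""   # "pre" | "post"
    group: str = ""     # "SV" | "control"

    def __post_init__(self) -> None:
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        if self.ap.ndim != 1 or self.ml.ndim != 1:
            raise DataError("ap and ml must be 1-D")
        if self.ap.shape != self.ml.shape:
            raise DataError("ap and ml must have equal length")
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if not (np.all(np.isfinite(self.ap)) and np.all(np.isfinite(self.ml))):
            raise DataError("COP trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.ap.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, ap: np.ndarray, ml: np.ndarray) -> "CopTrial":
        return replace(self, ap=ap, ml=ml)
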