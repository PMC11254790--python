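"""Core in-memory containers shared by every stage of the pipeline.

An :class:`EcgRecord` is a single-lead sampled voltage trace in millivolts
with its sampling rate and identity metadata.  A :class:`BeatDataset` is the
tabular collection of fixed-length (150-sample) labeled heartbeats that the
segmentation stage emits and the classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Number of samples every interpolated R-R beat is resampled to.
BEAT_LENGTH = 150


@dataclass
class EcgRecord:
    """A single-lead ECG trace.

    Parameters
    ----------
    samples : ndarray of float, shape (n,)
        Voltage samples in millivolts.
    fs : float
        Sampling rate in Hz, strictly positive.
    subject_id : str
        Identity label of the person the trace belongs to.
    record_id : str
        Identifier of the recording (one subject may have several).
    lead : str
        Lead / channel name, e.g. ``"ECG1"`` or ``"MLII"``.
    session : str
        Free-form session tag (acquisition day, device, ...).
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    record_id: str = ""
    lead: str = "ECG1"
    session: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain NaN or infinite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "EcgRecord":
        """Copy of this record with new samples (and optionally a new fs)."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       fs=self.fs if fs is None else fs)


@dataclass
class Beat:
    """One interpolated R-R heartbeat, :data:`BEAT_LENGTH` samples by default."""

    values: np.ndarray
    subject_id: str
    record_id: str = ""
    rr_samples: float = float("nan")  # original R-R length before interpolation

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("beat values must be a 1-D vector of >= 2 samples")


@dataclass
class BeatDataset:
    """Matrix of beats (rows) by sample values (150 columns) with labels.

    ``labels[i]`` is the subject of row ``i``; ``provenance[i]`` the record it
    was clipped from.  The container is deliberately plain — a numpy matrix
    plus parallel label arrays — so it converts trivially to the CSV dialect
    used on disk and to classifier inputs.
    """

    beats: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=float)
        if self.beats.size == 0:
            self.beats = self.beats.reshape(0, BEAT_LENGTH)
        if self.beats.ndim != 2 or self.beats.shape[1] != BEAT_LENGTH:
            raise ValueError(
                f"beats must be (n, {BEAT_LENGTH}), got {self.beats.shape}"
            )
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.beats.shape[0],):
            raise ValueError("labels length must equal beat row count")
        if self.provenance is None:
            self.provenance = np.array([""] * self.beats.shape[0], dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if self.provenance.shape != (self.beats.shape[0],):
            raise ValueError("provenance length must equal beat row count")

    def __len__(self) -> int:
        return int(self.beats.shape[0])

    @property
    def classes(self) -> list[str]:
        """Sorted distinct subject labels."""
        return sorted({str(x) for x in self.labels})

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[str(lab)] = counts.get(str(lab), 0) + 1
        return counts

    def subset(self, idx: np.ndarray) -> "BeatDataset":
        idx = np.asarray(idx)
        return BeatDataset(self.beats[idx], self.labels[idx], self.provenance[idx])

    @staticmethod
    def from_beats(beats: list[Beat]) -> "BeatDataset":
        if not beats:
            return BeatDataset(np.empty((0, BEAT_LENGTH)), np.array([], dtype=object))
        return BeatDataset(
            np.stack([b.values for b in beats]),
            np.array([b.subject_id for b in beats], dtype=object),
            np.array([b.record_id for b in beats], dtype=object),
        )

    @staticmethod
    def concat(parts: list["BeatDataset"]) -> "BeatDataset":
        if not parts:
            raise ValueError("no datasets to concatenate")
        return BeatDataset(
            np.concatenate([p.beats for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.provenance for p in parts]),
        )
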