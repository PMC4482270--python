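"""Filtering, artifact excision, montage re-referencing, epoching.

The preprocessing contract is asymmetric by design: the network path is
band-passed 0.5-50 Hz (3rd-order Butterworth, zero phase) with a 60 Hz notch
and each 2 s window is normalized to zero mean and unit variance; the
spectral path is left unfiltered (multitaper estimation handles broadband
content itself) and windows are only demeaned.  Both paths excise annotated
artifacts and trim an extra 0.5 s on each side of every cut so that filter
edge effects at discontinuities never enter an analysis window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .channels import Montage, TEN_TWENTY_LABELS, build_montage

logger = logging.getLogger(__name__)

VALID_FS = (200, 256, 500, 512)
EPOCH_SECONDS = 2.0
TRIM_SECONDS = 0.5


@dataclass
class Recording:
    """One subject's multichannel scalp EEG with annotations and metadata.

    samples: (time x channel) array in microvolts.
    artifact_annotations: disjoint (start_s, stop_s) intervals to excise.
    state_segments: (start_s, stop_s, label) with label in {'wake', 'NREM'};
        an empty list means the whole record is wake.
    """

    subject_id: str
    fs: float
    samples: np.ndarray
    channel_labels: tuple[str, ...] = TEN_TWENTY_LABELS
    group_label: str = "control"
    subtype: str = "none"
    split: str = "training"
    artifact_annotations: list[tuple[float, float]] = field(default_factory=list)
    state_segments: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"samples must be (time x {len(self.channel_labels)}) for labels "
                f"{self.channel_labels}"
            )
        dur = self.duration
        for start, stop in self.artifact_annotations:
            if not (0 <= start < stop <= dur + 1e-9):
                raise ValueError(
                    f"artifact interval ({start}, {stop}) outside record [0, {dur:.2f}]"
                )

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.fs

    def clean_seconds(self) -> float:
        """Artifact-free duration after the 0.5 s trimming around each cut."""
        return sum(stop - start for start, stop, _ in clean_segments(self))


@dataclass
class Segment:
    """A contiguous artifact-free stretch of a recording (sample indices)."""

    start: int   # inclusive sample index into the original record
    stop: int    # exclusive
    recording: Recording

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class EpochSet:
    """Montaged derivation signals cut into normalized 2 s windows.

    ``epochs`` has shape (n_epochs, n_samples_per_epoch, n_derivations); no
    epoch spans an excision discontinuity and each is demeaned per derivation
    (and variance-normalized when ``normalization='demean+unit_variance'``).
    """

    subject_id: str
    fs: float
    montage_name: str
    derivation_labels: tuple[str, ...]
    epochs: np.ndarray
    normalization: str
    state_labels: tuple[str, ...] = ()

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def select_state(self, state: str) -> "EpochSet":
        if not self.state_labels:
            return self
        keep = [i for i, s in enumerate(self.state_labels) if s == state]
        return replace(
            self,
            epochs=self.epochs[keep],
            state_labels=tuple(self.state_labels[i] for i in keep),
        )


def apply_filters(recording: Recording, purpose: str) -> Recording:
    """Network-path band-pass + notch, or the identity for the spectral path.

    purpose='network': zero-phase 3rd-order Butterworth band-pass 0.5-50 Hz
    plus a 3rd-order 58-62 Hz band-stop notch (skipped with a warning when
    the Nyquist frequency does not clear 60 Hz).
    purpose='spectral': returns the recording unchanged.
    """
    if purpose == "spectral":
        return recording
    if purpose != "network":
        raise ValueError(f"purpose must be 'network' or 'spectral', got {purpose!r}")
    fs = recording.fs
    nyq = fs / 2.0
    x = recording.samples
    sos_band = signal.butter(3, [0.5, 50.0], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos_band, x, axis=0)
    if nyq > 62.0:
        sos_notch = signal.butter(3, [58.0, 62.0], btype="bandstop", fs=fs, output="sos")
        y = signal.sosfiltfilt(sos_notch, y, axis=0)
    elif nyq > 60.0:
        logger.warning(
            "fs=%g leaves no room for the 58-62 Hz notch; notch skipped", fs
        )
    return replace(recording, samples=y)


def _merge_intervals(intervals):
    merged = []
    for start, stop in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    return merged


def excise_artifacts(recording: Recording) -> list[Segment]:
    """Remove annotated artifacts plus 0.5 s on both sides of every cut.

    Returns the remaining clean stretches as :class:`Segment` objects; a
    stretch fully consumed by the trimming is dropped (logged).  The record's
    own start and end are not discontinuities and are not trimmed.
    """
    fs = recording.fs
    n = recording.samples.shape[0]
    trim = int(round(TRIM_SECONDS * fs))
    cuts = _merge_intervals(recording.artifact_annotations)
    segments: list[Segment] = []
    prev_stop = 0          # sample index where the current clean run began
    boundary_left = False  # does the current run start at a cut?
    for start_s, stop_s in cuts:
        a = int(round(start_s * fs))
        b = int(round(stop_s * fs))
        seg_start = prev_stop + (trim if boundary_left else 0)
        seg_stop = a - trim
        if seg_stop > seg_start:
            segments.append(Segment(seg_start, seg_stop, recording))
        elif a > prev_stop:
            logger.info(
                "clean stretch [%.2f, %.2f] s fully consumed by 0.5 s trimming",
                prev_stop / fs, a / fs,
            )
        prev_stop = b
        boundary_left = True
    seg_start = prev_stop + (trim if boundary_left else 0)
    if n > seg_start:
        segments.append(Segment(seg_start, n, recording))
    elif n > prev_stop:
        logger.info("trailing clean stretch consumed by trimming")
    return segments


def clean_segments(recording: Recording) -> list[tuple[float, float, float]]:
    """Clean stretches as (start_s, stop_s, duration_s) triples."""
    return [
        (s.start / recording.fs, s.stop / recording.fs, s.n_samples / recording.fs)
        for s in excise_artifacts(recording)
    ]


def _state_at(recording: Recording, t0: float, t1: float) -> str:
    """State label covering [t0, t1); defaults to wake when unannotated."""
    for start, stop, label in recording.state_segments:
        if start <= t0 and t1 <= stop + 1e-9:
            return label
    return "wake"


def make_epochs(
    segments: list[Segment],
    montage: Montage | str = "double_banana",
    normalization: str = "demean+unit_variance",
) -> EpochSet:
    """Cut clean segments into non-overlapping 2 s derivation epochs.

    Windows are aligned to each segment's start, so none spans a
    discontinuity; segments shorter than 2 s contribute nothing.  Each window
    is demeaned per derivation; with ``'demean+unit_variance'`` (the network
    path) each derivation trace is additionally scaled to unit variance.
    """
    if normalization not in ("demean", "demean+unit_variance"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if not segments:
        raise ValueError("no clean segments to epoch")
    rec = segments[0].recording
    if isinstance(montage, str):
        montage = build_montage(rec.channel_labels, montage)
    M = montage.matrix().T
    nper = int(round(EPOCH_SECONDS * rec.fs))
    blocks, states = [], []
    for seg in segments:
        n_ep = seg.n_samples // nper
        for k in range(n_ep):
            a = seg.start + k * nper
            x = seg.recording.samples[a:a + nper] @ M
            x = x - x.mean(axis=0)
            if normalization == "demean+unit_variance":
                sd = x.std(axis=0)
                sd[sd == 0] = 1.0
                x = x / sd
            blocks.append(x)
            states.append(_state_at(rec, a / rec.fs, (a + nper) / rec.fs))
    epochs = np.array(blocks) if blocks else np.empty((0, nper, montage.n_derivations))
    return EpochSet(
        subject_id=rec.subject_id,
        fs=rec.fs,
        montage_name=montage.name,
        derivation_labels=montage.derivation_names,
        epochs=epochs,
        normalization=normalization,
        state_labels=tuple(states),
    )


def preprocess_recording(
    recording: Recording,
    purpose: str,
    montage: str = "double_banana",
    state: str | None = "wake",
) -> EpochSet:
    """Full path: filter (per purpose) -> excise -> montage -> epoch."""
    filtered = apply_filters(recording, purpose)
    segs = excise_artifacts(filtered)
    norm = "demean+unit_variance" if purpose == "network" else "demean"
    es = make_epochs(segs, build_montage(recording.channel_labels, montage), norm)
    if state is not None:
        es = es.select_state(state)
    return es
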