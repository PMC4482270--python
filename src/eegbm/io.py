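"""Reading and writing recordings: delimited text, annotations, EDF.

The delimited-matrix format is a lossless TSV (header row of channel labels,
one row per sample, microvolts).  Annotations are TSV triples
(start_s, stop_s, label) where label is 'artifact' or a state name
('wake'/'NREM').  Metadata is JSON.  EDF support uses a minimal EDF writer
implemented here (16-bit quantization against a per-channel physical range)
and MNE's EDF reader, which also serves as an independent round-trip check
on the writer.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .channels import TEN_TWENTY_LABELS
from .preprocess import Recording


# ---------------------------------------------------------------------------
# Delimited matrix
# ---------------------------------------------------------------------------

def write_matrix(path, samples: np.ndarray, channel_labels) -> None:
    header = "\t".join(channel_labels)
    np.savetxt(path, samples, delimiter="\t", header=header, comments="",
               fmt="%.17g")


def read_matrix(path) -> tuple[np.ndarray, tuple[str, ...]]:
    with open(path) as fh:
        labels = tuple(fh.readline().rstrip("\n").split("\t"))
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if data.shape[1] != len(labels):
        raise ValueError(f"{path}: header lists {len(labels)} channels, "
                         f"data has {data.shape[1]} columns")
    return data, labels


# ---------------------------------------------------------------------------
# Annotations and metadata
# ---------------------------------------------------------------------------

def write_annotations(path, artifact_intervals, state_segments=()) -> None:
    with open(path, "w") as fh:
        for start, stop in artifact_intervals:
            fh.write(f"{start:.6f}\t{stop:.6f}\tartifact\n")
        for start, stop, label in state_segments:
            fh.write(f"{start:.6f}\t{stop:.6f}\t{label}\n")


def read_annotations(path):
    artifacts, states = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            start, stop, label = line.rstrip("\n").split("\t")
            if label == "artifact":
                artifacts.append((float(start), float(stop)))
            else:
                states.append((float(start), float(stop), label))
    return artifacts, states


def write_metadata(path, recording: Recording, seed: int | None = None) -> None:
    meta = {
        "subject_id": recording.subject_id,
        "group": recording.group_label,
        "subtype": recording.subtype,
        "split": recording.split,
        "fs": recording.fs,
    }
    if seed is not None:
        meta["seed"] = seed
    Path(path).write_text(json.dumps(meta, indent=1))


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# EDF (European Data Format): minimal writer + MNE reader
# ---------------------------------------------------------------------------

def write_edf(path, samples: np.ndarray, channel_labels, fs: float) -> None:
    """Write a (time x channel) microvolt array as a plain EDF file.

    One-second data records, 16-bit samples scaled to a per-channel physical
    range; a trailing partial second is zero-padded.  Requires an integer
    sampling rate.
    """
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    x = np.asarray(samples, float)
    n_samples, n_sig = x.shape
    n_records = int(np.ceil(n_samples / fs))
    pad = n_records * fs - n_samples
    if pad:
        x = np.vstack([x, np.zeros((pad, n_sig))])

    phys_max = np.maximum(np.abs(x).max(axis=0), 1.0) * 1.000001
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * gain + dig_min).astype("<i2")

    def pad_field(value, width):
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad_field("0", 8),                       # version
        pad_field("X X X X", 80),                # patient id (anonymous)
        pad_field("Startdate X X X X", 80),      # recording id
        pad_field("01.01.00", 8),                # start date
        pad_field("00.00.00", 8),                # start time
        pad_field(256 + 256 * n_sig, 8),         # header bytes
        pad_field("", 44),                       # reserved
        pad_field(n_records, 8),
        pad_field("1", 8),                       # record duration (s)
        pad_field(n_sig, 4),
    ])
    fields = [
        (16, [lab for lab in channel_labels]),                  # label
        (80, ["" for _ in range(n_sig)]),                       # transducer
        (8, ["uV" for _ in range(n_sig)]),                      # physical dim
        (8, [f"{v:.3f}"[:8] for v in phys_min]),
        (8, [f"{v:.3f}"[:8] for v in phys_max]),
        (8, [dig_min for _ in range(n_sig)]),
        (8, [dig_max for _ in range(n_sig)]),
        (80, ["" for _ in range(n_sig)]),                       # prefiltering
        (8, [fs for _ in range(n_sig)]),                        # samples/record
        (32, ["" for _ in range(n_sig)]),                       # reserved
    ]
    sig_header = b"".join(
        b"".join(pad_field(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for rec in range(n_records):
            block = digital[rec * fs:(rec + 1) * fs]  # (fs, n_sig)
            fh.write(block.T.tobytes())


def read_edf(path) -> tuple[np.ndarray, tuple[str, ...], float]:
    """Read an EDF file via MNE; returns (samples uV, labels, fs)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # volts -> microvolts
    return data, tuple(raw.ch_names), float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# Subject-level fixture round trip
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, directory, fmt: str = "delimited",
                    seed: int | None = None) -> dict:
    """Write one subject's signal + annotation + metadata files.

    Returns the file paths written, keyed by role.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = recording.subject_id
    if fmt == "delimited":
        signal_path = directory / f"{sid}_signal.tsv"
        write_matrix(signal_path, recording.samples, recording.channel_labels)
    elif fmt == "edf":
        signal_path = directory / f"{sid}.edf"
        write_edf(signal_path, recording.samples, recording.channel_labels,
                  recording.fs)
    else:
        raise ValueError(f"format must be 'delimited' or 'edf', got {fmt!r}")
    ann_path = directory / f"{sid}_annotations.tsv"
    meta_path = directory / f"{sid}_metadata.json"
    write_annotations(ann_path, recording.artifact_annotations,
                      recording.state_segments)
    write_metadata(meta_path, recording, seed=seed)
    return {"signal": signal_path, "annotations": ann_path, "metadata": meta_path}


def read_recording(signal_path, annotations_path=None, metadata_path=None,
                   fs: float | None = None) -> Recording:
    """Reconstruct a Recording from its files (delimited or EDF signal)."""
    signal_path = Path(signal_path)
    if signal_path.suffix.lower() == ".edf":
        samples, labels, fs = read_edf(signal_path)
    else:
        samples, labels = read_matrix(signal_path)
    meta = read_metadata(metadata_path) if metadata_path else {}
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise ValueError("sampling rate unavailable: pass fs or a metadata file")
    artifacts, states = ([], [])
    if annotations_path:
        artifacts, states = read_annotations(annotations_path)
    return Recording(
        subject_id=meta.get("subject_id", signal_path.stem),
        fs=float(fs),
        samples=samples,
        channel_labels=tuple(labels),
        group_label=meta.get("group", "control"),
        subtype=meta.get("subtype", "none"),
        split=meta.get("split", "training"),
        artifact_annotations=artifacts,
        state_segments=states,
    )


def read_cohort(directory) -> list[Recording]:
    """Read every subject fixture under a directory (by metadata files)."""
    directory = Path(directory)
    recordings = []
    for meta_path in sorted(directory.glob("*_metadata.json")):
        sid = meta_path.name[: -len("_metadata.json")]
        tsv = directory / f"{sid}_signal.tsv"
        edf = directory / f"{sid}.edf"
        signal = tsv if tsv.exists() else edf
        if not signal.exists():
            raise FileNotFoundError(f"no signal file for subject {sid}")
        recordings.append(
            read_recording(signal, directory / f"{sid}_annotations.tsv", meta_path)
        )
    return recordings
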