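"""Reading, validation, epoching and grouping of multi-channel EEG.

Data layout convention: all sample arrays are time-major, ``[n_samples,
n_channels]``, in microvolts.  Epoch start offsets are 0-based seconds,
half-open windows ``[start, start + window)``.

The 32-electrode montage follows the international 10-20 system.  One label
in the canonical list is "FC" where the standard name is "FC2"; the constant
reproduces the acquisition montage verbatim and "FC2" is accepted as an
alias on input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, MontageError

logger = logging.getLogger(__name__)

#: Canonical 32-channel 10-20 montage of the acquisition system, in order.
CANONICAL_CHANNEL_NAMES: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC", "Cz",
    "C4", "T8", "Cp6", "Cp2", "P4", "P8", "PO4", "O2",
)

#: Accepted alternative spellings (standard 10-20 name -> montage label).
CHANNEL_ALIASES: dict[str, str] = {"fc2": "fc"}

#: Preprocessed sampling rate of the acquisition protocol, Hz.
DEFAULT_FS = 128.0

#: Epoch window length, seconds (4 s = 512 samples at 128 Hz).
DEFAULT_WINDOW_S = 4.0

#: Overlap fraction between successive epochs (stride = 2 s).
DEFAULT_OVERLAP = 0.5

#: Number of epochs per model input group.
DEFAULT_GROUP_SIZE = 8


def _norm_name(name: str) -> str:
    key = name.strip().lower()
    return CHANNEL_ALIASES.get(key, key)


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels of a recording montage."""

    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        keys = [_norm_name(n) for n in names]
        if len(set(keys)) != len(keys):
            raise MontageError(f"duplicate channel names in montage: {names}")

    def __len__(self) -> int:
        return len(self.channel_names)

    def index_of(self, name: str) -> int:
        """Index of ``name`` (case-insensitive, alias-aware)."""
        keys = [_norm_name(n) for n in self.channel_names]
        try:
            return keys.index(_norm_name(name))
        except ValueError:
            raise MontageError(f"channel {name!r} not in montage") from None

    def indices_of(self, names: Iterable[str]) -> list[int]:
        return [self.index_of(n) for n in names]


def canonical_montage() -> Montage:
    """The 32-channel 10-20 montage used by the acquisition protocol."""
    return Montage(CANONICAL_CHANNEL_NAMES)


@dataclass
class Recording:
    """One subject x clip multi-channel EEG segment.

    ``samples`` is time-major ``[n_samples, n_channels]`` in microvolts.
    ``label`` encodes emotion: -1 negative, 0 neutral, +1 positive.
    """

    samples: np.ndarray
    fs: float
    montage: Montage
    label: int
    subject_id: str = "s0"
    clip_id: str = "c0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] == 0:
            raise DataError("samples must be a non-empty [time x channels] matrix")
        if self.samples.shape[1] != len(self.montage):
            raise DataError(
                f"{self.samples.shape[1]} channels but montage has {len(self.montage)}"
            )
        if not self.fs > 0:
            raise DataError("sampling rate must be positive")
        if self.label not in (-1, 0, 1):
            raise DataError(f"label must be in {{-1, 0, +1}}, got {self.label}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """A fixed-length window cut from a Recording."""

    samples: np.ndarray  # [epoch_len x channels]
    start_s: float
    label: int
    subject_id: str = "s0"
    clip_id: str = "c0"


@dataclass
class EpochGroup:
    """G epochs of one label (and one subject), ordered by start time."""

    epochs: list[Epoch]
    label: int

    def __post_init__(self) -> None:
        if any(e.label != self.label for e in self.epochs):
            raise DataError("all epochs in a group must share one label")

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def subject_id(self) -> str:
        return self.epochs[0].subject_id

    def as_array(self) -> np.ndarray:
        """Stack member epochs into ``[G, epoch_len, n_channels]``."""
        return np.stack([e.samples for e in self.epochs])


# ---------------------------------------------------------------------------
# Reading

def _reorder(data: np.ndarray, names: Sequence[str], montage: Montage) -> np.ndarray:
    """Reorder columns of ``data`` (named ``names``) to ``montage`` order."""
    have = {_norm_name(n): i for i, n in enumerate(names)}
    cols = []
    for want in montage.channel_names:
        key = _norm_name(want)
        if key not in have:
            raise MontageError(f"channel {want!r} missing from input header")
        cols.append(have[key])
    return data[:, cols]


def read_recording(
    path: str | Path,
    expected_montage: Montage | None = None,
    fs: float | None = None,
    label: int = 0,
    subject_id: str = "s0",
    clip_id: str = "c0",
) -> Recording:
    """Read an EDF or delimited-text recording, reordered to the montage.

    EDF files carry their own sampling rate and channel names; delimited
    text (CSV/TSV) needs a channel-name header row and an explicit ``fs``.
    Channel matching is case-insensitive and accepts the FC2/FC alias.
    """
    path = Path(path)
    montage = expected_montage or canonical_montage()
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data().T * 1e6  # volts -> microvolts, time-major
        names = raw.ch_names
        rate = float(raw.info["sfreq"])
    else:
        try:
            df = pd.read_csv(path, sep=None, engine="python")
        except Exception as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            raise FormatError(f"non-numeric payload in {path}")
        if fs is None:
            raise DataError("fs must be given for delimited-text input")
        data = df.to_numpy(dtype=np.float64)
        names = list(df.columns)
        rate = float(fs)
    data = _reorder(data, names, montage)
    return Recording(data, rate, montage, label, subject_id, clip_id)


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV with a channel-name header row."""
    df = pd.DataFrame(rec.samples, columns=list(rec.montage.channel_names))
    df.to_csv(path, index=False, float_format="%.6f")


def write_recording_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as a minimal EDF file (16-bit, 1-s data records).

    Physical range is taken from the data; samples are quantized to the
    EDF 16-bit digital range.  The trailing partial second is dropped.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise DataError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record, per signal
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise DataError("recording shorter than one EDF data record (1 s)")
    data = rec.samples[: n_rec * spr]
    n_sig = data.shape[1]
    pmin = float(np.floor(data.min() - 1.0))
    pmax = float(np.ceil(data.max() + 1.0))
    dmin, dmax = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_sig)), 8), pad("EDF", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_sig), 4),
    ])
    names = list(rec.montage.channel_names)
    header += b"".join(pad(n, 16) for n in names)
    header += b"".join(pad("AgAgCl electrode", 80) for _ in names)
    header += b"".join(pad("uV", 8) for _ in names)
    header += b"".join(pad(f"{pmin:g}", 8) for _ in names)
    header += b"".join(pad(f"{pmax:g}", 8) for _ in names)
    header += b"".join(pad(str(dmin), 8) for _ in names)
    header += b"".join(pad(str(dmax), 8) for _ in names)
    header += b"".join(pad("", 80) for _ in names)
    header += b"".join(pad(str(spr), 8) for _ in names)
    header += b"".join(pad("", 32) for _ in names)

    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            chunk = data[r * spr:(r + 1) * spr]  # [spr x n_sig]
            dig = np.round((chunk - pmin) * scale + dmin).astype("<i2")
            # EDF stores each signal's samples contiguously within a record
            fh.write(dig.T.tobytes())


# ---------------------------------------------------------------------------
# Epoching

def epoch_recording(
    rec: Recording,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP,
) -> list[Epoch]:
    """Cut overlapped fixed-length epochs from a recording.

    Epoch starts sit on a fixed grid every ``stride = window_s *
    (1 - overlap_frac)`` seconds over ``[0, T)``; windows whose end runs
    past the recording wrap circularly to its start, so the count is
    exactly ``floor(T / stride)``.  At the protocol's 4-s window with 50%
    overlap this yields 240 epochs from 8 min and 360 from 12 min.
    """
    if not 0 <= overlap_frac < 1:
        raise DataError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    win = window_s * rec.fs
    if abs(win - round(win)) > 1e-6:
        raise DataError(f"window_s * fs = {win} is not an integer sample count")
    win = int(round(win))
    if win <= 0:
        raise DataError("window must be positive")
    if win > rec.n_samples:
        raise DataError(
            f"window of {win} samples exceeds recording of {rec.n_samples}"
        )
    stride_s = window_s * (1.0 - overlap_frac)
    stride = stride_s * rec.fs
    if abs(stride - round(stride)) > 1e-6 or round(stride) < 1:
        raise DataError(f"stride of {stride} samples is not a positive integer")
    stride = int(round(stride))
    n_epochs = rec.n_samples // stride
    idx = np.arange(win)
    out = []
    for k in range(n_epochs):
        rows = (k * stride + idx) % rec.n_samples  # circular wrap of the tail
        out.append(
            Epoch(
                samples=rec.samples[rows],
                start_s=k * stride / rec.fs,
                label=rec.label,
                subject_id=rec.subject_id,
                clip_id=rec.clip_id,
            )
        )
    return out


def group_epochs(
    epochs: Sequence[Epoch],
    G: int = DEFAULT_GROUP_SIZE,
    seed: int = 0,
) -> list[EpochGroup]:
    """Partition epochs into same-label, same-subject groups of size G.

    Within each (label, subject) partition, epochs are ordered by
    (clip_id, start_s) and cut into consecutive non-overlapping runs of G;
    leftovers shorter than G are dropped.  ``seed`` shuffles only the order
    of the returned groups, never their membership.
    """
    if G < 1:
        raise DataError(f"group size must be >= 1, got {G}")
    by_key: dict[tuple[int, str], list[Epoch]] = {}
    for ep in epochs:
        by_key.setdefault((ep.label, ep.subject_id), []).append(ep)
    groups: list[EpochGroup] = []
    for (label, _subject), eps in sorted(by_key.items(), key=lambda kv: kv[0]):
        eps = sorted(eps, key=lambda e: (e.clip_id, e.start_s))
        n_full = len(eps) // G
        if n_full == 0:
            logger.warning(
                "label %d / subject %s: %d epochs < group size %d, dropped",
                label, _subject, len(eps), G,
            )
        for i in range(n_full):
            groups.append(EpochGroup(eps[i * G:(i + 1) * G], label))
    labels_seen = {ep.label for ep in epochs}
    for label in labels_seen:
        if not any(g.label == label for g in groups):
            logger.warning("label %d yields zero groups", label)
    rng = np.random.default_rng(seed)
    rng.shuffle(groups)
    return groups


# ---------------------------------------------------------------------------
# Epoch-set serialization

def save_epoch_set(
    groups: Sequence[EpochGroup],
    out_dir: str | Path,
    fs: float,
    window_s: float,
    overlap_frac: float,
    montage: Montage | None = None,
) -> Path:
    """Write grouped epochs as ``epochs.npz`` plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    montage = montage or canonical_montage()
    arr = np.stack([g.as_array() for g in groups]).astype(np.float32)
    labels = np.array([g.label for g in groups], dtype=np.int64)
    subjects = np.array([g.subject_id for g in groups])
    np.savez(out_dir / "epochs.npz", groups=arr, labels=labels, subjects=subjects)
    manifest = {
        "fs": fs,
        "window_s": window_s,
        "overlap_frac": overlap_frac,
        "group_size": int(arr.shape[1]),
        "n_groups": int(arr.shape[0]),
        "montage": list(montage.channel_names),
        "labels": sorted(int(v) for v in set(labels.tolist())),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir


def load_epoch_set(in_dir: str | Path) -> tuple[list[EpochGroup], dict]:
    """Inverse of :func:`save_epoch_set`."""
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    npz = np.load(in_dir / "epochs.npz", allow_pickle=False)
    arr, labels, subjects = npz["groups"], npz["labels"], npz["subjects"]
    stride_s = manifest["window_s"] * (1.0 - manifest["overlap_frac"])
    groups = []
    for gi in range(arr.shape[0]):
        eps = [
            Epoch(arr[gi, ei].astype(np.float64), start_s=ei * stride_s,
                  label=int(labels[gi]), subject_id=str(subjects[gi]))
            for ei in range(arr.shape[1])
        ]
        groups.append(EpochGroup(eps, int(labels[gi])))
    return groups, manifest
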