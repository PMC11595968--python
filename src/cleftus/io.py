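"""Domain types and file I/O.

The corpus layout mirrors publicly documented ultrasound-tongue-imaging
collections: one manifest (CSV or JSON) listing participants and their
utterances, each utterance pointing at a directory of PNG ultrasound frames
with a small ``key=value`` sidecar, and a synchronized mono PCM WAV.

Three cleft classes are modelled: cleft palate only (CP), unilateral cleft
lip and palate (UCLP) and bilateral cleft lip and palate (BCLP).  Their
ordinal indices (CP=0, UCLP=1, BCLP=2) are fixed and used everywhere a tie
must be broken deterministically.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, IntegrityError, ReferentialError, SchemaError

__all__ = [
    "CleftLabel",
    "Sex",
    "Participant",
    "Utterance",
    "FrameSequence",
    "AudioSignal",
    "Manifest",
    "load_manifest",
    "save_manifest",
    "read_frame_sequence",
    "read_audio",
    "read_sidecar",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "participant_id",
    "label",
    "sex",
    "age_years",
    "utterance_id",
    "frames_path",
    "params_path",
    "audio_path",
    "prompt",
]

#: columns that must be present; the remainder may be empty but the header
#: must still carry them for CSV round-trips.
_REQUIRED_COLUMNS = [
    "participant_id",
    "label",
    "utterance_id",
    "frames_path",
    "params_path",
    "audio_path",
]

_SIDECAR_KEYS = ("fps", "width", "height", "n_frames")


class CleftLabel(enum.IntEnum):
    """Cleft type. The integer value is the fixed tie-breaking ordinal."""

    CP = 0
    UCLP = 1
    BCLP = 2

    @classmethod
    def from_string(cls, s: str) -> "CleftLabel":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            admissible = ", ".join(m.name for m in cls)
            raise ValueError(
                f"unknown cleft label {s!r}; admissible labels: {admissible}"
            ) from None


class Sex(enum.Enum):
    M = "M"
    F = "F"
    UNKNOWN = "unknown"

    @classmethod
    def from_string(cls, s: str | None) -> "Sex":
        if s is None:
            return cls.UNKNOWN
        s = str(s).strip()
        if s == "" or s.lower() in ("unknown", "nan", "none"):
            return cls.UNKNOWN
        if s.upper() in ("M", "MALE"):
            return cls.M
        if s.upper() in ("F", "FEMALE"):
            return cls.F
        raise ValueError(f"unknown sex {s!r}; admissible: M, F, unknown")


@dataclass(frozen=True)
class Participant:
    id: str
    label: CleftLabel
    sex: Sex = Sex.UNKNOWN
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.age_years is not None and (
            math.isnan(self.age_years) or self.age_years < 0
        ):
            object.__setattr__(self, "age_years", None)


@dataclass(frozen=True)
class Utterance:
    participant_id: str
    utterance_id: str
    frames_path: Path
    params_path: Path
    audio_path: Path
    prompt: str = ""


@dataclass
class FrameSequence:
    """An ordered stack of equally sized 2-D ultrasound frames."""

    frames: np.ndarray  # (n_frames, height, width), uint8 or float
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) stack")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class AudioSignal:
    """Mono audio, samples scaled to [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D (mono)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class Manifest:
    participants: list[Participant] = field(default_factory=list)
    utterances: list[Utterance] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(ids) != len(set(ids)):
            raise ReferentialError("duplicate participant ids in manifest")
        known = set(ids)
        for u in self.utterances:
            if u.participant_id not in known:
                raise ReferentialError(
                    f"utterance {u.utterance_id!r} references unknown "
                    f"participant {u.participant_id!r}"
                )
        keys = [(u.participant_id, u.utterance_id) for u in self.utterances]
        if len(keys) != len(set(keys)):
            raise ReferentialError("duplicate (participant_id, utterance_id) pair")

    def participant(self, pid: str) -> Participant:
        for p in self.participants:
            if p.id == pid:
                return p
        raise KeyError(pid)

    @property
    def classes_present(self) -> set[CleftLabel]:
        return {p.label for p in self.participants}

    @property
    def trainable(self) -> bool:
        """True when the manifest can back a training run: at least one
        utterance and every class represented."""
        return bool(self.utterances) and self.classes_present == set(CleftLabel)


def _rows_to_manifest(rows: list[dict], base: Path | None, check_paths: bool) -> Manifest:
    participants: dict[str, Participant] = {}
    utterances: list[Utterance] = []
    for i, row in enumerate(rows):
        for col in _REQUIRED_COLUMNS:
            if col not in row or row[col] in (None, ""):
                raise SchemaError(f"row {i}: missing required column {col!r}")
        pid = str(row["participant_id"])
        label = CleftLabel.from_string(str(row["label"]))
        sex = Sex.from_string(row.get("sex"))
        age_raw = row.get("age_years")
        age = None
        if age_raw not in (None, ""):
            age = float(age_raw)
            if math.isnan(age):
                age = None
        p = Participant(id=pid, label=label, sex=sex, age_years=age)
        if pid in participants:
            if participants[pid].label != label:
                raise ReferentialError(
                    f"participant {pid!r} listed with conflicting labels"
                )
        else:
            participants[pid] = p

        def _resolve(key: str) -> Path:
            path = Path(str(row[key]))
            if base is not None and not path.is_absolute():
                path = base / path
            if check_paths and not path.exists():
                raise ReferentialError(f"row {i}: {key} {path} does not exist")
            return path

        utterances.append(
            Utterance(
                participant_id=pid,
                utterance_id=str(row["utterance_id"]),
                frames_path=_resolve("frames_path"),
                params_path=_resolve("params_path"),
                audio_path=_resolve("audio_path"),
                prompt=str(row.get("prompt") or ""),
            )
        )
    return Manifest(participants=list(participants.values()), utterances=utterances)


def load_manifest(path: str | Path, check_paths: bool = True) -> Manifest:
    """Load and validate a manifest from CSV or JSON.

    Paths inside the manifest are resolved relative to the manifest's own
    directory.  Row order is preserved.  With ``check_paths`` (the default)
    every referenced file/directory must exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise SchemaError("JSON manifest must be a list of row objects")
        rows = data
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"manifest missing required column(s): {missing}")
        rows = df.to_dict(orient="records")
    return _rows_to_manifest(rows, base=path.parent, check_paths=check_paths)


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest as CSV (default) or JSON, one row per utterance.

    Paths are written relative to the manifest's directory when possible so
    the corpus stays relocatable.
    """
    path = Path(path)
    base = path.parent.resolve()
    by_id = {p.id: p for p in manifest.participants}

    def _rel(p: Path) -> str:
        try:
            return str(Path(p).resolve().relative_to(base))
        except ValueError:
            return str(p)

    rows = []
    for u in manifest.utterances:
        p = by_id[u.participant_id]
        rows.append(
            {
                "participant_id": p.id,
                "label": p.label.name,
                "sex": p.sex.value if p.sex != Sex.UNKNOWN else "",
                "age_years": "" if p.age_years is None else repr(p.age_years),
                "utterance_id": u.utterance_id,
                "frames_path": _rel(u.frames_path),
                "params_path": _rel(u.params_path),
                "audio_path": _rel(u.audio_path),
                "prompt": u.prompt,
            }
        )
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_sidecar(path: str | Path) -> dict[str, float]:
    """Parse a ``key=value`` sidecar; fps/width/height/n_frames required."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise SchemaError(f"sidecar line without '=': {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = float(value.strip())
    missing = [k for k in _SIDECAR_KEYS if k not in out]
    if missing:
        raise SchemaError(f"sidecar {path} missing key(s): {missing}")
    return out


def read_frame_sequence(
    frames_path: str | Path, params_path: str | Path
) -> FrameSequence:
    """Load a directory of PNG frames as an ordered stack.

    Frames are taken in lexicographic filename order regardless of directory
    listing order.  The sidecar's declared n_frames / width / height must
    match the files on disk.
    """
    frames_path = Path(frames_path)
    params = read_sidecar(params_path)
    files = sorted(frames_path.glob("*.png"))
    n_declared = int(params["n_frames"])
    if len(files) != n_declared:
        raise IntegrityError(
            f"{frames_path}: sidecar declares {n_declared} frames, "
            f"found {len(files)} PNG files"
        )
    if not files:
        raise IntegrityError(f"{frames_path}: no frames")
    arrays = []
    for f in files:
        with Image.open(f) as im:
            arrays.append(np.asarray(im.convert("L"), dtype=np.uint8))
    shape = arrays[0].shape
    for f, a in zip(files, arrays):
        if a.shape != shape:
            raise IntegrityError(
                f"{f}: frame size {a.shape[::-1]} differs from first frame "
                f"{shape[::-1]}"
            )
    h, w = shape
    if (w, h) != (int(params["width"]), int(params["height"])):
        raise IntegrityError(
            f"{frames_path}: frames are {w}x{h} but sidecar declares "
            f"{int(params['width'])}x{int(params['height'])}"
        )
    return FrameSequence(frames=np.stack(arrays), fps=float(params["fps"]))


def read_audio(audio_path: str | Path) -> AudioSignal:
    """Read a PCM WAV as a mono signal scaled to [-1, 1].

    Stereo (or any multichannel) input is averaged across channels.  Integer
    PCM is scaled by the magnitude of its most negative representable value,
    so a full-scale square wave maps to {-1.0, +1.0} up to one quantization
    step.
    """
    from scipy.io import wavfile

    try:
        rate, data = wavfile.read(audio_path)
    except Exception as exc:  # scipy raises bare ValueError on bad payloads
        raise FormatError(f"cannot read WAV {audio_path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"unsupported WAV sample format {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    elif samples.ndim != 1:
        raise FormatError("WAV payload has unexpected dimensionality")
    return AudioSignal(samples=samples, sample_rate=int(rate))


def manifests_equal(a: Manifest, b: Manifest) -> bool:
    """Field-by-field equality, resolving paths before comparison."""
    if len(a.participants) != len(b.participants):
        return False
    if len(a.utterances) != len(b.utterances):
        return False
    for pa, pb in zip(a.participants, b.participants):
        age_ok = (
            (pa.age_years is None and pb.age_years is None)
            or (
                pa.age_years is not None
                and pb.age_years is not None
                and math.isclose(pa.age_years, pb.age_years)
            )
        )
        if not (pa.id == pb.id and pa.label == pb.label and pa.sex == pb.sex and age_ok):
            return False
    for ua, ub in zip(a.utterances, b.utterances):
        if not (
            ua.participant_id == ub.participant_id
            and ua.utterance_id == ub.utterance_id
            and Path(ua.frames_path).resolve() == Path(ub.frames_path).resolve()
            and Path(ua.params_path).resolve() == Path(ub.params_path).resolve()
            and Path(ua.audio_path).resolve() == Path(ub.audio_path).resolve()
            and ua.prompt == ub.prompt
        ):
            return False
    return True
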