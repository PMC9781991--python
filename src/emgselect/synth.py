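"""Seeded synthetic surface-EMG databases.

Real multi-channel EMG recordings of repeated limb movements are emulated as
band-limited (10–500 Hz) zero-mean Gaussian noise whose amplitude envelope is
modulated by the movement: each non-rest class drives a fixed subset of
channels through a trapezoidal activation envelope, while the rest class (and
the initial relaxation phase of every trial) stays at a low baseline.  A
multiplicative per-subject gain (log-normal, sigma = 0.1) makes cross-subject
pooling non-trivial.  The generator is fully deterministic given its seed.

This is a statistical stand-in for a private human-subject database: it
reproduces the structure (subjects × movements × repetitions, channel count,
sampling rate, durations) and the amplitude contrasts that time-domain
features respond to, not motor-unit physiology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import FormatError, ParameterError

#: baseline (resting) noise amplitude relative to the unit movement amplitude
BASELINE_LEVEL = 0.05
#: rise/fall time of the trapezoidal activation envelope, seconds
RAMP_S = 0.25


@dataclass(frozen=True)
class DatabaseSpec:
    """Layout of a synthetic EMG database.

    Defaults mirror a lower-limb protocol: 8 subjects, 7 movement classes
    (six active + rest), 20 repetitions, 4 bipolar channels sampled at
    1 kHz for 7 s with 1 s of initial relaxation.
    """

    n_subjects: int = 8
    movement_names: tuple[str, ...] = ("AP", "AT", "LP", "LT", "PD", "PI", "RR")
    n_reps: int = 20
    n_channels: int = 4
    fs: float = 1000.0
    duration: float = 7.0
    rest_lead: float = 1.0
    seed: int = 0
    rest_name: str = "RR"

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_reps < 1 or self.n_channels < 1:
            raise ParameterError("n_subjects, n_reps and n_channels must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ParameterError("fs and duration must be positive")
        if not self.movement_names:
            raise ParameterError("movement_names must be non-empty")
        if len(set(self.movement_names)) != len(self.movement_names):
            raise ParameterError("movement_names must be unique")
        if not 0 <= self.rest_lead < self.duration:
            raise ParameterError("rest_lead must satisfy 0 <= rest_lead < duration")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def n_recordings(self) -> int:
        return self.n_subjects * len(self.movement_names) * self.n_reps


@dataclass
class Recording:
    """One multi-channel EMG trial.

    ``samples`` is channel-major, shape ``(n_channels, n_samples)``, in
    arbitrary (unit-scaled) amplitude units.
    """

    samples: np.ndarray
    fs: float
    subject: int
    movement: str
    repetition: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ParameterError("samples must be 2-D (n_channels, n_samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def activation_map(movement_names: tuple[str, ...], n_channels: int, rest_name: str) -> np.ndarray:
    """Fixed class -> channel activation amplitudes, shape (n_classes, n_channels).

    Class ``j`` (rest excluded) drives a primary channel ``j % n_channels``
    strongly, a secondary channel moderately, and all channels weakly — so
    every movement has a distinct amplitude signature across channels.
    The rest class is zero everywhere (baseline only).
    """
    amps = np.full((len(movement_names), n_channels), 0.2)
    active = 0
    for j, name in enumerate(movement_names):
        if name == rest_name:
            amps[j, :] = 0.0
            continue
        amps[j, active % n_channels] = 1.5
        amps[j, (active + 1) % n_channels] += 0.5
        active += 1
    return amps


def _band_limit(white: np.ndarray, fs: float) -> np.ndarray:
    """Shape white noise into the 10–500 Hz surface-EMG band (4th-order Butterworth)."""
    high = min(500.0, 0.99 * fs / 2.0)
    b, a = signal.butter(2, [10.0, high], btype="band", fs=fs)
    return signal.lfilter(b, a, white, axis=-1)


def _envelope(spec: DatabaseSpec, amp: np.ndarray) -> np.ndarray:
    """Trapezoidal activation envelope, shape (n_channels, n_samples).

    Baseline during the initial rest_lead, then ramps up over RAMP_S,
    holds at the class/channel amplitude, and ramps back down at the end
    of the trial.
    """
    t = np.arange(spec.n_samples) / spec.fs
    up0 = spec.rest_lead
    up1 = min(up0 + RAMP_S, spec.duration)
    dn1 = spec.duration
    dn0 = max(dn1 - RAMP_S, up1)
    shape = np.interp(t, [0.0, up0, up1, dn0, dn1], [0.0, 0.0, 1.0, 1.0, 0.0])
    return BASELINE_LEVEL + np.outer(amp, shape)


def generate_database(spec: DatabaseSpec) -> list[Recording]:
    """Generate the full subjects × movements × repetitions collection.

    Deterministic: the same spec (including seed) yields bit-identical
    sample arrays; per-recording streams are derived with
    ``numpy.random.SeedSequence.spawn`` so recordings are independent.
    """
    amps = activation_map(spec.movement_names, spec.n_channels, spec.rest_name)
    root = np.random.SeedSequence(spec.seed)
    subject_ss, rec_ss = root.spawn(2)
    # one multiplicative gain per subject, drawn once
    gains = np.exp(
        np.random.default_rng(subject_ss).normal(0.0, 0.1, size=spec.n_subjects)
    )
    streams = rec_ss.spawn(spec.n_recordings)
    recordings: list[Recording] = []
    i = 0
    for s in range(spec.n_subjects):
        for j, movement in enumerate(spec.movement_names):
            env = _envelope(spec, amps[j]) * gains[s]
            for r in range(spec.n_reps):
                rng = np.random.default_rng(streams[i])
                i += 1
                noise = _band_limit(
                    rng.standard_normal((spec.n_channels, spec.n_samples)), spec.fs
                )
                recordings.append(
                    Recording(
                        samples=env * noise,
                        fs=spec.fs,
                        subject=s,
                        movement=movement,
                        repetition=r,
                    )
                )
    return recordings


# ---------------------------------------------------------------------------
# delimited-text persistence
# ---------------------------------------------------------------------------

_META_KEYS = ("fs", "subject", "movement", "repetition")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write one recording as CSV: ``# key=value`` metadata header lines,
    then one column per channel (``ch1..chN``)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# subject={rec.subject}\n")
        fh.write(f"# movement={rec.movement}\n")
        fh.write(f"# repetition={rec.repetition}\n")
        header = ",".join(f"ch{c + 1}" for c in range(rec.n_channels))
        fh.write(header + "\n")
        np.savetxt(fh, rec.samples.T, delimiter=",", fmt="%.12g")


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` naming the offending line for empty files,
    missing metadata, non-numeric cells, or rows with unequal column counts.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    header: list[str] | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise FormatError(f"{path}:{lineno}: malformed metadata line {line!r}")
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
            elif header is None:
                header = [c.strip() for c in line.split(",")]
            else:
                data_lines.append((lineno, line))
    if header is None or not data_lines:
        raise FormatError(f"{path}: empty or headerless recording file")
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata keys {missing}")
    n_channels = len(header)
    rows = np.empty((len(data_lines), n_channels))
    for i, (lineno, line) in enumerate(data_lines):
        cells = line.split(",")
        if len(cells) != n_channels:
            raise FormatError(
                f"{path}:{lineno}: expected {n_channels} columns, found {len(cells)}"
            )
        try:
            rows[i] = [float(c) for c in cells]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    return Recording(
        samples=rows.T,
        fs=float(meta["fs"]),
        subject=int(meta["subject"]),
        movement=meta["movement"],
        repetition=int(meta["repetition"]),
    )


def write_database(recordings: list[Recording], directory: str | Path) -> Path:
    """Write a database as one CSV per recording plus a metadata table.

    Returns the path of the metadata CSV (columns
    ``file,subject,movement,repetition,fs``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"s{rec.subject}_{rec.movement}_r{rec.repetition}.csv"
        write_recording(rec, directory / fname)
        rows.append(
            {
                "file": fname,
                "subject": rec.subject,
                "movement": rec.movement,
                "repetition": rec.repetition,
                "fs": rec.fs,
            }
        )
    meta_path = directory / "metadata.csv"
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    return meta_path


def read_database(meta_path: str | Path) -> list[Recording]:
    """Read every recording listed in a metadata table written by
    :func:`write_database`."""
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path)
    required = {"file", "subject", "movement", "repetition", "fs"}
    if not required.issubset(meta.columns):
        raise FormatError(f"{meta_path}: metadata table must have columns {sorted(required)}")
    return [read_recording(meta_path.parent / row.file) for row in meta.itertuples()]
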