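"""Epoch matrices: synthetic ECG generation, segmentation and CSV I/O.

An *epoch* is a fixed-length, non-overlapping slice of a continuous ECG
recording; it is the unit sample of the whole pipeline.  Arrhythmia
classes (VT, PVC, ST) are sampled at 360 Hz with 360-sample epochs;
normal sinus rhythm (NSR) is sampled at 128 Hz with 128-sample epochs.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

CLASS_LABELS = ("VT", "PVC", "ST", "NSR")

#: per-class (epoch length in samples, sampling frequency in Hz)
CLASS_SHAPE = {
    "VT": (360, 360.0),
    "PVC": (360, 360.0),
    "ST": (360, 360.0),
    "NSR": (128, 128.0),
}

#: default heart rate per class, beats per minute
CLASS_RATE = {"VT": 190.0, "PVC": 75.0, "ST": 80.0, "NSR": 75.0}


@dataclass
class EpochMatrix:
    """Fixed-length signal epochs with per-epoch class labels.

    Attributes
    ----------
    data : (n_epochs, epoch_length) float array
    fs : sampling frequency in Hz
    labels : (n_epochs,) array of class tags from {VT, PVC, ST, NSR}
    provenance : free-text source tag
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D epochs-by-samples matrix")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.data.shape[1] <= 0:
            raise ValueError("epoch_length must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"labels has {len(self.labels)} entries for "
                f"{self.data.shape[0]} epochs"
            )
        unknown = set(self.labels) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def epoch_length(self) -> int:
        return self.data.shape[1]

    def subset(self, idx: np.ndarray, note: str = "") -> "EpochMatrix":
        """Row subset preserving labels; `note` is appended to provenance."""
        prov = self.provenance + (f"; {note}" if note else "")
        return EpochMatrix(self.data[idx], self.fs, self.labels[idx], prov)

    @staticmethod
    def concat(parts: list["EpochMatrix"]) -> "EpochMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        lengths = {p.epoch_length for p in parts}
        fss = {p.fs for p in parts}
        if len(lengths) > 1 or len(fss) > 1:
            raise ValueError(
                "cannot concatenate epoch matrices with differing "
                f"epoch_length {lengths} or fs {fss}"
            )
        return EpochMatrix(
            np.vstack([p.data for p in parts]),
            parts[0].fs,
            np.concatenate([p.labels for p in parts]),
            "; ".join(p.provenance for p in parts if p.provenance),
        )


@dataclass
class SyntheticConfig:
    """Conditions for the synthetic ECG epoch generator.

    The morphology is a sum-of-Gaussians beat template (P/QRS/T bumps) on
    a periodic beat phase; classes differ in rate, complex width, segment
    offset and ectopy so that they are learnably separable.  ``noise_sd``
    is additive white measurement noise (signal units, R amplitude = 1);
    ``artifact_frac`` is the fraction of epochs carrying a superimposed
    motion artifact (baseline wander plus broadband noise), emulating the
    noisy stretches present in ambulatory recordings; ``distortion``
    scales the class-specific morphological deviation from normal sinus
    rhythm.
    """

    class_label: str
    n_epochs: int
    seed: int = 0
    noise_sd: float = 0.05
    beat_rate: float | None = None  # beats/min; None = class default
    p_amp: float = 0.15
    qrs_amp: float = 1.0
    t_amp: float = 0.35
    distortion: float = 1.0
    artifact_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"unknown class_label {self.class_label!r}; "
                f"expected one of {CLASS_LABELS}"
            )
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rate = self.beat_rate
        if rate is None:
            rate = CLASS_RATE[self.class_label]
            self.beat_rate = rate
        if rate <= 0:
            raise ValueError("beat rate must be positive")
        if not 0 <= self.artifact_frac <= 1:
            raise ValueError("artifact_frac must be in [0, 1]")


def segment_into_epochs(
    signal: np.ndarray, epoch_length: int, fs: float, label: str
) -> EpochMatrix:
    """Slice a 1-D sample sequence into consecutive non-overlapping epochs.

    Returns ``floor(len(signal) / epoch_length)`` rows; any trailing
    partial epoch is discarded.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    if len(signal) < epoch_length:
        raise ValueError(
            f"signal of {len(signal)} samples is shorter than one epoch "
            f"({epoch_length} samples)"
        )
    n = len(signal) // epoch_length
    data = signal[: n * epoch_length].reshape(n, epoch_length)
    return EpochMatrix(
        data,
        fs,
        np.array([label] * n, dtype=object),
        provenance=f"segmented contiguous non-overlapping length={epoch_length}",
    )


def _gauss(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    # wrap-around distance on the unit beat phase
    d = np.abs(phase - center)
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / width) ** 2)


def _beat_waveform(phase: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """One cardiac cycle on beat phase in [0, 1): P wave, QRS complex, T wave."""
    c, d = cfg.class_label, cfg.distortion
    p_amp, r_amp, t_amp = cfg.p_amp, cfg.qrs_amp, cfg.t_amp
    if c == "VT":
        # monomorphic wide-complex tachycardia: no P, broad merged QRS-T
        w = r_amp * 1.5 * _gauss(phase, 0.40, 0.020 + 0.05 * d)
        w -= 0.5 * d * _gauss(phase, 0.58, 0.07)
        return w
    w = p_amp * _gauss(phase, 0.18, 0.025)
    w -= 0.10 * _gauss(phase, 0.37, 0.008)
    w += r_amp * _gauss(phase, 0.40, 0.012)
    w -= 0.15 * _gauss(phase, 0.43, 0.010)
    w += t_amp * _gauss(phase, 0.62, 0.045)
    if c == "ST":
        # ischemic ST-segment elevation between the QRS and the T wave
        w += 0.25 * d * _gauss(phase, 0.52, 0.045)
    return w


def generate_synthetic_ecg(config: SyntheticConfig) -> EpochMatrix:
    """Generate an epoch matrix of synthetic ECG-like signals.

    Deterministic given the config (including seed).  Per epoch the beat
    phase is randomized and the rate and amplitude jittered; PVC epochs
    carry one early wide ectopic complex; a fraction ``artifact_frac`` of
    epochs receives a superimposed motion artifact.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    length, fs = CLASS_SHAPE[cfg.class_label]
    t = np.arange(length) / fs
    data = np.empty((cfg.n_epochs, length))
    for i in range(cfg.n_epochs):
        rate = cfg.beat_rate * (1.0 + 0.05 * rng.standard_normal())
        rate = max(rate, 1.0)
        phase0 = rng.uniform(0.0, 1.0)
        phase = (t * rate / 60.0 + phase0) % 1.0
        amp = 1.0 + 0.1 * rng.standard_normal()
        x = amp * _beat_waveform(phase, cfg)
        if cfg.class_label == "PVC":
            # ectopic wide complex with inverted T at a random time
            t0 = rng.uniform(0.1, 0.9) * t[-1]
            width = 0.045 * cfg.distortion + 0.015
            x += 1.3 * np.exp(-0.5 * ((t - t0) / width) ** 2)
            x -= 0.5 * np.exp(-0.5 * ((t - t0 - 0.18) / 0.06) ** 2)
        if rng.uniform() < cfg.artifact_frac:
            # motion artifact superimposed on the beat train: baseline
            # wander plus broadband noise
            wander = 0.3 * np.sin(2 * np.pi * rng.uniform(0.3, 1.5) * t + rng.uniform(0, 2 * np.pi))
            x = x + wander + 0.3 * rng.standard_normal(length)
        x += cfg.noise_sd * rng.standard_normal(length)
        data[i] = x
    return EpochMatrix(
        data,
        fs,
        np.array([cfg.class_label] * cfg.n_epochs, dtype=object),
        provenance=(
            f"synthetic {cfg.class_label} seed={cfg.seed} "
            f"noise_sd={cfg.noise_sd} rate={cfg.beat_rate} "
            f"artifact_frac={cfg.artifact_frac}"
        ),
    )


# ---------------------------------------------------------------------------
# CSV I/O: metadata header lines (#key=value) followed by label,s0,...,sL-1

def write_epoch_matrix(matrix: EpochMatrix, path) -> None:
    with open(path, "w") as f:
        f.write("#format=ecgdetect-epochs-v1\n")
        f.write(f"#fs={matrix.fs:g}\n")
        f.write(f"#epoch_length={matrix.epoch_length}\n")
        f.write(f"#provenance={matrix.provenance}\n")
        f.write("label," + ",".join(f"s{i}" for i in range(matrix.epoch_length)) + "\n")
        for lab, row in zip(matrix.labels, matrix.data):
            f.write(str(lab) + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_epoch_matrix(path) -> EpochMatrix:
    with open(path) as f:
        lines = f.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty file is not a valid epoch matrix")
    meta: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    for key in ("fs", "epoch_length"):
        if key not in meta:
            raise ValueError(f"{path}: malformed header, missing #{key}=")
    fs = float(meta["fs"])
    epoch_length = int(meta["epoch_length"])
    body = lines[body_start:]
    if not body or not body[0].startswith("label,"):
        raise ValueError(f"{path}: line {body_start + 1}: expected 'label,s0,...' header row")
    rows, labels = [], []
    for j, line in enumerate(body[1:], start=body_start + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != epoch_length + 1:
            raise ValueError(
                f"{path}: line {j}: row has {len(parts) - 1} samples, "
                f"expected epoch_length={epoch_length}"
            )
        if parts[0] not in CLASS_LABELS:
            raise ValueError(f"{path}: line {j}: unknown label {parts[0]!r}")
        labels.append(parts[0])
        rows.append(np.array(parts[1:], dtype=float))
    if not rows:
        raise ValueError(f"{path}: no epoch rows found")
    return EpochMatrix(
        np.vstack(rows), fs, np.array(labels, dtype=object),
        provenance=meta.get("provenance", ""),
    )
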