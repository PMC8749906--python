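"""Seeded generation of synthetic stuttered / fluent utterances.

The corpus this toolkit targets (4-s mono recordings, 22,050 Hz, labelled as
blocks, syllable repetitions, sound-initial prolongations or fluent speech)
is not publicly deposited, so every downstream stage is exercised on
synthetic signals that emulate the acoustic signatures those classes rely
on:

* ``block`` — a long near-silent lead-in followed by a plosive-like
  broadband burst and ordinary voiced speech;
* ``repetition`` — several short voiced bursts separated by silent gaps,
  then continuous speech;
* ``prolongation`` — a sustained sibilant-like noise with its energy
  concentrated above 3,150 Hz, then voiced speech;
* ``fluent`` — continuous syllabic alternation with brief pauses.

No attempt is made at phonetic realism: the waveforms are built from
harmonic pulse trains and band-limited noise only, which is sufficient for
the third-octave band-level representation the analysis chain consumes.

A separate low-rank-plus-noise matrix generator provides fixtures for the
principal-component selection rule, bypassing waveform synthesis entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "CLASSES",
    "Utterance",
    "LabeledDataset",
    "generate_utterance",
    "generate_dataset",
    "generate_lowrank_filterbank",
    "write_wav",
    "read_wav",
    "save_dataset",
]

#: Canonical class order used everywhere (tables, confusion matrices, seeds).
CLASSES: tuple[str, ...] = ("block", "repetition", "prolongation", "fluent")

DEFAULT_FS = 22_050
DEFAULT_DURATION_S = 4.0

# Amplitudes are clipped here before 16-bit quantisation to avoid wrap-around
# on WAV export.
CLIP = 0.99


@dataclass
class Utterance:
    """A labelled mono waveform with amplitudes in [-1, 1]."""

    samples: np.ndarray
    fs: int
    label: str
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class LabeledDataset:
    utterances: list[Utterance] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for u in self.utterances:
            counts[u.label] = counts.get(u.label, 0) + 1
        return counts

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([u.label for u in self.utterances])

    def __len__(self) -> int:
        return len(self.utterances)

    def __iter__(self):
        return iter(self.utterances)


# ---------------------------------------------------------------------------
# waveform building blocks
# ---------------------------------------------------------------------------

def _voiced(rng: np.random.Generator, n: int, fs: int, f0: float,
            n_harm: int, amp: float) -> np.ndarray:
    """Harmonic pulse segment: summed harmonics with 1/h roll-off, random
    phases and a raised-cosine envelope."""
    t = np.arange(n) / fs
    nyq = fs / 2
    out = np.zeros(n)
    for h in range(1, n_harm + 1):
        f = h * f0
        if f >= 0.95 * nyq:
            break
        out += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) / h
    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
    out *= env
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= amp / peak
    return out


def _band_noise(rng: np.random.Generator, n: int, fs: int,
                lo: float, hi: float, amp: float) -> np.ndarray:
    """Band-passed white noise with a raised-cosine envelope."""
    hi = min(hi, 0.98 * fs / 2)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = sps.sosfilt(sos, rng.standard_normal(n))
    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
    out *= env
    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out *= amp / rms
    return out


def _syllable_train(rng: np.random.Generator, n_total: int, fs: int,
                    f0: float, syl_s: float, pause_s: float,
                    n_harm: int, amp: float) -> np.ndarray:
    """Alternating voiced syllables and pauses filling ``n_total`` samples."""
    out = np.zeros(n_total)
    pos = 0
    n_syl = int(round(syl_s * fs))
    n_pause = int(round(pause_s * fs))
    while pos < n_total:
        seg = _voiced(rng, n_syl, fs, f0 * rng.uniform(0.95, 1.05),
                      n_harm, amp)
        end = min(pos + n_syl, n_total)
        out[pos:end] = seg[: end - pos]
        pos = end + n_pause
    return out


# per-class synthesis parameters; "easy" maximises inter-class spectral and
# temporal contrast, "hard" shrinks silences and spectral emphasis so the
# classes genuinely overlap.
_PROFILES = {
    "easy": dict(
        block_silence_s=1.3, burst_amp=0.7, burst_s=0.09,
        rep_burst_s=0.15, rep_gap_s=0.20, rep_cycles=5,
        prolong_s=1.6, prolong_amp=0.45, prolong_lo=3200.0, prolong_hi=10000.0,
        fluent_syl_s=0.22, fluent_pause_s=0.12,
        background=5e-4,
    ),
    "hard": dict(
        block_silence_s=0.7, burst_amp=0.5, burst_s=0.08,
        rep_burst_s=0.16, rep_gap_s=0.14, rep_cycles=4,
        prolong_s=1.1, prolong_amp=0.25, prolong_lo=2500.0, prolong_hi=9000.0,
        fluent_syl_s=0.20, fluent_pause_s=0.11,
        background=5e-4,
    ),
}

# distinct voicing registers per class sharpen the band-profile contrast
_F0 = {"block": 110.0, "repetition": 190.0, "prolongation": 130.0,
       "fluent": 140.0}
_NHARM = {"block": 12, "repetition": 6, "prolongation": 10, "fluent": 18}


def generate_utterance(label: str, duration_s: float = DEFAULT_DURATION_S,
                       fs: int = DEFAULT_FS, seed: int = 0,
                       difficulty: str = "easy") -> Utterance:
    """Synthesise one labelled utterance.

    Deterministic for a fixed ``(label, seed)`` pair: the random stream is
    keyed on both so that different classes generated with the same seed do
    not share noise.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASSES}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs < 8000:
        raise ValueError("fs must be at least 8000 Hz")
    if difficulty not in _PROFILES:
        raise ValueError(f"difficulty must be one of {sorted(_PROFILES)}")

    p = _PROFILES[difficulty]
    rng = np.random.default_rng(
        np.random.SeedSequence((int(seed), CLASSES.index(label), 0x5EED)))
    n = int(round(duration_s * fs))
    out = rng.standard_normal(n) * p["background"]

    f0, n_harm = _F0[label], _NHARM[label]

    if label == "fluent":
        out += _syllable_train(rng, n, fs, f0, p["fluent_syl_s"],
                               p["fluent_pause_s"], n_harm, 0.35)
    elif label == "block":
        n_sil = int(p["block_silence_s"] * fs)
        n_burst = int(p["burst_s"] * fs)
        pos = min(n_sil, n)
        if pos + n_burst <= n:
            out[pos:pos + n_burst] += _band_noise(
                rng, n_burst, fs, 300.0, 8000.0, p["burst_amp"])
        tail = pos + n_burst + int(0.05 * fs)
        if tail < n:
            out[tail:] += _syllable_train(rng, n - tail, fs, f0,
                                          p["fluent_syl_s"],
                                          p["fluent_pause_s"], n_harm, 0.35)
    elif label == "repetition":
        n_burst = int(p["rep_burst_s"] * fs)
        n_gap = int(p["rep_gap_s"] * fs)
        pos = int(0.05 * fs)
        for _ in range(p["rep_cycles"]):
            if pos + n_burst > n:
                break
            out[pos:pos + n_burst] += _voiced(rng, n_burst, fs, f0,
                                              n_harm, 0.4)
            pos += n_burst + n_gap
        if pos < n:
            out[pos:] += _syllable_train(rng, n - pos, fs, f0,
                                         p["fluent_syl_s"],
                                         p["fluent_pause_s"], n_harm, 0.35)
    else:  # prolongation
        n_pro = min(int(p["prolong_s"] * fs), n)
        out[:n_pro] += _band_noise(rng, n_pro, fs, p["prolong_lo"],
                                   p["prolong_hi"], p["prolong_amp"])
        tail = n_pro + int(0.05 * fs)
        if tail < n:
            out[tail:] += _syllable_train(rng, n - tail, fs, f0,
                                          p["fluent_syl_s"],
                                          p["fluent_pause_s"], n_harm, 0.30)

    np.clip(out, -CLIP, CLIP, out=out)
    return Utterance(samples=out, fs=fs, label=label,
                     id=f"{label}-{seed}")


def generate_dataset(class_counts: dict[str, int], seed: int = 0,
                     duration_s: float = DEFAULT_DURATION_S,
                     fs: int = DEFAULT_FS,
                     difficulty: str = "easy") -> LabeledDataset:
    """Generate a labelled dataset with exactly the requested per-class
    counts; reproducible for a fixed seed."""
    for label, count in class_counts.items():
        if label not in CLASSES:
            raise ValueError(f"unknown label {label!r}")
        if count < 0:
            raise ValueError(f"negative count for class {label!r}")
    ss = np.random.SeedSequence(int(seed))
    # one derived integer seed per utterance, below 2**31
    total = sum(class_counts.values())
    child = ss.generate_state(max(total, 1)) % (2**31)
    utterances = []
    k = 0
    for label in CLASSES:
        for i in range(class_counts.get(label, 0)):
            u = generate_utterance(label, duration_s, fs, int(child[k]),
                                   difficulty)
            u.id = f"{label}-{i:03d}"
            utterances.append(u)
            k += 1
    return LabeledDataset(utterances=utterances)


# ---------------------------------------------------------------------------
# low-rank fixture for the component-selection rule
# ---------------------------------------------------------------------------

def _basis_profiles(n_bands: int, rank: int) -> np.ndarray:
    """Fixed smooth spectral profiles: Gaussian bumps spread over the bands."""
    centers = np.linspace(0.5, n_bands - 1.5, rank)
    width = max(2.0, n_bands / (2.0 * rank))
    j = np.arange(n_bands)
    return np.exp(-((j[None, :] - centers[:, None]) ** 2) / (2 * width**2))


def generate_lowrank_filterbank(n_frames: int = 171, n_bands: int = 21,
                                rank: int = 4, noise_sd: float = 0.3,
                                seed: int = 0):
    """Low-rank-plus-noise band-level matrix.

    The matrix is a linear combination of ``rank`` fixed smooth spectral
    basis profiles with random time-varying weights, plus i.i.d. Gaussian
    noise of standard deviation ``noise_sd``.  With ``noise_sd=0`` its
    numerical rank equals ``rank`` exactly.
    """
    from .frontend import FilterbankMatrix, third_octave_bands, FRAME_LEN

    if not 1 <= rank <= n_bands:
        raise ValueError("rank must satisfy 1 <= rank <= n_bands")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(int(seed))
    basis = _basis_profiles(n_bands, rank)
    weights = rng.standard_normal((n_frames, rank))
    levels = weights @ basis
    if noise_sd > 0:
        levels = levels + rng.standard_normal((n_frames, n_bands)) * noise_sd
    if n_bands == 21:
        centers = third_octave_bands().centre_freqs
    else:
        centers = np.arange(n_bands, dtype=float)
    return FilterbankMatrix(levels=levels,
                            frame_duration=FRAME_LEN / DEFAULT_FS,
                            band_centers=centers,
                            sample_id=f"lowrank-r{rank}-s{seed}")


# ---------------------------------------------------------------------------
# WAV / manifest I/O
# ---------------------------------------------------------------------------

def write_wav(utterance: Utterance, path) -> None:
    """Write RIFF PCM, 16-bit signed, mono."""
    x = np.clip(utterance.samples, -CLIP, CLIP)
    wavfile.write(str(path), utterance.fs,
                  np.round(x * 32767.0).astype(np.int16))


def read_wav(path, label: str = "", id: str = "") -> Utterance:
    fs, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError("expected mono WAV")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    else:
        samples = data.astype(np.float64)
    return Utterance(samples=samples, fs=int(fs), label=label,
                     id=id or Path(path).stem)


def save_dataset(dataset: LabeledDataset, out_dir,
                 params: dict | None = None) -> Path:
    """Write WAV files plus a ``manifest.csv`` (id, path, label) and a JSON
    sidecar with the generator parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["id,path,label"]
    for u in dataset:
        fname = f"{u.id}.wav"
        write_wav(u, out / fname)
        rows.append(f"{u.id},{fname},{u.label}")
    (out / "manifest.csv").write_text("\n".join(rows) + "\n")
    if params is not None:
        (out / "generator_params.json").write_text(
            json.dumps(params, indent=2, sort_keys=True) + "\n")
    return out / "manifest.csv"
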