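"""Seeded generator of Bonn-like single-channel EEG records.

Three distinguishable signal classes are produced so the whole pipeline is
testable without the real corpus:

``healthy``
    1/f^beta broadband noise plus an alpha-band (8-13 Hz) sinusoid of random
    frequency and phase — the dominant rhythm of relaxed healthy scalp EEG.
``interictal``
    The healthy background plus sparse Poisson-timed biphasic spikes
    (epileptiform discharges between seizures).
``ictal``
    The broadband background plus a sustained high-amplitude low-frequency
    (3-5 Hz) oscillation, emulating continuous rhythmic seizure activity.

These are synthetic fixtures chosen to be learnable and statistically
separable, not physiologically validated EEG.  Records are reproducible
individually: the per-record random stream is derived from
``(seed, stream label, record index)``, where the stream label is the subset
code when generating a full dataset.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bonn import DEFAULT_FS, EEGRecord, write_record_file

__all__ = [
    "CLASS_CODES",
    "SUBSET_CLASS",
    "SynthParams",
    "SyntheticDataset",
    "generate_record",
    "generate_dataset",
    "band_power",
]

CLASS_CODES = ("healthy", "interictal", "ictal")

#: Which signal class backs each Bonn subset.
SUBSET_CLASS: Mapping[str, str] = {
    "Z": "healthy",
    "O": "healthy",
    "N": "interictal",
    "F": "interictal",
    "S": "ictal",
}


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic EEG generator.

    Amplitude factors are unitless ratios relative to the RMS of the
    broadband background (which is generated at unit RMS and only scaled to
    integer ADC-like units at the very end, via ``output_scale``).
    """

    fs: float = DEFAULT_FS
    n_samples: int = 4096
    healthy_alpha_band: tuple[float, float] = (8.0, 13.0)
    ictal_band: tuple[float, float] = (3.0, 5.0)
    ictal_amp_factor: float = 5.0
    spike_rate_hz: float = 0.5
    spike_amp_factor: float = 4.0
    alpha_amp_factor: float = 1.0
    noise_exponent: float = 1.0
    output_scale: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.n_samples <= 0:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        for name in ("ictal_amp_factor", "spike_amp_factor", "alpha_amp_factor", "output_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spike_rate_hz < 0:
            raise ValueError("spike_rate_hz must be non-negative")
        nyq = self.fs / 2.0
        for name in ("healthy_alpha_band", "ictal_band"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo < hi < nyq):
                raise ValueError(
                    f"{name}={lo, hi} must lie strictly inside (0, fs/2)=(0, {nyq})"
                )


def _record_seed_seq(params: SynthParams, stream: str, index: int) -> np.random.SeedSequence:
    # per-record seed = hash(global seed, stream label, record index)
    return np.random.SeedSequence([params.seed, zlib.crc32(stream.encode()), index])


def _pink_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Unit-RMS, zero-mean 1/f^beta noise synthesized in the frequency domain."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    x /= x.std()
    return x


def _biphasic_spike(fs: float, width_s: float = 0.07) -> np.ndarray:
    """Canonical biphasic spike: derivative-of-Gaussian, peak amplitude 1.

    One positive and one negative lobe; total support about *width_s*.
    """
    sigma = width_s / 6.0
    t = np.arange(-3 * sigma, 3 * sigma + 0.5 / fs, 1.0 / fs)
    w = -t * np.exp(-(t**2) / (2 * sigma**2))
    return w / np.abs(w).max()


def generate_record(
    class_code: str,
    params: SynthParams = SynthParams(),
    record_index: int = 0,
    stream: str = "rec",
) -> EEGRecord:
    """Generate one synthetic EEG record of the given class.

    The same ``(seed, stream, record_index)`` always yields a bit-identical
    record.  The broadband background and alpha component depend only on the
    seed material, not on the class, so an interictal record with
    ``spike_rate_hz = 0`` is identical to the healthy record at the same seed.
    Samples are rounded to integers (Bonn records are integer ADC counts).
    """
    if class_code not in CLASS_CODES:
        raise ValueError(f"unknown class code {class_code!r}; expected one of {CLASS_CODES}")
    n = params.n_samples
    ss = _record_seed_seq(params, stream, int(record_index))
    noise_ss, alpha_ss, event_ss = ss.spawn(3)

    x = _pink_noise(np.random.default_rng(noise_ss), n, params.noise_exponent)
    t = np.arange(n) / params.fs

    alpha_rng = np.random.default_rng(alpha_ss)
    f_alpha = alpha_rng.uniform(*params.healthy_alpha_band)
    phi_alpha = alpha_rng.uniform(0.0, 2.0 * np.pi)
    if class_code in ("healthy", "interictal"):
        x = x + params.alpha_amp_factor * np.sin(2.0 * np.pi * f_alpha * t + phi_alpha)

    event_rng = np.random.default_rng(event_ss)
    if class_code == "interictal":
        duration = n / params.fs
        n_spikes = event_rng.poisson(params.spike_rate_hz * duration)
        if n_spikes:
            wave = _biphasic_spike(params.fs)
            half = wave.size // 2
            centers = np.sort(event_rng.integers(0, n, n_spikes))
            for c in centers:
                lo, hi = c - half, c - half + wave.size
                wlo, whi = max(0, -lo), wave.size - max(0, hi - n)
                x[max(0, lo) : min(n, hi)] += params.spike_amp_factor * wave[wlo:whi]
    elif class_code == "ictal":
        f_ictal = event_rng.uniform(*params.ictal_band)
        phi_ictal = event_rng.uniform(0.0, 2.0 * np.pi)
        x = x + params.ictal_amp_factor * np.sin(2.0 * np.pi * f_ictal * t + phi_ictal)

    samples = np.round(params.output_scale * x)
    return EEGRecord(
        samples,
        fs=params.fs,
        subset="?",
        source_id=f"syn-{class_code}-{stream}-{record_index:03d}",
    )


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its manifest.

    ``manifest`` columns: ``path`` (empty when not written), ``subset``,
    ``class``, ``seed``, ``index``.
    """

    records: list[EEGRecord]
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)


def generate_dataset(
    n_per_class: int,
    params: SynthParams = SynthParams(),
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate the five Bonn subsets: Z,O healthy; N,F interictal; S ictal.

    Each subset receives *n_per_class* records (the real corpus has 100).
    When *out_dir* is given, records are written as Bonn-format text files in
    one directory per subset (``out_dir/Z/Z000.txt`` ...), plus a
    ``manifest.csv`` at the root.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    root = None
    if out_dir is not None:
        root = Path(out_dir)
        if root.exists() and not root.is_dir():
            raise OSError(f"out_dir {root} exists and is not a directory")
        root.mkdir(parents=True, exist_ok=True)

    records: list[EEGRecord] = []
    rows = []
    for subset in ("Z", "O", "N", "F", "S"):
        cls = SUBSET_CLASS[subset]
        subdir = None
        if root is not None:
            subdir = root / subset
            subdir.mkdir(exist_ok=True)
        for i in range(n_per_class):
            rec = generate_record(cls, params, record_index=i, stream=subset)
            rec.subset = subset
            rec.source_id = f"{subset}{i:03d}"
            path = ""
            if subdir is not None:
                fpath = subdir / f"{rec.source_id}.txt"
                write_record_file(rec, fpath)
                path = f"{subset}/{rec.source_id}.txt"  # root-relative: reruns are byte-identical
            records.append(rec)
            rows.append(
                {"path": path, "subset": subset, "class": cls, "seed": params.seed, "index": i}
            )
    manifest = pd.DataFrame(rows, columns=["path", "subset", "class", "seed", "index"])
    if root is not None:
        manifest.to_csv(root / "manifest.csv", index=False)
    return SyntheticDataset(records, manifest)


def band_power(signal: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Integrated periodogram power of *signal* within *band* (half-open [lo, hi)).

    Uses the raw (boxcar, undetrended) periodogram, so summing band powers over
    a partition of (0, fs/2) recovers the signal's mean square (Parseval),
    up to the DC bin which is excluded for zero-mean signals.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise ValueError("band_power requires a signal of length >= 2")
    lo, hi = band
    if not (0.0 <= lo < hi <= fs / 2.0):
        raise ValueError(f"band {band} must lie inside (0, fs/2)=(0, {fs/2})")
    freqs, pxx = sps.periodogram(signal, fs=fs, window="boxcar", detrend=False)
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    if hi == fs / 2.0:  # close the partition at Nyquist
        mask |= freqs == hi
    return float(pxx[mask].sum() * df)
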