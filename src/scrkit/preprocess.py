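"""Filtering and stimulus-locked segmentation of EDA recordings.

The filter chain is a zero-phase low-pass (5th-order Butterworth applied
forward-backward, 4 Hz cutoff by default) followed by Gaussian smoothing
to attenuate single-sample artifacts and sensor noise.  Segmentation cuts
the recording into one slice per stimulus event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import signal as sps

from .io import EDASignal, StimulusEvent

DEFAULT_CUTOFF_HZ = 4.0
DEFAULT_SMOOTH_WINDOW_S = 1.0
DEFAULT_SMOOTH_SIGMA_S = 0.2
BUTTER_ORDER = 5


@dataclass
class Segment:
    """One stimulus-locked slice of a recording."""

    signal: EDASignal
    event: StimulusEvent
    participant_id: str = ""

    def __post_init__(self) -> None:
        if abs(self.signal.samples.size / self.signal.fs - self.event.duration) > 1.5 / self.signal.fs:
            raise ValueError(
                f"segment length {self.signal.samples.size / self.signal.fs:.3f} s "
                f"does not match event duration {self.event.duration} s"
            )


def lowpass_filter(sig: EDASignal, cutoff: float = DEFAULT_CUTOFF_HZ) -> EDASignal:
    """Zero-phase 5th-order Butterworth low-pass.

    If the cutoff is at or above 95% of Nyquist the stage would be
    unrealizable (this happens at the E4's native 4 Hz EDA rate with the
    default 4 Hz cutoff); it is then skipped with a warning rather than
    erroring, so the rest of the chain still runs.
    """
    if not np.isfinite(sig.fs) or sig.fs <= 0:
        raise ValueError(f"invalid sampling rate {sig.fs}")
    nyq = sig.fs / 2.0
    if cutoff >= 0.95 * nyq:
        warnings.warn(
            f"low-pass cutoff {cutoff} Hz >= 95% of Nyquist ({nyq} Hz); stage skipped",
            stacklevel=2,
        )
        return EDASignal(sig.samples.copy(), sig.fs, sig.t0, sig.label)
    sos = sps.butter(BUTTER_ORDER, cutoff, btype="low", fs=sig.fs, output="sos")
    out = sps.sosfiltfilt(sos, sig.samples)
    return EDASignal(out, sig.fs, sig.t0, sig.label)


def gaussian_kernel(window_s: float, sigma_s: float, fs: float) -> np.ndarray:
    """Unit-sum truncated Gaussian kernel of odd length ~= window_s * fs."""
    half = max(1, int(round(window_s * fs / 2)))
    x = np.arange(-half, half + 1) / fs
    k = np.exp(-0.5 * (x / sigma_s) ** 2)
    return k / k.sum()


def gaussian_smooth(
    sig: EDASignal,
    window_s: float = DEFAULT_SMOOTH_WINDOW_S,
    sigma_s: float = DEFAULT_SMOOTH_SIGMA_S,
) -> EDASignal:
    """Convolve with a unit-sum truncated Gaussian; edges by reflection."""
    if window_s < 1.0 / sig.fs:
        raise ValueError(f"window_s {window_s} shorter than one sample period")
    k = gaussian_kernel(window_s, sigma_s, sig.fs)
    half = k.size // 2
    padded = np.pad(sig.samples, half, mode="reflect")
    out = np.convolve(padded, k, mode="valid")
    return EDASignal(out, sig.fs, sig.t0, sig.label)


def preprocess(
    sig: EDASignal,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    window_s: float = DEFAULT_SMOOTH_WINDOW_S,
    sigma_s: float = DEFAULT_SMOOTH_SIGMA_S,
) -> EDASignal:
    """Full filter chain: low-pass then Gaussian smoothing."""
    return gaussian_smooth(lowpass_filter(sig, cutoff), window_s, sigma_s)


def segment_recording(
    sig: EDASignal, events: list[StimulusEvent], participant_id: str = ""
) -> list[Segment]:
    """Cut one Segment per event.

    Sample indices are half-open, 0-based: floor(onset*fs) to
    floor((onset+duration)*fs).
    """
    segments = []
    for ev in events:
        i0 = int(np.floor(ev.onset * sig.fs))
        i1 = int(np.floor(ev.end * sig.fs))
        if i0 < 0 or i1 > sig.samples.size:
            raise ValueError(
                f"event {ev.label!r} [{ev.onset}, {ev.end}) s extends outside the "
                f"recording (0 to {sig.samples.size / sig.fs:.1f} s)"
            )
        slice_sig = EDASignal(
            sig.samples[i0:i1],
            sig.fs,
            sig.t0 + ev.onset,
            label=f"{sig.label}/{ev.label}" if sig.label else ev.label,
        )
        segments.append(Segment(slice_sig, ev, participant_id))
    return segments
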