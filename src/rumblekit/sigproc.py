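"""Spectrogram preprocessing: filtering, time-frequency maps, snippet images.

The analysis chain mirrors how continuous records are prepared for both
visual scanning and CNN classification: traces are zero-phase band-passed
to 1–80 Hz, converted to short-time power spectrograms (the three seismic
components are averaged on the linear power scale to raise the
signal-to-noise ratio), cut into 12-s snippets centred on pick times, and
rendered as fixed-size 232 × 115 RGB images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from matplotlib import colormaps
from scipy import signal

from .trace import Trace

#: analysis band used throughout (Hz)
ANALYSIS_BAND = (1.0, 80.0)

#: snippet length fed to the classifier (s)
SNIPPET_LENGTH = 12.0

#: rendered snippet image size (width, height) in pixels
IMAGE_SIZE = (232, 115)


@dataclass
class TimeFreqMap:
    """Short-time power spectrogram with explicit axes.

    ``power`` is indexed [time bin, frequency bin] and is non-negative on
    the linear scale; both axes are strictly increasing.
    """

    power: np.ndarray
    time_axis: np.ndarray
    freq_axis: np.ndarray
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        if self.power.shape != (self.time_axis.size, self.freq_axis.size):
            raise ValueError("power must be (n_times, n_freqs)")
        if np.any(np.diff(self.time_axis) <= 0) or np.any(
            np.diff(self.freq_axis) <= 0
        ):
            raise ValueError("axes must be strictly increasing")
        if self.scale == "linear" and np.any(self.power < 0):
            raise ValueError("linear-scale power must be non-negative")

    def band(self, f_lo: float, f_hi: float) -> "TimeFreqMap":
        """Restrict to frequency rows in ``[f_lo, f_hi]``."""
        sel = (self.freq_axis >= f_lo) & (self.freq_axis <= f_hi)
        if not sel.any():
            raise ValueError("band selects no frequency bins")
        return TimeFreqMap(
            self.power[:, sel], self.time_axis, self.freq_axis[sel], self.scale
        )


@dataclass
class SnippetImage:
    """A rendered 232 × 115 RGB snippet with its class label and domain."""

    pixels: np.ndarray  # (height, width, 3) uint8
    label: str = "unlabeled"  # rumble | noise | unlabeled
    domain: str = "seismic"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        h, w = IMAGE_SIZE[1], IMAGE_SIZE[0]
        if self.pixels.shape != (h, w, 3) or self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8 of shape ({h}, {w}, 3)")

    def to_png(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(Path(path))

    def as_float(self) -> np.ndarray:
        """Pixels scaled to [0, 1] float32, as fed to the network."""
        return self.pixels.astype(np.float32) / 255.0


# ----------------------------------------------------------------------
# Operations


def bandpass_filter(
    trace: Trace, f_lo: float = ANALYSIS_BAND[0], f_hi: float = ANALYSIS_BAND[1]
) -> Trace:
    """Zero-phase Butterworth band-pass; metadata unchanged.

    Two-pass (forward-backward) filtering keeps pick times unshifted; the
    8th-order design keeps the transition bands narrow enough that
    re-filtering already-filtered data changes its RMS by well under 1 %.
    """
    nyq = trace.sampling_rate / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(
            f"require 0 < f_lo < f_hi < Nyquist ({nyq:g} Hz); "
            f"got ({f_lo:g}, {f_hi:g})"
        )
    sos = signal.butter(
        8, [f_lo, f_hi], btype="bandpass", fs=trace.sampling_rate, output="sos"
    )
    out = trace.copy()
    out.data = signal.sosfiltfilt(sos, trace.data)
    return out


def compute_spectrogram(
    trace: Trace, window_length: float = 1.0, overlap: float = 0.75
) -> TimeFreqMap:
    """Short-time power spectral density of a trace.

    Hann-windowed STFT with the stated window length (frequency resolution
    1/window_length) and fractional overlap; returns linear power.
    """
    nperseg = int(round(window_length * trace.sampling_rate))
    if nperseg < 8:
        raise ValueError("window_length x sampling_rate must be >= 8 samples")
    if nperseg > trace.npts:
        raise ValueError("spectrogram window longer than trace")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    noverlap = int(round(overlap * nperseg))
    freqs, times, sxx = signal.spectrogram(
        trace.data,
        fs=trace.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        scaling="density",
        mode="psd",
    )
    return TimeFreqMap(sxx.T, times, freqs, scale="linear")


def average_component_maps(maps: Sequence[TimeFreqMap]) -> TimeFreqMap:
    """Cell-wise arithmetic mean of component spectrograms (linear power).

    Averaging the N, E and Z maps raises the ridge-to-background ratio of
    tonal signals whose energy is split across components.
    """
    if len(maps) == 0:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if (
            m.power.shape != first.power.shape
            or not np.allclose(m.time_axis, first.time_axis)
            or not np.allclose(m.freq_axis, first.freq_axis)
            or m.scale != first.scale
        ):
            raise ValueError("component maps must share axes and scale")
    mean = np.mean([m.power for m in maps], axis=0)
    return TimeFreqMap(mean, first.time_axis.copy(), first.freq_axis.copy(), first.scale)


def extract_snippet(
    trace: Trace, t_pick: float, length: float = SNIPPET_LENGTH
) -> Trace:
    """Cut ``[t_pick - length/2, t_pick + length/2)`` seconds around a pick.

    ``t_pick`` is in seconds relative to the trace start.  Picks closer than
    ``length/2`` to either edge raise — snippets are never padded.
    """
    t0 = t_pick - length / 2.0
    t1 = t_pick + length / 2.0
    if t0 < 0 or t1 > trace.duration + 1e-9:
        raise ValueError(
            f"snippet [{t0:g}, {t1:g}) s exceeds trace bounds [0, {trace.duration:g}) s"
        )
    i0 = int(round(t0 * trace.sampling_rate))
    n = int(round(length * trace.sampling_rate))
    out = trace.copy()
    out.data = trace.data[i0 : i0 + n]
    out.start_time = trace.start_time + pd.to_timedelta(
        i0 / trace.sampling_rate, unit="s"
    )
    return out


def render_snippet_image(
    tfmap: TimeFreqMap,
    freq_range: tuple[float, float] = ANALYSIS_BAND,
    label: str = "unlabeled",
    domain: str = "seismic",
    size: tuple[int, int] = IMAGE_SIZE,
    anchors: tuple[float, float] = (2.0, 98.0),
    colormap: str = "viridis",
) -> SnippetImage:
    """Render a spectrogram as a fixed-size color image.

    Power is converted to dB, clipped at per-snippet percentile anchors
    (default 2nd/98th), mapped through a perceptually uniform colormap and
    bilinearly resampled to exactly ``size`` (width × height).  The
    rendering is a pure function of the map and the anchors.
    """
    if tfmap.power.size == 0:
        raise ValueError("empty time-frequency map")
    sub = tfmap.band(*freq_range)
    db = 10.0 * np.log10(np.maximum(sub.power, 1e-30))
    lo, hi = np.percentile(db, anchors)
    if hi <= lo:
        scaled = np.zeros_like(db)
    else:
        scaled = np.clip((db - lo) / (hi - lo), 0.0, 1.0)
    # rows = frequency (low at bottom), columns = time
    rgba = colormaps[colormap](scaled.T[::-1, :])
    rgb8 = (rgba[:, :, :3] * 255.0).round().astype(np.uint8)
    img = Image.fromarray(rgb8, mode="RGB").resize(size, Image.BILINEAR)
    return SnippetImage(np.asarray(img, dtype=np.uint8), label=label, domain=domain)


def snippet_image_from_traces(
    traces: Sequence[Trace],
    t_pick: float | None = None,
    label: str = "unlabeled",
    window_length: float = 1.0,
    overlap: float = 0.75,
) -> SnippetImage:
    """Full chain from raw component traces to a classifier-ready image.

    Band-passes each trace, optionally cuts the 12-s snippet around
    ``t_pick``, computes per-component spectrograms, averages them (the
    multi-component seismic case) and renders the image.
    """
    processed = []
    for tr in traces:
        tr = bandpass_filter(tr)
        if t_pick is not None:
            tr = extract_snippet(tr, t_pick)
        processed.append(tr)
    maps = [compute_spectrogram(tr, window_length, overlap) for tr in processed]
    merged = average_component_maps(maps) if len(maps) > 1 else maps[0]
    return SnippetImage(
        render_snippet_image(merged, label=label, domain=processed[0].domain).pixels,
        label=label,
        domain=processed[0].domain,
    )


@dataclass
class ScanWindow:
    """One visual-scanning interval ``[start, stop)`` in seconds."""

    start: float
    stop: float
    partial: bool = False


def scan_windows(trace: Trace, window: float = 200.0) -> list[ScanWindow]:
    """Contiguous non-overlapping scanning windows covering the trace.

    The final window is shorter when the record length is not a multiple of
    the window and is flagged ``partial``.
    """
    if trace.duration + 1e-9 < window:
        raise ValueError("trace shorter than one scanning window")
    out: list[ScanWindow] = []
    t = 0.0
    dur = trace.duration
    while t < dur - 1e-9:
        stop = min(t + window, dur)
        out.append(ScanWindow(t, stop, partial=stop - t < window - 1e-9))
        t += window
    return out
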