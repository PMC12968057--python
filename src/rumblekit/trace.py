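"""Waveform container and plain-format waveform I/O.

A :class:`Trace` is a uniformly sampled amplitude series with the metadata
needed downstream: sampling rate, absolute start time, channel code and
sensing domain.  Seismic traces carry ground velocity in µm/s on the N, E or
Z component; infrasound traces carry pressure in Pa on the single P channel.

Waveforms are read and written as WAV (float32 samples) or two-column CSV
(time_s, amplitude).  Instrument metadata that those formats cannot hold
travels in a JSON sidecar written next to the waveform file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

SEISMIC = "seismic"
INFRASOUND = "infrasound"

#: channel codes: three seismic components plus the pressure channel
CHANNELS = ("N", "E", "Z", "P")

#: default absolute origin for synthetic scenes (campaign-style August night)
DEFAULT_EPOCH = pd.Timestamp("2024-08-02 00:00:00")


@dataclass
class Trace:
    """A uniformly sampled waveform with channel/domain metadata.

    Parameters
    ----------
    data : ndarray
        Amplitude samples, µm/s (seismic) or Pa (infrasound).
    sampling_rate : float
        Samples per second; must be positive.
    start_time : pandas.Timestamp
        Absolute time of the first sample (UTC, tz-naive).
    channel : str
        One of ``N``, ``E``, ``Z`` (seismic) or ``P`` (infrasound pressure).
    domain : str
        ``"seismic"`` or ``"infrasound"``.
    units : str
        Physical units of ``data``.
    """

    data: np.ndarray
    sampling_rate: float = 200.0
    start_time: pd.Timestamp = field(default_factory=lambda: DEFAULT_EPOCH)
    channel: str = "Z"
    domain: str = SEISMIC
    units: str = "um/s"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 1 or self.data.size == 0:
            raise ValueError("trace data must be a non-empty 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.domain not in (SEISMIC, INFRASOUND):
            raise ValueError("domain must be 'seismic' or 'infrasound'")
        if not isinstance(self.start_time, pd.Timestamp):
            self.start_time = pd.Timestamp(self.start_time)

    # ------------------------------------------------------------------
    @property
    def npts(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.npts / self.sampling_rate

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.to_timedelta(self.duration, unit="s")

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to ``start_time``."""
        return np.arange(self.npts) / self.sampling_rate

    def copy(self, **changes) -> "Trace":
        tr = replace(self, **changes)
        tr.data = np.array(tr.data, copy=True)
        return tr

    def slice(self, t0: float, t1: float) -> "Trace":
        """Return the samples in ``[t0, t1)`` seconds relative to start."""
        i0 = int(round(t0 * self.sampling_rate))
        i1 = int(round(t1 * self.sampling_rate))
        if i0 < 0 or i1 > self.npts or i1 <= i0:
            raise ValueError(f"slice [{t0}, {t1}) s outside trace bounds")
        return Trace(
            self.data[i0:i1].copy(),
            self.sampling_rate,
            self.start_time + pd.to_timedelta(i0 / self.sampling_rate, unit="s"),
            self.channel,
            self.domain,
            self.units,
        )

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.data**2)))


# ----------------------------------------------------------------------
# I/O


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_meta(path: Path, trace: Trace) -> None:
    meta = {
        "sampling_rate": trace.sampling_rate,
        "start_time": trace.start_time.isoformat(),
        "channel": trace.channel,
        "domain": trace.domain,
        "units": trace.units,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def _read_meta(path: Path) -> dict:
    sc = _sidecar(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def write_wav(path: str | Path, trace: Trace) -> None:
    """Write a trace as float32 WAV plus a JSON metadata sidecar."""
    path = Path(path)
    wavfile.write(path, int(round(trace.sampling_rate)), trace.data.astype(np.float32))
    _write_meta(path, trace)


def read_wav(path: str | Path) -> Trace:
    path = Path(path)
    fs, data = wavfile.read(path)
    meta = _read_meta(path)
    return Trace(
        np.asarray(data, dtype=np.float64),
        sampling_rate=float(meta.get("sampling_rate", fs)),
        start_time=pd.Timestamp(meta["start_time"]) if "start_time" in meta else DEFAULT_EPOCH,
        channel=meta.get("channel", "Z"),
        domain=meta.get("domain", SEISMIC),
        units=meta.get("units", "um/s"),
    )


def write_csv(path: str | Path, trace: Trace) -> None:
    """Write a trace as (time_s, amplitude) CSV plus a metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.times(), "amplitude": trace.data}).to_csv(
        path, index=False
    )
    _write_meta(path, trace)


def read_csv(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if t.size > 1 and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling in CSV waveform")
    fs = 1.0 / dt[0] if t.size > 1 else 200.0
    meta = _read_meta(path)
    return Trace(
        df["amplitude"].to_numpy(dtype=np.float64),
        sampling_rate=float(meta.get("sampling_rate", fs)),
        start_time=pd.Timestamp(meta["start_time"]) if "start_time" in meta else DEFAULT_EPOCH,
        channel=meta.get("channel", "Z"),
        domain=meta.get("domain", SEISMIC),
        units=meta.get("units", "um/s"),
    )


def read_waveform(path: str | Path) -> Trace:
    """Dispatch on file extension (.wav or .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        return read_wav(path)
    if path.suffix.lower() == ".csv":
        return read_csv(path)
    raise ValueError(f"unsupported waveform format: {path.suffix} (use WAV or CSV)")


def write_waveform(path: str | Path, trace: Trace) -> None:
    path = Path(path)
    if path.suffix.lower() == ".wav":
        write_wav(path, trace)
    elif path.suffix.lower() == ".csv":
        write_csv(path, trace)
    else:
        raise ValueError(f"unsupported waveform format: {path.suffix} (use WAV or CSV)")
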