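"""Synthetic seismo-acoustic scene generation with known ground truth.

Emulates the phenomenology of a zoo enclosure monitored by a co-located
three-component seismometer and an infrasound sensor, both at 200 Hz:

* **Rumbles** — tonal elephant calls with a fundamental at 10–25 Hz,
  harmonics above (first harmonic 25–45 Hz), durations of 1–8 s and peak
  ground velocities of 1–10 µm/s.  The same source waveform is rendered on
  the seismic channels (partitioned by a per-call direction cosine) and on
  the pressure channel, so the two domains carry matched call physics.
* **Footfalls** — short broadband ground-velocity impulses from locomotion
  and trampling; they appear on the seismic channels only and never on the
  pressure channel.
* **Noise** — Gaussian background at a night-time RMS that rises by a
  configurable factor (5–10 for the seismic channels) inside opening hours,
  plus daytime monochromatic machine lines (12/25/30 Hz) and short broadband
  bursts on the seismic channels.
* **Housing schedule** — a per-night multiplicative factor on the nocturnal
  rumble rate, reproducing the alternating high/low activity of two
  elephant sub-groups housed indoors on alternating nights.

Every drawn quantity comes from a single seeded generator, so a scene is a
pure function of its configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .trace import (
    DEFAULT_EPOCH,
    INFRASOUND,
    SEISMIC,
    Trace,
    write_waveform,
)

logger = logging.getLogger(__name__)


class AliasingError(ValueError):
    """A requested harmonic lies at or above the Nyquist frequency."""


# ----------------------------------------------------------------------
# Source specifications


@dataclass
class RumbleSpec:
    """One tonal call: frequency contour, harmonic stack and amplitudes.

    ``apex_frequency`` is the maximum of the fundamental's frequency
    contour, reached at the temporal centre of the call; the contour falls
    off by the fraction ``contour_depth`` at the edges.  ``n_harmonics``
    counts overtones above the fundamental, each scaled by
    ``harmonic_decay`` per order.
    """

    onset_time: float
    apex_frequency: float
    duration: float
    n_harmonics: int = 1
    harmonic_decay: float = 0.5
    peak_ground_velocity: float = 5.0
    peak_pressure: float = 0.05
    contour_depth: float = 0.1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.apex_frequency <= 0:
            raise ValueError("apex_frequency must be positive")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")
        if not 0 < self.harmonic_decay <= 1:
            raise ValueError("harmonic_decay must be in (0, 1]")
        if not 0 <= self.contour_depth < 1:
            raise ValueError("contour_depth must be in [0, 1)")
        if self.peak_ground_velocity < 0 or self.peak_pressure < 0:
            raise ValueError("peak amplitudes must be non-negative")


@dataclass
class FootfallSpec:
    """One broadband locomotion impulse (seismic channels only)."""

    onset_time: float
    impulse_duration: float = 0.15
    peak_ground_velocity: float = 5.0
    spectral_corner: float = 25.0

    def __post_init__(self) -> None:
        if self.impulse_duration <= 0:
            raise ValueError("impulse_duration must be positive")
        if self.peak_ground_velocity < 0:
            raise ValueError("peak_ground_velocity must be non-negative")


@dataclass
class NoiseModel:
    """Diurnal background-noise model for both sensing domains.

    Night-time backgrounds are Gaussian at the stated RMS.  Inside
    ``opening_hours`` the RMS is multiplied by the domain's day factor; the
    seismic channels additionally carry monochromatic machine lines and
    Poisson-scheduled broadband bursts during the day.
    """

    night_rms_seismic: float = 0.05  # µm/s
    day_factor_seismic: float = 7.0  # in the observed 5-10 range
    machine_line_freqs: tuple[float, ...] = (12.0, 25.0, 30.0)
    machine_line_rms: float = 0.07  # µm/s per line
    night_rms_infrasound: float = 0.002  # Pa
    day_factor_infrasound: float = 2.0
    burst_rate_day: float = 20.0  # events/hour inside opening hours
    opening_hours: tuple[float, float] = (7.0, 17.0)  # [start, end) UTC

    def __post_init__(self) -> None:
        if not self.day_factor_seismic > self.day_factor_infrasound >= 1:
            raise ValueError(
                "require day_factor_seismic > day_factor_infrasound >= 1"
            )


def hour_of_day_clock(start_time: pd.Timestamp) -> Callable[[np.ndarray], np.ndarray]:
    """Map scene time (s since ``start_time``) to UTC hour-of-day."""
    t0 = (
        start_time.hour
        + start_time.minute / 60.0
        + start_time.second / 3600.0
    )

    def clock(t: np.ndarray) -> np.ndarray:
        return (t0 + np.asarray(t, dtype=float) / 3600.0) % 24.0

    return clock


def is_open(hours: np.ndarray, opening_hours: tuple[float, float]) -> np.ndarray:
    """Boolean mask for hours inside the half-open opening interval."""
    lo, hi = opening_hours
    hours = np.asarray(hours)
    if lo <= hi:
        return (hours >= lo) & (hours < hi)
    return (hours >= lo) | (hours < hi)  # interval wraps midnight


# ----------------------------------------------------------------------
# Elementary source synthesis


def synth_rumble(
    spec: RumbleSpec, sampling_rate: float, domain: str = SEISMIC
) -> np.ndarray:
    """Render one rumble as an amplitude segment of ``duration`` seconds.

    The fundamental follows a raised-cosine frequency contour rising from
    ``apex × (1 − contour_depth)`` at the edges to ``apex_frequency`` at the
    temporal centre; overtones are exact integer multiples of the
    instantaneous fundamental with geometrically decaying amplitude and a
    shared cosine-tapered envelope.  The peak absolute amplitude equals the
    spec's peak ground velocity (seismic) or peak pressure (infrasound).
    """
    top = spec.apex_frequency * (spec.n_harmonics + 1)
    if top >= sampling_rate / 2:
        raise AliasingError(
            f"harmonic at {top:g} Hz >= Nyquist ({sampling_rate / 2:g} Hz)"
        )
    n = int(round(spec.duration * sampling_rate))
    peak = (
        spec.peak_ground_velocity if domain == SEISMIC else spec.peak_pressure
    )
    if n == 0:
        return np.zeros(0)
    t = np.arange(n) / sampling_rate
    # contour weight: raised-cosine ramps over the outer quarters with a
    # plateau at 1 across the central half, so the call dwells at its apex
    # and the spectral peak of the fundamental sits at apex_frequency
    tau = 0.25 * spec.duration
    w = np.ones(n)
    rising = t < tau
    falling = t > spec.duration - tau
    w[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / tau))
    w[falling] = 0.5 * (1.0 - np.cos(np.pi * (spec.duration - t[falling]) / tau))
    f_inst = spec.apex_frequency * (1.0 - spec.contour_depth * (1.0 - w))
    phase = 2.0 * np.pi * np.cumsum(f_inst) / sampling_rate
    seg = np.zeros(n)
    for k in range(1, spec.n_harmonics + 2):
        seg += spec.harmonic_decay ** (k - 1) * np.sin(k * phase)
    seg *= signal.windows.tukey(n, alpha=0.2)
    m = np.max(np.abs(seg))
    if m > 0 and peak > 0:
        seg *= peak / m
    else:
        seg[:] = 0.0
    return seg


def synth_footfall(
    spec: FootfallSpec, sampling_rate: float, seed: int = 0
) -> np.ndarray:
    """Render one footfall: exponentially damped band-limited noise burst."""
    n = int(round(spec.impulse_duration * sampling_rate))
    if n < 4:
        raise ValueError("impulse_duration x sampling_rate must be >= 4 samples")
    rng = np.random.default_rng(seed)
    burst = rng.standard_normal(n)
    corner = min(spec.spectral_corner, 0.45 * sampling_rate)
    sos = signal.butter(4, corner, btype="highpass", fs=sampling_rate, output="sos")
    burst = signal.sosfilt(sos, burst)
    t = np.arange(n) / sampling_rate
    burst *= np.exp(-4.0 * t / spec.impulse_duration)
    m = np.max(np.abs(burst))
    if m > 0 and spec.peak_ground_velocity > 0:
        burst *= spec.peak_ground_velocity / m
    else:
        burst[:] = 0.0
    return burst


def synth_noise(
    model: NoiseModel,
    domain: str,
    t_start: float,
    t_end: float,
    clock: Callable[[np.ndarray], np.ndarray],
    seed: int,
    sampling_rate: float = 200.0,
) -> np.ndarray:
    """Background noise for ``[t_start, t_end)`` scene seconds.

    Gaussian broadband noise at the domain's night RMS, multiplied by the
    day factor inside opening hours.  Seismic noise additionally carries
    daytime sinusoidal machine lines and Poisson-scheduled broadband bursts.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    rng = np.random.default_rng(seed)
    n = int(round((t_end - t_start) * sampling_rate))
    t = t_start + np.arange(n) / sampling_rate
    day = is_open(clock(t), model.opening_hours)

    if domain == SEISMIC:
        night_rms, day_factor = model.night_rms_seismic, model.day_factor_seismic
    else:
        night_rms, day_factor = (
            model.night_rms_infrasound,
            model.day_factor_infrasound,
        )

    out = rng.standard_normal(n) * night_rms
    out[day] *= day_factor

    if domain == SEISMIC and day.any():
        phases = rng.uniform(0, 2 * np.pi, size=len(model.machine_line_freqs))
        lines = np.zeros(n)
        for f, ph in zip(model.machine_line_freqs, phases):
            lines += np.sqrt(2.0) * model.machine_line_rms * np.sin(
                2 * np.pi * f * t + ph
            )
        out[day] += lines[day]

        day_seconds = day.sum() / sampling_rate
        n_bursts = rng.poisson(model.burst_rate_day * day_seconds / 3600.0)
        day_idx = np.flatnonzero(day)
        day_rms = night_rms * day_factor
        for _ in range(n_bursts):
            dur = rng.uniform(0.5, 2.0)
            m = int(round(dur * sampling_rate))
            i0 = int(rng.choice(day_idx))
            m = min(m, n - i0)
            if m < 8:
                continue
            amp = rng.uniform(1.5, 3.0) * day_rms
            env = signal.windows.hann(m)
            out[i0 : i0 + m] += amp * env * rng.standard_normal(m)
    return out


# ----------------------------------------------------------------------
# Scene configuration and rendering


@dataclass
class SceneConfig:
    """Everything needed to render one reproducible scene.

    Sources can be given explicitly (``rumble_specs``/``footfall_specs``) or
    drawn from the default priors via ``rumble_rate`` (calls/hour at night,
    modulated per night by ``housing_schedule``) and ``footfall_coupling``
    (probability that a rumble is accompanied by a locomotion cluster).
    """

    duration: float
    sampling_rate: float = 200.0
    seed: int = 0
    start_time: pd.Timestamp = field(default_factory=lambda: DEFAULT_EPOCH)
    rumble_specs: list[RumbleSpec] | None = None
    rumble_rate: float = 10.0  # calls/hour, nocturnal baseline
    day_rate_factor: float = 0.6  # daytime rate relative to nocturnal baseline
    footfall_specs: list[FootfallSpec] | None = None
    footfall_coupling: float = 0.67  # fraction of rumbles with motion signals
    noise: NoiseModel = field(default_factory=NoiseModel)
    housing_schedule: tuple[float, ...] = (1.0, 4.0)  # per-night rate factors

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not isinstance(self.start_time, pd.Timestamp):
            self.start_time = pd.Timestamp(self.start_time)
        # Nyquist guard for the default priors (apex <= 25 Hz, <= 2 overtones)
        if self.sampling_rate <= 2 * 25.0 * 3:
            raise ValueError("sampling_rate must exceed twice the highest frequency")

    # -- file round trip ------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "SceneConfig":
        path = Path(path)
        text = path.read_text()
        raw = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        if "seed" not in raw:
            raise ValueError("scene config file must state a seed")
        if "noise" in raw and isinstance(raw["noise"], dict):
            nm = dict(raw["noise"])
            for key in ("machine_line_freqs", "opening_hours"):
                if key in nm:
                    nm[key] = tuple(nm[key])
            raw["noise"] = NoiseModel(**nm)
        if raw.get("rumble_specs"):
            raw["rumble_specs"] = [RumbleSpec(**r) for r in raw["rumble_specs"]]
        if raw.get("footfall_specs"):
            raw["footfall_specs"] = [FootfallSpec(**f) for f in raw["footfall_specs"]]
        if "housing_schedule" in raw:
            raw["housing_schedule"] = tuple(raw["housing_schedule"])
        return cls(**raw)


@dataclass
class GroundTruthCatalog:
    """The sources actually injected into a scene, sorted by onset."""

    rumbles: list[RumbleSpec]
    footfalls: list[FootfallSpec]

    def __post_init__(self) -> None:
        self.rumbles = sorted(self.rumbles, key=lambda s: s.onset_time)
        self.footfalls = sorted(self.footfalls, key=lambda s: s.onset_time)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "type": "rumble",
                "onset_time": s.onset_time,
                "apex_frequency": s.apex_frequency,
                "duration": s.duration,
                "peak_amplitude": s.peak_ground_velocity,
            }
            for s in self.rumbles
        ] + [
            {
                "type": "footfall",
                "onset_time": s.onset_time,
                "apex_frequency": np.nan,
                "duration": s.impulse_duration,
                "peak_amplitude": s.peak_ground_velocity,
            }
            for s in self.footfalls
        ]
        df = pd.DataFrame(
            rows,
            columns=["type", "onset_time", "apex_frequency", "duration", "peak_amplitude"],
        )
        return df.sort_values("onset_time", kind="stable").reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SceneBundle:
    """Rendered scene: three seismic traces, one pressure trace, the truth."""

    seismic_N: Trace
    seismic_E: Trace
    seismic_Z: Trace
    infrasound: Trace
    truth: GroundTruthCatalog
    config: SceneConfig

    @property
    def seismic(self) -> list[Trace]:
        return [self.seismic_N, self.seismic_E, self.seismic_Z]

    def write(self, directory: str | Path, fmt: str = "wav") -> dict[str, str]:
        """Write all four channels plus the truth catalog; returns paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, tr in [
            ("seismic_N", self.seismic_N),
            ("seismic_E", self.seismic_E),
            ("seismic_Z", self.seismic_Z),
            ("infrasound", self.infrasound),
        ]:
            p = directory / f"{name}.{fmt}"
            write_waveform(p, tr)
            paths[name] = str(p)
        truth_path = directory / "truth_catalog.csv"
        self.truth.to_csv(truth_path)
        paths["truth"] = str(truth_path)
        return paths


# -- priors -------------------------------------------------------------


def draw_rumble_spec(rng: np.random.Generator, onset_time: float) -> RumbleSpec:
    """Draw one call from the default priors.

    Fundamental uniform on 10–25 Hz, duration triangular on 1–8 s with mode
    3.5 s (mean ≈ 4 s), peak ground velocity uniform on 1–10 µm/s; usually
    one overtone, occasionally two.
    """
    return RumbleSpec(
        onset_time=onset_time,
        apex_frequency=rng.uniform(10.0, 25.0),
        duration=rng.triangular(1.0, 3.5, 8.0),
        n_harmonics=int(rng.choice([1, 1, 1, 2])),
        harmonic_decay=rng.uniform(0.3, 0.7),
        peak_ground_velocity=rng.uniform(1.0, 10.0),
        peak_pressure=rng.uniform(0.02, 0.2),
        contour_depth=rng.uniform(0.05, 0.2),
    )


def draw_footfall_spec(rng: np.random.Generator, onset_time: float) -> FootfallSpec:
    return FootfallSpec(
        onset_time=onset_time,
        impulse_duration=rng.uniform(0.05, 0.3),
        peak_ground_velocity=rng.uniform(2.0, 10.0),
        spectral_corner=25.0,
    )


def _schedule_rumbles(config: SceneConfig, rng: np.random.Generator) -> list[RumbleSpec]:
    """Poisson schedule with day/night and per-night housing modulation."""
    clock = hour_of_day_clock(config.start_time)
    grid = 60.0  # rate treated as constant per minute
    edges = np.arange(0.0, config.duration + grid, grid)
    specs: list[RumbleSpec] = []
    open_lo, _ = config.noise.opening_hours
    for lo in edges[:-1]:
        hi = min(lo + grid, config.duration)
        h = clock(np.array([lo]))[0]
        daytime = bool(is_open(np.array([h]), config.noise.opening_hours)[0])
        if daytime:
            rate = config.rumble_rate * config.day_rate_factor
        else:
            # index nights by the number of opening times passed since start
            night_idx = int((lo / 3600.0 + config.start_time.hour) // 24.0)
            factor = config.housing_schedule[
                night_idx % len(config.housing_schedule)
            ]
            rate = config.rumble_rate * factor
        lam = rate * (hi - lo) / 3600.0
        for _ in range(rng.poisson(lam)):
            onset = rng.uniform(lo, hi)
            spec = draw_rumble_spec(rng, onset)
            if onset + spec.duration < config.duration:
                specs.append(spec)
    return sorted(specs, key=lambda s: s.onset_time)


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    """Unit direction cosines (N, E, Z) for partitioning seismic energy."""
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def render_scene(config: SceneConfig) -> SceneBundle:
    """Render a full scene: noise plus injected sources, with ground truth.

    Rumbles appear on all four channels — the seismic waveform is
    partitioned across N/E/Z by per-call direction cosines so that the
    vector-sum peak equals the spec's peak ground velocity — while footfalls
    are rendered on the seismic channels only.  Identical configurations
    (including the seed) give bit-identical bundles.
    """
    fs = config.sampling_rate
    rng = np.random.default_rng(config.seed)
    clock = hour_of_day_clock(config.start_time)
    n = int(round(config.duration * fs))

    child = rng.spawn(5)
    chans = {
        "N": synth_noise(config.noise, SEISMIC, 0, config.duration, clock,
                         child[0].integers(2**31), fs),
        "E": synth_noise(config.noise, SEISMIC, 0, config.duration, clock,
                         child[1].integers(2**31), fs),
        "Z": synth_noise(config.noise, SEISMIC, 0, config.duration, clock,
                         child[2].integers(2**31), fs),
    }
    pressure = synth_noise(config.noise, INFRASOUND, 0, config.duration, clock,
                           child[3].integers(2**31), fs)
    src_rng = child[4]

    if config.rumble_specs is not None:
        rumbles = sorted(config.rumble_specs, key=lambda s: s.onset_time)
    else:
        rumbles = _schedule_rumbles(config, src_rng)

    prev_end = -np.inf
    for spec in rumbles:
        if spec.onset_time < prev_end:
            logger.warning("overlapping rumbles at t=%.1f s", spec.onset_time)
        prev_end = max(prev_end, spec.onset_time + spec.duration)
        i0 = int(round(spec.onset_time * fs))
        seg = synth_rumble(spec, fs, SEISMIC)
        seg_p = synth_rumble(spec, fs, INFRASOUND)
        i1 = min(i0 + seg.size, n)
        if i1 <= i0:
            continue
        d = _random_direction(src_rng)
        for comp, ch in enumerate("NEZ"):
            chans[ch][i0:i1] += d[comp] * seg[: i1 - i0]
        pressure[i0:i1] += seg_p[: i1 - i0]

    if config.footfall_specs is not None:
        footfalls = sorted(config.footfall_specs, key=lambda s: s.onset_time)
    else:
        footfalls = []
        for spec in rumbles:
            if src_rng.uniform() < config.footfall_coupling:
                k = int(src_rng.integers(2, 7))
                offsets = src_rng.uniform(-30.0, 30.0, size=k)
                for off in offsets:
                    onset = spec.onset_time + off
                    if 0 <= onset < config.duration - 0.5:
                        footfalls.append(draw_footfall_spec(src_rng, onset))
        footfalls.sort(key=lambda s: s.onset_time)

    for spec in footfalls:
        i0 = int(round(spec.onset_time * fs))
        seg = synth_footfall(spec, fs, seed=int(src_rng.integers(2**31)))
        i1 = min(i0 + seg.size, n)
        if i1 <= i0:
            continue
        d = _random_direction(src_rng)
        for comp, ch in enumerate("NEZ"):
            chans[ch][i0:i1] += d[comp] * seg[: i1 - i0]

    def mk(ch: str, data: np.ndarray, domain: str, units: str) -> Trace:
        return Trace(data, fs, config.start_time, ch, domain, units)

    return SceneBundle(
        seismic_N=mk("N", chans["N"], SEISMIC, "um/s"),
        seismic_E=mk("E", chans["E"], SEISMIC, "um/s"),
        seismic_Z=mk("Z", chans["Z"], SEISMIC, "um/s"),
        infrasound=mk("P", pressure, INFRASOUND, "Pa"),
        truth=GroundTruthCatalog(rumbles, footfalls),
        config=config,
    )


# ----------------------------------------------------------------------
# Labeled training snippets


def make_training_snippets(
    n_rumble: int,
    n_noise: int,
    domain: str,
    seed: int,
    noise_model: NoiseModel | None = None,
    snippet_length: float = 12.0,
    sampling_rate: float = 200.0,
    footfall_fraction: float = 0.5,
) -> list[tuple[list[Trace], int]]:
    """Generate labeled 12-s snippets for classifier training.

    Rumble snippets carry one call drawn from the default priors with its
    pick time at the temporal centre; noise snippets carry background only.
    Day and night backgrounds are sampled in equal proportion so the
    classifier sees the full diurnal noise variability, and half of the
    seismic snippets of either class also contain a footfall cluster of
    1-5 impulses — matching the locomotion-coupled clusters that rendered
    scenes place around calls, so a rumble buried in trampling is still a
    rumble to the classifier.  Returns ``(traces, label)`` pairs with
    label 1 for rumble, 0 for noise; seismic samples hold the three
    component traces, infrasound one trace.
    """
    if noise_model is None:
        noise_model = NoiseModel()
    rng = np.random.default_rng(seed)
    out: list[tuple[list[Trace], int]] = []
    labels = [1] * n_rumble + [0] * n_noise
    centre = snippet_length / 2.0
    for i, label in enumerate(labels):
        daytime = i % 2 == 0
        start_hour = 10.0 if daytime else 22.0
        t0 = pd.Timestamp("2024-08-02") + pd.Timedelta(hours=start_hour)
        clock = hour_of_day_clock(t0)
        sub = rng.spawn(1)[0]
        channels = "NEZ" if domain == SEISMIC else "P"
        datas = {
            ch: synth_noise(
                noise_model, domain, 0, snippet_length, clock,
                int(sub.integers(2**31)), sampling_rate,
            )
            for ch in channels
        }
        if domain == SEISMIC and rng.uniform() < footfall_fraction:
            k = int(rng.integers(1, 6))
            for _ in range(k):
                f_spec = draw_footfall_spec(rng, rng.uniform(0.5, snippet_length - 1))
                seg = synth_footfall(f_spec, sampling_rate, seed=int(rng.integers(2**31)))
                i0 = int(round(f_spec.onset_time * sampling_rate))
                d = _random_direction(rng)
                for comp, ch in enumerate("NEZ"):
                    datas[ch][i0 : i0 + seg.size] += d[comp] * seg
        if label == 1:
            spec = draw_rumble_spec(rng, 0.0)
            seg = synth_rumble(
                spec, sampling_rate, SEISMIC if domain == SEISMIC else INFRASOUND
            )
            i0 = int(round((centre - spec.duration / 2) * sampling_rate))
            if domain == SEISMIC:
                d = _random_direction(rng)
                for comp, ch in enumerate("NEZ"):
                    datas[ch][i0 : i0 + seg.size] += d[comp] * seg
            else:
                datas["P"][i0 : i0 + seg.size] += seg
        traces = [
            Trace(
                datas[ch],
                sampling_rate,
                t0,
                ch,
                domain,
                "um/s" if domain == SEISMIC else "Pa",
            )
            for ch in channels
        ]
        out.append((traces, label))
    return out


def synth_polarized_call(
    fundamental: float = 18.0,
    harmonic_ratio: int = 2,
    duration: float = 4.0,
    sampling_rate: float = 200.0,
    fundamental_amplitude: float = 5.0,
    harmonic_amplitude: float = 3.0,
    noise_rms: float = 0.02,
    seed: int = 0,
) -> tuple[Trace, Trace, Trace]:
    """Three-component call with a vertically polarized fundamental and a
    transversely (horizontally) polarized overtone, for particle-motion
    studies: the fundamental rides on Z, the overtone on N/E."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    env = signal.windows.tukey(n, alpha=0.2)
    fund = fundamental_amplitude * env * np.sin(2 * np.pi * fundamental * t)
    harm = harmonic_amplitude * env * np.sin(
        2 * np.pi * fundamental * harmonic_ratio * t
    )
    az = rng.uniform(0, 2 * np.pi)
    data = {
        "N": harm * np.cos(az) + noise_rms * rng.standard_normal(n),
        "E": harm * np.sin(az) + noise_rms * rng.standard_normal(n),
        "Z": fund + noise_rms * rng.standard_normal(n),
    }
    return tuple(
        Trace(data[ch], sampling_rate, DEFAULT_EPOCH, ch, SEISMIC, "um/s")
        for ch in "NEZ"
    )
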