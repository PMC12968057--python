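"""Particle-motion analysis of three-component seismic windows.

Band-passed N/E/Z windows are summarized by the eigen-structure of their
3×3 zero-lag covariance matrix.  A vertical-to-horizontal energy ratio far
above one together with a steep dominant eigenvector indicates
Rayleigh-type (vertical-plane) particle motion; energy concentrated in the
horizontal plane indicates Love-type (transverse) motion.  Applied per
frequency band, this separates a vertically polarized fundamental from a
horizontally polarized first harmonic within one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sigproc import bandpass_filter
from .trace import Trace

RAYLEIGH_LIKE = "rayleigh_like"
LOVE_LIKE = "love_like"
MIXED = "mixed"

#: default analysis bands: fundamental and first harmonic (Hz)
DEFAULT_BANDS = ((16.0, 20.0), (30.0, 40.0))

#: vh_ratio at or above this → rayleigh_like
RAYLEIGH_THRESHOLD = 2.0
#: vh_ratio at or below this → love_like.  Note: for isotropic noise the
#: expected Z/(N+E) energy ratio is exactly 0.5, so the love threshold sits
#: well below it to keep unpolarized windows classified as mixed.
LOVE_THRESHOLD = 0.25


@dataclass
class PolarizationResult:
    """Summary of particle motion in one frequency band."""

    band: tuple[float, float]
    vh_ratio: float  # vertical / horizontal energy, >= 0
    incidence_angle: float  # dominant eigenvector, degrees from horizontal
    rectilinearity: float  # 0 (isotropic) .. 1 (linear)
    classification: str

    def __post_init__(self) -> None:
        if self.vh_ratio < 0:
            raise ValueError("vh_ratio must be >= 0")
        if not 0 <= self.incidence_angle <= 90:
            raise ValueError("incidence angle must lie in [0, 90] degrees")


def _classify(vh_ratio: float) -> str:
    if vh_ratio >= RAYLEIGH_THRESHOLD:
        return RAYLEIGH_LIKE
    if vh_ratio <= LOVE_THRESHOLD:
        return LOVE_LIKE
    return MIXED


def particle_motion(
    trace_n: Trace,
    trace_e: Trace,
    trace_z: Trace,
    band: tuple[float, float],
) -> PolarizationResult:
    """Covariance eigen-analysis of a band-passed three-component window.

    ``vh_ratio`` is the Z-component energy over the summed N+E energy;
    the incidence angle is measured between the dominant covariance
    eigenvector and the horizontal plane; rectilinearity is
    ``1 − (λ₂+λ₃)/(2λ₁)`` from the sorted eigenvalues.
    """
    comps = []
    for tr in (trace_n, trace_e, trace_z):
        f = bandpass_filter(tr, band[0], band[1])
        comps.append(f.data - f.data.mean())
    x = np.vstack(comps)  # rows: N, E, Z
    energies = np.sum(x**2, axis=1)
    if np.all(energies == 0):
        raise ValueError("zero-energy window: cannot analyze particle motion")
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    dominant = evecs[:, 0]
    incidence = float(np.degrees(np.arcsin(np.clip(abs(dominant[2]), 0, 1))))
    horiz = energies[0] + energies[1]
    vh = float(energies[2] / horiz) if horiz > 0 else np.inf
    rect = float(1.0 - (evals[1] + evals[2]) / (2.0 * evals[0])) if evals[0] > 0 else 0.0
    return PolarizationResult(
        band=band,
        vh_ratio=vh,
        incidence_angle=incidence,
        rectilinearity=max(0.0, min(1.0, rect)),
        classification=_classify(vh),
    )


def classify_band_polarization(
    trace_n: Trace,
    trace_e: Trace,
    trace_z: Trace,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> dict[tuple[float, float], PolarizationResult]:
    """Run :func:`particle_motion` per band and classify each result."""
    return {
        tuple(band): particle_motion(trace_n, trace_e, trace_z, tuple(band))
        for band in bands
    }


def polarization_table(
    results: dict[tuple[float, float], PolarizationResult]
) -> pd.DataFrame:
    rows = [
        {
            "f_lo_hz": band[0],
            "f_hi_hz": band[1],
            "vh_ratio": r.vh_ratio,
            "incidence_deg": r.incidence_angle,
            "rectilinearity": r.rectilinearity,
            "classification": r.classification,
        }
        for band, r in results.items()
    ]
    return pd.DataFrame(rows)


def write_polarization_csv(
    results: dict[tuple[float, float], PolarizationResult], path: str | Path
) -> None:
    polarization_table(results).to_csv(path, index=False)
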