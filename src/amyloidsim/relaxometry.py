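"""Spin-echo T2' fitting and linewidth decomposition.

The bulk coherence lifetime T2' is fitted from a variable-delay spin-echo
decay with a single exponential I(tau) = I0 exp(-tau / T2').  It sets the
homogeneous (dynamic) part of the linewidth as the Lorentzian FWHM
1/(pi T2'); the remainder of the observed total width is attributed to static
structural heterogeneity (additive decomposition, e.g. an observed 750 Hz
width splitting into 250 Hz from dynamics and 500 Hz from heterogeneity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .spectra import SpectrometerConfig, hz_to_ppm

__all__ = [
    "RelaxationDecay",
    "ExponentialFit",
    "LinewidthBudget",
    "read_decay",
    "fit_t2",
    "homogeneous_linewidth",
    "t2_for_linewidth",
    "decompose_linewidth",
]


@dataclass(frozen=True)
class ExponentialFit:
    i0: float
    t2_prime_ms: float
    residual: float  # root-mean-square residual, intensity units
    stderr_ms: float = float("nan")


@dataclass
class RelaxationDecay:
    delays_ms: np.ndarray
    intensities: np.ndarray
    temperature_C: float | None = None
    fit: ExponentialFit | None = None

    def __post_init__(self) -> None:
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays_ms.shape != self.intensities.shape:
            raise ValueError("delays and intensities differ in length")
        if len(self.delays_ms) < 3:
            raise ValueError("need at least 3 points to fit a decay")
        if np.any(self.delays_ms < 0):
            raise ValueError("delays must be >= 0")
        if np.any(np.diff(self.delays_ms) <= 0):
            raise ValueError("delays must be strictly increasing")


def read_decay(path: str | Path) -> RelaxationDecay:
    """Two-column text (delay_ms, intensity), optional third column temperature."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError("decay file needs at least 2 columns")
    temp = float(data[0, 2]) if data.shape[1] > 2 else None
    return RelaxationDecay(data[:, 0], data[:, 1], temperature_C=temp)


def fit_t2(d: RelaxationDecay, with_offset: bool = False) -> RelaxationDecay:
    """Least-squares single-exponential fit; initialized from log-linear regression.

    By default the model is a pure exponential (no baseline term);
    ``with_offset=True`` adds a constant baseline ``I(tau) = I0 e^(-tau/T2') + c``
    for decays that do not relax to zero.  Raises ``ValueError`` for
    non-decaying data (constant or growing intensities, for which T2' would
    be infinite or negative).
    """
    if np.any(d.intensities <= 0):
        raise ValueError("intensities must be positive for the exponential fit")
    slope, logi0 = np.polyfit(d.delays_ms, np.log(d.intensities), 1)
    if slope >= -1e-12:
        raise ValueError("non-decaying data: fitted T2' would be infinite or negative")
    if with_offset:
        if len(d.delays_ms) < 4:
            raise ValueError("offset fit needs at least 4 points")
        p0 = (float(np.exp(logi0)), float(-1.0 / slope), 0.0)

        def model(tau, i0, t2, c):
            return i0 * np.exp(-tau / t2) + c

    else:
        p0 = (float(np.exp(logi0)), float(-1.0 / slope))

        def model(tau, i0, t2):
            return i0 * np.exp(-tau / t2)

    popt, pcov = curve_fit(model, d.delays_ms, d.intensities, p0=p0, maxfev=10000)
    i0, t2 = popt[0], popt[1]
    if t2 <= 0:
        raise ValueError(f"fit converged to non-physical T2' = {t2:.3g} ms")
    resid = d.intensities - model(d.delays_ms, *popt)
    stderr = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    fit = ExponentialFit(float(i0), float(t2), float(np.sqrt(np.mean(resid**2))), stderr)
    return RelaxationDecay(d.delays_ms, d.intensities, d.temperature_C, fit)


def homogeneous_linewidth(t2_prime_ms: float) -> float:
    """Lorentzian FWHM in Hz from the coherence lifetime: 1 / (pi T2')."""
    if t2_prime_ms <= 0:
        raise ValueError("T2' must be > 0")
    if np.isinf(t2_prime_ms):
        return 0.0
    return 1.0 / (np.pi * t2_prime_ms * 1e-3)


def t2_for_linewidth(width_hz: float) -> float:
    """Inverse of :func:`homogeneous_linewidth`: T2' (ms) giving a target FWHM."""
    if width_hz <= 0:
        raise ValueError("width must be > 0")
    return 1e3 / (np.pi * width_hz)


@dataclass(frozen=True)
class LinewidthBudget:
    """Additive split of an observed linewidth: total = homogeneous + heterogeneous."""

    total_hz: float
    homogeneous_hz: float
    heterogeneous_hz: float
    field: SpectrometerConfig = field(default_factory=SpectrometerConfig)

    def __post_init__(self) -> None:
        if min(self.total_hz, self.homogeneous_hz, self.heterogeneous_hz) < 0:
            raise ValueError("linewidths must be >= 0")
        if abs(self.homogeneous_hz + self.heterogeneous_hz - self.total_hz) > 1e-9 * max(1.0, self.total_hz):
            raise ValueError("budget must satisfy homogeneous + heterogeneous = total")

    def in_ppm(self, nucleus: str = "C13") -> dict[str, float]:
        return {
            "total_ppm": hz_to_ppm(self.total_hz, nucleus, self.field),
            "homogeneous_ppm": hz_to_ppm(self.homogeneous_hz, nucleus, self.field),
            "heterogeneous_ppm": hz_to_ppm(self.heterogeneous_hz, nucleus, self.field),
        }

    def report(self, nucleus: str = "C13") -> str:
        ppm = self.in_ppm(nucleus)
        return (
            f"total_hz\t{self.total_hz:.0f}\t{ppm['total_ppm']:.1f} ppm\n"
            f"homogeneous_hz\t{self.homogeneous_hz:.0f}\t{ppm['homogeneous_ppm']:.1f} ppm\n"
            f"heterogeneous_hz\t{self.heterogeneous_hz:.0f}\t{ppm['heterogeneous_ppm']:.1f} ppm\n"
        )


def decompose_linewidth(
    total_hz: float,
    t2_prime_ms: float,
    cfg: SpectrometerConfig | None = None,
) -> LinewidthBudget:
    """Split an observed linewidth into dynamic and heterogeneous parts.

    The homogeneous part follows from T2'; the heterogeneous part is the
    remainder.  Raises if the homogeneous width alone exceeds the total.
    """
    homog = homogeneous_linewidth(t2_prime_ms)
    if homog > total_hz:
        raise ValueError(
            f"homogeneous width {homog:.1f} Hz exceeds total {total_hz:.1f} Hz"
        )
    return LinewidthBudget(
        total_hz=float(total_hz),
        homogeneous_hz=float(homog),
        heterogeneous_hz=float(total_hz - homog),
        field=cfg or SpectrometerConfig(),
    )
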