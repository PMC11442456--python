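"""Linewidth unit conversion, 2D Gaussian spectrum rendering and model scoring.

A peak list becomes a dense 2D intensity grid by placing a 2D Gaussian at
every peak position, with the per-axis standard deviation derived from the
desired full width at half maximum (sigma = FWHM / (2 sqrt(2 ln 2))).
Linewidths stated in Hz convert to ppm through the nucleus Larmor frequency
(e.g. a 500 Hz carbon width at an 850 MHz proton field is 2.3 ppm).
Candidate structural models are scored against a reference spectrum by the
Pearson correlation of their rendered grids over a spectral window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SpectrometerConfig",
    "Axis",
    "Spectrum2D",
    "nucleus_frequency",
    "hz_to_ppm",
    "ppm_to_hz",
    "render_spectrum",
    "sum_spectra",
    "compare_spectra",
    "rank_models",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# gyromagnetic frequency ratios relative to 1H (IUPAC Xi values)
DEFAULT_RATIOS = {"H1": 1.0, "C13": 0.25145020, "N15": 0.10136767}


@dataclass(frozen=True)
class SpectrometerConfig:
    proton_larmor: float = 850.0  # MHz
    frequency_ratio: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATIOS))

    def __post_init__(self) -> None:
        if self.proton_larmor <= 0:
            raise ValueError("proton_larmor must be > 0")


def nucleus_frequency(cfg: SpectrometerConfig, nucleus: str) -> float:
    """Larmor frequency of a nucleus in MHz."""
    try:
        ratio = cfg.frequency_ratio[nucleus]
    except KeyError as exc:
        raise ValueError(f"unknown nucleus {nucleus!r}") from exc
    return cfg.proton_larmor * ratio


def hz_to_ppm(width_hz: float, nucleus: str, cfg: SpectrometerConfig | None = None) -> float:
    """Convert a linewidth in Hz to ppm at the configured field."""
    if width_hz < 0:
        raise ValueError("width must be >= 0")
    cfg = cfg or SpectrometerConfig()
    return width_hz / nucleus_frequency(cfg, nucleus)


def ppm_to_hz(width_ppm: float, nucleus: str, cfg: SpectrometerConfig | None = None) -> float:
    if width_ppm < 0:
        raise ValueError("width must be >= 0")
    cfg = cfg or SpectrometerConfig()
    return width_ppm * nucleus_frequency(cfg, nucleus)


@dataclass(frozen=True)
class Axis:
    nucleus: str
    ppm_min: float
    ppm_max: float
    n_points: int

    def __post_init__(self) -> None:
        if self.ppm_min >= self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    def grid(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)

    @property
    def step(self) -> float:
        return (self.ppm_max - self.ppm_min) / (self.n_points - 1)


@dataclass
class Spectrum2D:
    axis1: Axis
    axis2: Axis
    grid: np.ndarray  # shape (axis1.n_points, axis2.n_points)
    fwhm_hz: tuple[float, float] = (0.0, 0.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (self.axis1.n_points, self.axis2.n_points):
            raise ValueError(
                f"grid shape {self.grid.shape} does not match axes "
                f"({self.axis1.n_points}, {self.axis2.n_points})"
            )
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("non-finite intensities")

    def same_axes(self, other: "Spectrum2D") -> bool:
        return self.axis1 == other.axis1 and self.axis2 == other.axis2

    def total(self) -> float:
        return float(self.grid.sum())

    def write(self, path: str | Path) -> None:
        """Axes header + dense grid as plain text."""
        header = (
            f"axis1 {self.axis1.nucleus} {self.axis1.ppm_min} {self.axis1.ppm_max} {self.axis1.n_points}\n"
            f"axis2 {self.axis2.nucleus} {self.axis2.ppm_min} {self.axis2.ppm_max} {self.axis2.n_points}\n"
            f"fwhm_hz {self.fwhm_hz[0]} {self.fwhm_hz[1]}\n"
            f"provenance {self.provenance}"
        )
        np.savetxt(path, self.grid, header=header)

    @classmethod
    def read(cls, path: str | Path) -> "Spectrum2D":
        lines = Path(path).read_text().splitlines()
        meta = {}
        for ln in lines[:4]:
            tok = ln.lstrip("# ").split(maxsplit=1)
            if tok:
                meta[tok[0]] = tok[1] if len(tok) > 1 else ""
        def _axis(s: str) -> Axis:
            n, lo, hi, npts = s.split()
            return Axis(n, float(lo), float(hi), int(npts))
        grid = np.loadtxt(path)
        f1, f2 = meta.get("fwhm_hz", "0 0").split()
        return cls(
            axis1=_axis(meta["axis1"]),
            axis2=_axis(meta["axis2"]),
            grid=grid,
            fwhm_hz=(float(f1), float(f2)),
            provenance=meta.get("provenance", ""),
        )


def render_spectrum(
    peaks,
    axis1: Axis,
    axis2: Axis,
    fwhm_hz: tuple[float, float] = (750.0, 750.0),
    cfg: SpectrometerConfig | None = None,
    provenance: str = "",
) -> Spectrum2D:
    """Render a peak list to a 2D Gaussian intensity grid.

    Each peak contributes ``A * G(omega1; sigma1) * G(omega2; sigma2)`` with
    unit apex height; sigma per axis comes from the requested FWHM (in Hz,
    converted at the configured field).  Peaks farther than 6 sigma outside
    the window are skipped.
    """
    import warnings

    cfg = cfg or SpectrometerConfig()
    if fwhm_hz[0] <= 0 or fwhm_hz[1] <= 0:
        raise ValueError("FWHM must be > 0")
    s1 = hz_to_ppm(fwhm_hz[0], axis1.nucleus, cfg) / FWHM_TO_SIGMA
    s2 = hz_to_ppm(fwhm_hz[1], axis2.nucleus, cfg) / FWHM_TO_SIGMA
    fwhm1_ppm = s1 * FWHM_TO_SIGMA
    if axis1.step > fwhm1_ppm / 3 or axis2.step > s2 * FWHM_TO_SIGMA / 3:
        warnings.warn("grid coarser than 3 points per FWHM; peaks will be undersampled")
    x = axis1.grid()
    y = axis2.grid()
    grid = np.zeros((axis1.n_points, axis2.n_points))
    peak_iter = peaks.peaks if hasattr(peaks, "peaks") else peaks
    for p in peak_iter:
        if not (axis1.ppm_min - 6 * s1 <= p.omega1 <= axis1.ppm_max + 6 * s1):
            continue
        if not (axis2.ppm_min - 6 * s2 <= p.omega2 <= axis2.ppm_max + 6 * s2):
            continue
        gx = np.exp(-0.5 * ((x - p.omega1) / s1) ** 2)
        gy = np.exp(-0.5 * ((y - p.omega2) / s2) ** 2)
        grid += p.amplitude * np.outer(gx, gy)
    return Spectrum2D(axis1, axis2, grid, fwhm_hz=fwhm_hz, provenance=provenance)


def sum_spectra(spectra: Sequence[Spectrum2D]) -> Spectrum2D:
    """Element-wise sum of spectra sharing identical axes."""
    if not spectra:
        raise ValueError("no spectra to sum")
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_axes(s):
            raise ValueError("cannot sum spectra with mismatched axes")
    grid = np.sum([s.grid for s in spectra], axis=0)
    prov = " + ".join(s.provenance for s in spectra if s.provenance)
    return replace(first, grid=grid, provenance=prov)


def _window_mask(axis1: Axis, axis2: Axis, window) -> tuple[np.ndarray, np.ndarray]:
    if window is None:
        return np.ones(axis1.n_points, bool), np.ones(axis2.n_points, bool)
    lo1, hi1, lo2, hi2 = window
    m1 = (axis1.grid() >= lo1) & (axis1.grid() <= hi1)
    m2 = (axis2.grid() >= lo2) & (axis2.grid() <= hi2)
    return m1, m2


def compare_spectra(a: Spectrum2D, b: Spectrum2D, window=None) -> float:
    """Pearson correlation of the two intensity grids over a spectral window.

    ``window`` is (ppm_min1, ppm_max1, ppm_min2, ppm_max2) or None for the
    whole grid.  Raises on zero-variance input.
    """
    if not a.same_axes(b):
        raise ValueError("spectra have mismatched axes")
    m1, m2 = _window_mask(a.axis1, a.axis2, window)
    ga = a.grid[np.ix_(m1, m2)].ravel()
    gb = b.grid[np.ix_(m1, m2)].ravel()
    if ga.size < 2:
        raise ValueError("window selects fewer than 2 grid points")
    va, vb = ga.std(), gb.std()
    if va == 0 or vb == 0:
        raise ValueError("zero-variance spectrum; correlation undefined")
    return float(np.corrcoef(ga, gb)[0, 1])


def rank_models(
    candidates: Mapping[str, Spectrum2D],
    reference: Spectrum2D,
    window=None,
) -> list[tuple[str, float]]:
    """Rank candidate spectra by similarity to a reference spectrum.

    Returns (label, score) sorted by descending Pearson correlation; ties
    break lexicographically on label.
    """
    if not candidates:
        raise ValueError("no candidates")
    scored = [
        (label, compare_spectra(s, reference, window)) for label, s in candidates.items()
    ]
    return sorted(scored, key=lambda t: (-t[1], t[0]))
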