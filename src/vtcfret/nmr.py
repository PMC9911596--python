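"""In-cell ³¹P-NMR polyphosphate quantification.

Vacuolar polyP gives characteristic ³¹P resonances for the terminal and
central phosphate residues of the chain; their integrals, normalized to an
external methylene diphosphonate (MDP) reference capillary of known
concentration (3.3 mM, δ = 20.58 ppm, two equivalent ³¹P nuclei per
molecule), yield phosphate-unit concentrations::

    c_window = (I_window / I_ref) * c_ref * nuclei_ref

Spectra are (ppm, intensity) tables with a descending ppm axis (NMR
convention).  Quantification is ratio-based, hence invariant to global
intensity scaling, and windows whose integral stays below three times the
baseline noise are reported as non-detected (the readout that distinguishes
polyP-producing strains from vtc deletion strains).  A Lorentzian
synthetic-spectrum generator stands in for the in-cell acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum31P",
    "NmrRefConfig",
    "WindowResult",
    "synth_spectrum",
    "calibrate_shift",
    "integrate_window",
    "quantify_polyp",
    "write_spectrum",
    "read_spectrum",
]

#: Default polyP integration windows (ppm); placeholder assignments for the
#: terminal and central phosphate residues of the chain, configurable because
#: exact shifts vary with counter-ion and pH.
DEFAULT_WINDOWS = (
    ("polyP_terminal", -8.0, -6.0),
    ("polyP_central", -23.0, -21.0),
)


@dataclass
class Spectrum31P:
    """A 1-D ³¹P spectrum: descending ppm axis with matched intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    metadata: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.ppm) != len(self.intensity):
            raise ValueError("ppm and intensity lengths differ")
        d = np.diff(self.ppm)
        if len(d) and not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if len(d) and d[0] > 0:                 # store descending
            self.ppm = self.ppm[::-1]
            self.intensity = self.intensity[::-1]


@dataclass(frozen=True)
class NmrRefConfig:
    """External-reference calibration settings.

    Defaults describe the MDP capillary: δ = 20.58 ppm, 3.3 mM, two ³¹P
    nuclei per molecule.  ``windows`` are (label, ppm_lo, ppm_hi) integration
    intervals for the analyte; they must not overlap.
    """

    reference_ppm: float = 20.58
    reference_mm: float = 3.3
    reference_nuclei: int = 2
    reference_halfwidth: float = 1.0
    windows: tuple[tuple[str, float, float], ...] = DEFAULT_WINDOWS
    noise_factor: float = 3.0

    def __post_init__(self) -> None:
        ivs = sorted((lo, hi) for _, lo, hi in self.windows)
        for (lo, hi) in ivs:
            if not lo < hi:
                raise ValueError(f"window bounds must satisfy lo < hi, got ({lo}, {hi})")
        for (_, h1), (l2, _) in zip(ivs, ivs[1:]):
            if l2 < h1:
                raise ValueError("windows must not overlap")


@dataclass
class WindowResult:
    label: str
    integral: float
    concentration_mm: float
    detected: bool
    noise_limit: float


def synth_spectrum(
    peaks: list[tuple[float, float, float]],
    noise_sd: float = 0.0,
    ppm_range: tuple[float, float] = (25.0, -30.0),
    ppm_step: float = 0.01,
    seed: int = 0,
) -> Spectrum31P:
    """Synthesize a spectrum of Lorentzian peaks plus Gaussian noise.

    Each peak is (center ppm, integrated area, full width at half maximum);
    the Lorentzian is normalized so its full-axis integral equals the given
    area.  Deterministic for a given seed.
    """
    hi, lo = max(ppm_range), min(ppm_range)
    ppm = np.arange(hi, lo - 0.5 * ppm_step, -ppm_step)
    y = np.zeros_like(ppm)
    for center, area, fwhm in peaks:
        if fwhm <= 0:
            raise ValueError("peak width must be positive")
        gam = fwhm / 2.0
        y += area * gam / np.pi / ((ppm - center) ** 2 + gam**2)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(ppm))
    return Spectrum31P(ppm, y, metadata="synthetic")


def calibrate_shift(
    spec: Spectrum31P,
    observed_reference_ppm: float,
    config: NmrRefConfig = NmrRefConfig(),
) -> Spectrum31P:
    """Shift the ppm axis so the reference peak sits at its nominal shift."""
    delta = config.reference_ppm - observed_reference_ppm
    return Spectrum31P(spec.ppm + delta, spec.intensity.copy(), spec.metadata)


def _window_slice(spec: Spectrum31P, lo: float, hi: float) -> np.ndarray:
    return (spec.ppm >= lo) & (spec.ppm <= hi)


def integrate_window(
    spec: Spectrum31P,
    lo: float,
    hi: float,
    baseline_margin: float = 0.5,
) -> tuple[float, float]:
    """Trapezoidal integral over [lo, hi] after linear baseline subtraction.

    The baseline is the line through the median intensities of flanking
    margins of width ``baseline_margin`` ppm.  Returns (integral, estimated
    sd of the integral from the flank noise) — the sd feeds the detection
    limit.
    """
    m = _window_slice(spec, lo, hi)
    if not m.any():
        raise ValueError(f"window ({lo}, {hi}) outside the spectrum axis")
    left = _window_slice(spec, hi, hi + baseline_margin)
    right = _window_slice(spec, lo - baseline_margin, lo)
    x = spec.ppm[m]
    y = spec.intensity[m]
    anchors_x, anchors_y, resid = [], [], []
    for flank in (left, right):
        if flank.any():
            anchors_x.append(float(np.median(spec.ppm[flank])))
            anchors_y.append(float(np.median(spec.intensity[flank])))
            resid.append(spec.intensity[flank] - np.median(spec.intensity[flank]))
    if len(anchors_x) == 2 and anchors_x[0] != anchors_x[1]:
        slope = (anchors_y[1] - anchors_y[0]) / (anchors_x[1] - anchors_x[0])
        baseline = anchors_y[0] + slope * (x - anchors_x[0])
    elif anchors_y:
        baseline = np.full_like(y, np.mean(anchors_y))
    else:
        baseline = np.zeros_like(y)
    noise = float(np.std(np.concatenate(resid))) if resid else 0.0
    n_flank = sum(len(r) for r in resid)
    # ppm axis is descending; integrate on the increasing axis
    integral = float(np.trapezoid((y - baseline)[::-1], x[::-1]))
    # integral uncertainty: point noise accumulated over the window plus the
    # coherent error of the median-based baseline anchors
    step = float(np.median(np.abs(np.diff(x)))) if len(x) > 1 else 0.0
    width = hi - lo
    var = noise**2 * (step**2 * len(x) + width**2 * (np.pi / 2) / max(n_flank, 1))
    return integral, float(np.sqrt(var))


def quantify_polyp(
    spec: Spectrum31P,
    config: NmrRefConfig = NmrRefConfig(),
) -> list[WindowResult]:
    """Per-window polyP concentration in mM phosphate units.

    The spectrum must already be shift-calibrated.  The reference integral
    is taken over ``reference_ppm ± reference_halfwidth`` and must be
    positive; each analyte window below ``noise_factor`` times its baseline
    noise (scaled to the window width) is flagged non-detected and reported
    at its measured value.
    """
    ref_lo = config.reference_ppm - config.reference_halfwidth
    ref_hi = config.reference_ppm + config.reference_halfwidth
    ref_integral, _ = integrate_window(spec, ref_lo, ref_hi)
    if ref_integral <= 0:
        raise ValueError("reference peak absent or non-positive integral")
    scale = config.reference_mm * config.reference_nuclei / ref_integral
    results = []
    for label, lo, hi in config.windows:
        integral, sigma = integrate_window(spec, lo, hi)
        limit = config.noise_factor * sigma
        results.append(
            WindowResult(
                label=label,
                integral=integral,
                concentration_mm=integral * scale,
                detected=bool(integral > limit),
                noise_limit=limit * scale,
            )
        )
    return results


def write_spectrum(spec: Spectrum31P, path) -> None:
    pd.DataFrame({"ppm": spec.ppm, "intensity": spec.intensity}).to_csv(
        path, sep="\t", index=False
    )


def read_spectrum(path) -> Spectrum31P:
    df = pd.read_csv(path, sep="\t")
    if not {"ppm", "intensity"} <= set(df.columns):
        raise ValueError("spectrum table must have columns ppm, intensity")
    return Spectrum31P(df["ppm"].to_numpy(), df["intensity"].to_numpy(),
                       metadata=str(path))
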