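"""Synthetic edible-oil 1H-NMR signal generator.

Emulates the 300 MHz proton spectrum of a triacylglycerol (TG) mixture in
CDCl3 with internal TMS: ten assigned oil signal groups A-J, the TMS
reference at 0 ppm, residual water with a temperature-dependent chemical
shift, the residual CHCl3 line, and 13C satellites at natural abundance.
Lineshapes are Lorentzian (exponentially decaying complex time-domain
components); additive complex Gaussian noise is seeded and reproducible.

The acyl-chain composition is parameterised by the molar fractions of
saturated (modelled as stearic, 18:0), oleic (18:1 n-9), linoleic
(18:2 n-6) and linolenic (18:3 n-3) chains.  Signal areas follow exact
per-mole-of-TG proton bookkeeping:

===========  =================================  =======================
signal       assignment                         protons per mole TG
===========  =================================  =======================
A  0.88 ppm  terminal CH3 (all but 18:3)        9 (1 - w)
B  0.97 ppm  terminal CH3 of linolenic (n-3)    9 w
C  1.29 ppm  bulk chain (CH2)n                  84x + 60y + 42z + 24w
D  1.61 ppm  CH2 beta to the carbonyl           6
E  2.02 ppm  allylic CH2                        12 (y + z + w)
F  2.30 ppm  CH2 alpha to the carbonyl          6
G  2.77 ppm  bis-allylic CH2                    6z + 12w
H  4.2  ppm  glycerol sn-1,3 CH2 (2 lines)      4
I  5.26 ppm  glycerol sn-2 CH                   1
J  5.35 ppm  olefinic CH                        6y + 12z + 18w
===========  =================================  =======================

with (x, y, z, w) the saturated/oleic/linoleic/linolenic fractions.  The
totals reproduce the exact molecular proton counts (tristearin C57H110O6:
110 H; triolein C57H104O6: 104 H; trilinolenin C57H92O6: 92 H).

A non-zero ``free_fatty_acid_fraction`` q removes the corresponding share
of glycerol protons (signals H and I scale by 1 - q) while the chain
signals persist, emulating the F/H ratio rising above 1.50 in samples with
free acids or partial glycerides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .bruker import AcquisitionParameters, RawFID

__all__ = [
    "OilSpec",
    "Line",
    "OIL_PRESETS",
    "LINE_CENTERS",
    "SIGNAL_NAMES",
    "proton_counts",
    "water_shift",
    "build_line_catalog",
    "synthesize_fid",
    "synthesize_spectrum",
    "noise_sigma_for_snr",
]

SIGNAL_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H", "I", "J")

#: Default line centers in ppm; H is split over the two sn-1,3 AB doublet arms.
LINE_CENTERS: dict[str, tuple[tuple[float, float], ...]] = {
    "A": ((0.88, 1.0),),
    "B": ((0.97, 1.0),),
    "C": ((1.29, 1.0),),
    "D": ((1.61, 1.0),),
    "E": ((2.02, 1.0),),
    "F": ((2.30, 1.0),),
    "G": ((2.77, 1.0),),
    "H": ((4.14, 0.5), (4.29, 0.5)),
    "I": ((5.26, 1.0),),
    "J": ((5.35, 1.0),),
}

#: One-bond 1H-13C coupling constants (Hz) used for satellite placement.
J_CH_DEFAULT = 125.0
J_CH_TMS = 118.0
J_CH_CHCL3 = 209.0

#: Natural 13C abundance; each satellite carries half of it.
C13_ABUNDANCE = 0.011

#: Water chemical-shift model defaults: delta(T) = delta30 + slope * (T - 30).
WATER_DELTA_30C = 1.56  # ppm
WATER_SLOPE = -0.012  # ppm per deg C

#: Representative acyl-chain compositions (saturated, oleic, linoleic, linolenic).
OIL_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "olive": (0.16, 0.73, 0.10, 0.01),
    "arbequina": (0.142, 0.776, 0.076, 0.006),
    "picual": (0.124, 0.851, 0.020, 0.005),
    "sunflower": (0.11, 0.28, 0.60, 0.01),
    "soy": (0.16, 0.23, 0.54, 0.07),
    "sesame": (0.15, 0.40, 0.44, 0.01),
    "linseed": (0.10, 0.18, 0.17, 0.55),
}


@dataclass
class OilSpec:
    """Ground-truth description of one synthetic oil sample."""

    saturated: float = 0.16
    oleic: float = 0.73
    linoleic: float = 0.10
    linolenic: float = 0.01
    free_fatty_acid_fraction: float = 0.0
    temperature: float = 30.0  # deg C
    noise_sigma: float = 0.0  # time-domain sd per real/imag component
    line_width: float = 0.68  # Hz, Lorentzian FWHM of the oil/TMS lines
    water_line_width: float = 2.0  # Hz
    water_amplitude: float = 0.5  # proton-equivalents per mole TG
    tms_amplitude: float = 2.0
    chloroform_amplitude: float = 0.2
    include_satellites: bool = True
    include_tms: bool = True
    include_water: bool = True
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        fractions = (self.saturated, self.oleic, self.linoleic, self.linolenic)
        for f in fractions:
            if not -1e-12 <= f <= 1.0 + 1e-12:
                raise ValueError(f"chain fraction {f} outside [0, 1]")
        total = sum(fractions)
        # all-zero fractions describe an oil-free blank (TMS/water only)
        if abs(total - 1.0) > 1e-9 and abs(total) > 1e-9:
            raise ValueError(
                f"chain fractions must sum to 1 (got {total!r})"
            )
        if not 0.0 <= self.free_fatty_acid_fraction < 1.0:
            raise ValueError("free_fatty_acid_fraction must be in [0, 1)")
        if self.line_width <= 0:
            raise ValueError("line_width must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @classmethod
    def preset(cls, name: str, **kwargs) -> "OilSpec":
        x, y, z, w = OIL_PRESETS[name]
        kwargs.setdefault("label", name)
        return cls(saturated=x, oleic=y, linoleic=z, linolenic=w, **kwargs)

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (self.saturated, self.oleic, self.linoleic, self.linolenic)


def proton_counts(spec: OilSpec) -> dict[str, float]:
    """Protons per mole of TG contributing to each signal A-J.

    Derived from the chain structures: per chain the methyl contributes 3 H
    (signal A, or B for n-3 chains), the alpha- and beta-CH2 2 H each
    (F, D), each allylic CH2 2 H (E), each bis-allylic CH2 2 H (G), each
    olefinic CH 1 H (J), the remaining chain CH2 fall in C; the glycerol
    backbone adds 4 H (H) and 1 H (I).
    """
    x, y, z, w = spec.fractions
    if abs(x + y + z + w) < 1e-9:  # oil-free blank
        return {name: 0.0 for name in SIGNAL_NAMES}
    return {
        "A": 9.0 * (1.0 - w),
        "B": 9.0 * w,
        "C": 84.0 * x + 60.0 * y + 42.0 * z + 24.0 * w,
        "D": 6.0,
        "E": 12.0 * (y + z + w),
        "F": 6.0,
        "G": 6.0 * z + 12.0 * w,
        "H": 4.0,
        "I": 1.0,
        "J": 6.0 * y + 12.0 * z + 18.0 * w,
    }


def water_shift(
    temperature: float,
    delta_30c: float = WATER_DELTA_30C,
    slope: float = WATER_SLOPE,
) -> float:
    """Chemical shift (ppm) of residual water at *temperature* (deg C).

    Linear model delta(T) = delta30 + slope * (T - 30); the residual water
    line in CDCl3 moves upfield as the sample warms.
    """
    if not 0.0 <= temperature <= 80.0:
        raise ValueError(f"temperature {temperature} degC outside 0-80 degC")
    return delta_30c + slope * (temperature - 30.0)


@dataclass(frozen=True)
class Line:
    """One Lorentzian component of the synthetic spectrum."""

    name: str
    center_ppm: float
    area: float
    width_hz: float
    j_ch: float | None = None  # None: no 13C satellites (e.g. water OH)


def build_line_catalog(spec: OilSpec) -> list[Line]:
    """All spectral lines implied by *spec* (before satellite expansion)."""
    counts = proton_counts(spec)
    q = spec.free_fatty_acid_fraction
    lines: list[Line] = []
    for name in SIGNAL_NAMES:
        area = counts[name]
        if name in ("H", "I"):
            area *= 1.0 - q
        if area <= 0:
            continue
        for center, weight in LINE_CENTERS[name]:
            lines.append(Line(name, center, area * weight, spec.line_width, J_CH_DEFAULT))
    if spec.include_tms and spec.tms_amplitude > 0:
        lines.append(Line("TMS", 0.0, spec.tms_amplitude, spec.line_width, J_CH_TMS))
    if spec.include_water and spec.water_amplitude > 0:
        lines.append(
            Line("water", water_shift(spec.temperature), spec.water_amplitude,
                 spec.water_line_width, None)
        )
    if spec.chloroform_amplitude > 0:
        lines.append(
            Line("CHCl3", 7.26, spec.chloroform_amplitude, spec.line_width, J_CH_CHCL3)
        )
    return lines


def _expand_satellites(lines: list[Line], spec: OilSpec,
                       params: AcquisitionParameters) -> list[Line]:
    """Split off the 13C satellites of every carbon-bound-proton line.

    Each satellite sits at +-J(CH)/2 from the parent and carries half the
    natural 13C abundance of the parent area; the parent keeps the rest.
    """
    if not spec.include_satellites:
        return lines
    out: list[Line] = []
    sep_factor = 0.5 / params.spectrometer_frequency  # Hz -> ppm, halved
    for ln in lines:
        if ln.j_ch is None:
            out.append(ln)
            continue
        offset = ln.j_ch * sep_factor
        out.append(replace(ln, area=ln.area * (1.0 - C13_ABUNDANCE)))
        half = ln.area * C13_ABUNDANCE / 2.0
        out.append(Line(ln.name + "_sat", ln.center_ppm - offset, half, ln.width_hz, None))
        out.append(Line(ln.name + "_sat", ln.center_ppm + offset, half, ln.width_hz, None))
    return out


def synthesize_fid(
    spec: OilSpec,
    params: AcquisitionParameters | None = None,
    noiseless: bool = False,
) -> RawFID:
    """Simulate the complex FID for *spec* under acquisition *params*.

    Each line contributes ``area * exp(2i*pi*f*t - pi*width*t)`` with
    ``f`` its offset from the transmitter in Hz, i.e. the Fourier transform
    is a Lorentzian of FWHM ``width`` whose integral is proportional to the
    line area.  Gaussian noise of sd ``spec.noise_sigma`` per real and
    imaginary point is added (seeded; identical seeds give identical FIDs)
    unless *noiseless* overrides it.
    """
    params = params or AcquisitionParameters(temperature=spec.temperature)
    n = params.n_complex_points
    t = np.arange(n) / params.spectral_width_hz
    fid = np.zeros(n, dtype=np.complex128)
    lo = params.transmitter_offset - params.spectral_width / 2.0
    hi = params.transmitter_offset + params.spectral_width / 2.0
    for ln in _expand_satellites(build_line_catalog(spec), spec, params):
        if not lo <= ln.center_ppm <= hi:
            warnings.warn(
                f"line {ln.name} at {ln.center_ppm:.3f} ppm falls outside the "
                f"spectral window [{lo:.2f}, {hi:.2f}] ppm and is truncated",
                stacklevel=2,
            )
            continue
        f_hz = (ln.center_ppm - params.transmitter_offset) * params.spectrometer_frequency
        fid += ln.area * np.exp((2j * np.pi * f_hz - np.pi * ln.width_hz) * t)
    if spec.noise_sigma > 0 and not noiseless:
        rng = np.random.default_rng(spec.seed)
        fid += spec.noise_sigma * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    return RawFID(data=fid, params=params, source_path="<synthetic>",
                  sample_label=spec.label)


def synthesize_spectrum(
    spec: OilSpec,
    params: AcquisitionParameters | None = None,
    noiseless: bool = True,
    zero_fill_to: int | None = None,
):
    """Frequency-domain spectrum for *spec*: the transform of its FID.

    Building the spectrum through the same Fourier route the pipeline uses
    guarantees the two representations agree to numerical precision.
    Noiseless by default so the result is the sum of absorption-mode
    Lorentzians with areas proportional to the proton counts.
    """
    from .processing import transform

    params = params or AcquisitionParameters(temperature=spec.temperature)
    fid = synthesize_fid(spec, params, noiseless=noiseless)
    return transform(fid, zero_fill_to=zero_fill_to or 2 * params.n_complex_points)


def noise_sigma_for_snr(
    spec: OilSpec,
    params: AcquisitionParameters | None = None,
    snr: float = 250.0,
    signal: str = "B",
) -> float:
    """Time-domain noise sd that yields a target spectral S/N on one signal.

    Uses the construction S/N = peak / (2 * sd_spectrum) with
    ``sd_spectrum = sigma_t * sqrt(N)`` for an N-point transform, where the
    peak height is read off a noiseless synthesis of the same spec.
    """
    params = params or AcquisitionParameters(temperature=spec.temperature)
    spectrum = synthesize_spectrum(spec, params, noiseless=True)
    centers = LINE_CENTERS[signal]
    center = centers[0][0]
    mask = np.abs(spectrum.ppm - center) <= 0.05
    peak = float(np.max(spectrum.intensity[mask]))
    if peak <= 0:
        raise ValueError(f"signal {signal} absent from the noiseless spectrum")
    sd_spectrum = peak / (2.0 * snr)
    return sd_spectrum / np.sqrt(params.n_complex_points)
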