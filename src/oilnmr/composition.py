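"""Fatty acid composition, iodine value and F/H validation ratio.

From the integrals A-J the screening method reports, per sample:

* the SFA/MUFA/PUFA percentages of acyl chains,

      SFA  = (4A + 4B - 3E) / (6F)
      MUFA = (4B + 3E - 6G) / (6F)
      PUFA = (3G - 2B) / (3F)

  Each acyl chain carries exactly two alpha-carbonyl protons (signal F),
  so 6F counts three chains; the allylic (E), bis-allylic (G) and n-3
  methyl (B) integrals separate the unsaturation classes.  Against the
  exact proton-count model these three expressions return the saturated,
  monounsaturated and polyunsaturated chain fractions identically, and
  they always sum to 1.  (A published variant of the MUFA formula uses
  the glycerol signal H in place of G; it does not close the mass balance
  — triolein would report 33.3% MUFA — and is available for comparison
  via ``eq2_uses_h=True``.)

* the olefinic proton percentage %OP = 100 J / (A + ... + J) and from it
  the iodine value through the linear regression IV = 10.54 + 13.39 x %OP;

* the F/H ratio (6 vs 4 protons per intact TG, hence 1.50): deviations
  indicate free fatty acids or partial glycerides and flag the FAC values
  as untrustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .integration import IntegralTable, SignalRegionSet, integrate, normalize
from .processing import QualityMetrics, Spectrum

__all__ = [
    "FACResult",
    "FacPercentages",
    "ImplausibleIntegralsError",
    "IV_INTERCEPT",
    "IV_SLOPE",
    "compute_fac",
    "compute_op_percent",
    "compute_iv",
    "compute_fh",
    "analyze_sample",
]

IV_INTERCEPT = 10.54
IV_SLOPE = 13.39

FH_BAND = (1.45, 1.55)

#: Raw fractions this far below zero are treated as integration noise and
#: clamped; anything lower fails the sample.
NEGATIVE_CLAMP_TOLERANCE = 0.02


class ImplausibleIntegralsError(ValueError):
    """Raw chain fractions fall far outside [0, 1]: the integrals are bad."""


@dataclass
class FacPercentages:
    sfa: float
    mufa: float
    pufa: float
    qc_flags: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter((self.sfa, self.mufa, self.pufa))


@dataclass
class FACResult:
    """One row of the screening report."""

    sample_label: str
    sfa: float  # % of acyl chains
    mufa: float
    pufa: float
    op_percent: float  # olefinic protons as % of all assigned protons
    iv: float  # iodine value, g I2 / 100 g
    fh_ratio: float
    qc_flags: list[str] = field(default_factory=list)

    @property
    def qc_ok(self) -> bool:
        return not self.qc_flags


def compute_fac(table: IntegralTable, eq2_uses_h: bool = False) -> FacPercentages:
    """SFA/MUFA/PUFA percentages from an integral table.

    Raises :class:`ImplausibleIntegralsError` when any raw fraction leaves
    [-0.02, 1.02]; small negatives within the noise tolerance are clamped
    to zero and flagged ``negative_fraction_clamped``.
    """
    a, b, e, f = table["A"], table["B"], table["E"], table["F"]
    g, h = table["G"], table["H"]
    if f <= 0:
        raise ValueError("non-positive F integral: invalid spectrum")
    sfa = (4.0 * a + 4.0 * b - 3.0 * e) / (6.0 * f)
    pufa = (3.0 * g - 2.0 * b) / (3.0 * f)
    mono_counter = h if eq2_uses_h else g
    mufa = (4.0 * b + 3.0 * e - 6.0 * mono_counter) / (6.0 * f)

    flags: list[str] = []
    out = []
    for value in (sfa, mufa, pufa):
        if not -NEGATIVE_CLAMP_TOLERANCE <= value <= 1.0 + NEGATIVE_CLAMP_TOLERANCE:
            raise ImplausibleIntegralsError(
                f"implausible integrals: raw fraction {value:.4f} outside "
                f"[-{NEGATIVE_CLAMP_TOLERANCE}, {1 + NEGATIVE_CLAMP_TOLERANCE}]"
            )
        if value < 0.0:
            value = 0.0
            if "negative_fraction_clamped" not in flags:
                flags.append("negative_fraction_clamped")
        out.append(100.0 * min(value, 1.0))
    return FacPercentages(sfa=out[0], mufa=out[1], pufa=out[2], qc_flags=flags)


def compute_op_percent(table: IntegralTable) -> float:
    """Olefinic protons as a percentage of all assigned signal areas A-J."""
    total = table.total
    if total <= 0:
        raise ValueError("non-positive total area")
    return 100.0 * max(table["J"], 0.0) / total


def compute_iv(op_percent: float) -> float:
    """Iodine value from the olefinic-proton percentage: 10.54 + 13.39 x %OP."""
    if op_percent < 0:
        raise ValueError("op_percent must be non-negative")
    return IV_INTERCEPT + IV_SLOPE * op_percent


def compute_fh(table: IntegralTable) -> float:
    """F/H area ratio; 1.50 for intact triglycerides."""
    h = table["H"]
    if h <= 0:
        raise ValueError("non-positive H integral")
    return table["F"] / h


def analyze_sample(
    spec: Spectrum,
    regions: SignalRegionSet,
    quality: QualityMetrics,
    tail_correction: bool = True,
    eq2_uses_h: bool = False,
    j_includes_sn2: bool = False,
    fh_band: tuple[float, float] = FH_BAND,
    sample_label: str | None = None,
) -> FACResult:
    """Integrate a processed spectrum and assemble the full report row.

    QC flags merge the spectrum-level conditions (``tms_missing``,
    ``phase_fallback``), the S/N acceptance floor (``snr_fail``), an F/H
    ratio outside *fh_band* (``FH_out_of_range``) and clamped negative
    fractions.
    """
    table = integrate(
        spec,
        regions,
        tail_correction=tail_correction,
        line_width_hz=quality.linewidth_tms_hz,
        j_includes_sn2=j_includes_sn2,
    )
    table = normalize(table, "f6")
    fac = compute_fac(table, eq2_uses_h=eq2_uses_h)
    op = compute_op_percent(table)
    iv = compute_iv(op)
    fh = compute_fh(table)

    flags = list(fac.qc_flags)
    if not quality.snr_ok:
        flags.append("snr_fail")
    for flag in spec.flags:
        if flag not in flags:
            flags.append(flag)
    if not fh_band[0] <= fh <= fh_band[1]:
        flags.append("FH_out_of_range")
    return FACResult(
        sample_label=sample_label if sample_label is not None else table.sample_label,
        sfa=fac.sfa,
        mufa=fac.mufa,
        pufa=fac.pufa,
        op_percent=op,
        iv=iv,
        fh_ratio=fh,
        qc_flags=flags,
    )
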