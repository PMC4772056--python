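# Methods

## Scope and model

`oilnmr` treats an edible oil as a mixture of C18 acyl chains —
saturated (stearic-like), oleic (18:1 n−9), linoleic (18:2 n−6) and
linolenic (18:3 n−3) — esterified on glycerol.  With molar chain fractions
(x, y, z, w), exact per-mole-of-triacylglycerol proton counts follow from
the chain structures:

| signal | δ (ppm) | assignment | protons per TG |
|---|---|---|---|
| A | 0.88 | terminal CH₃ (all but n−3) | 9(1−w) |
| B | 0.97 | terminal CH₃, n−3 chains | 9w |
| C | 1.29 | bulk (CH₂)ₙ | 84x + 60y + 42z + 24w |
| D | 1.61 | CH₂ β to carbonyl | 6 |
| E | 2.02 | allylic CH₂ | 12(y+z+w) |
| F | 2.30 | CH₂ α to carbonyl | 6 |
| G | 2.77 | bis-allylic CH₂ | 6z + 12w |
| H | 4.14/4.29 | glycerol sn-1,3 CH₂ | 4 |
| I | 5.26 | glycerol sn-2 CH | 1 |
| J | 5.35 | olefinic CH | 6y + 12z + 18w |

These totals reproduce the molecular formulas (tristearin 110 H, triolein
104 H, trilinolenin 92 H) and are property-tested against an independent
atom-by-atom classifier.

The composition equations invert this bookkeeping:
SFA = (4A+4B−3E)/6F, MUFA = (4B+3E−6G)/6F, PUFA = (3G−2B)/3F.
Against the proton-count model they return (x, y, z+w) exactly and sum to
1 identically.  A published variant of the MUFA expression uses the
glycerol integral H in place of the bis-allylic G; it does not close the
mass balance (triolein would report 33⅓ % MUFA) and is therefore treated
as a transcription slip.  It remains available as `eq2_uses_h=True` for
comparison.  The iodine value is the linear regression
IV = 10.54 + 13.39 × %OP on the olefinic proton percentage
%OP = 100·J/Σ(A…J); the denominator is the sum of all ten assigned
signals (TMS, water and satellite-only areas excluded).

## Synthetic data generator

`simulate.OilSpec` describes one sample; `synthesize_fid` renders it as a
sum of decaying complex exponentials so the spectrum is a sum of
Lorentzians whose areas are proportional to the proton counts.  Defaults
reproduce the screening protocol's acquisition: 300.13 MHz, 12 ppm
spectral width centred at 5 ppm, 16384 complex points (AQ ≈ 4.56 s), 8
scans + 2 dummy scans, 4 s recycle delay, 30 °C — hence the 86 s
experiment duration and 0.11 Hz digital resolution the quality module
reports.  Other defaults, chosen once as realistic study conditions:

- **line width** 0.68 Hz FWHM, the reported TMS line width at half height
  under this protocol; all oil signals share it (multiplets are collapsed
  to single Lorentzians — areas, not shapes, carry the information);
- **¹³C satellites** on every carbon-bound proton signal: ±J(CH)/2 with
  J = 125 Hz (118 Hz for TMS, 209 Hz for CHCl₃), each carrying 0.55 % of
  the parent area (1.1 % natural abundance);
- **residual water** at δ(T) = 1.56 − 0.012·(T − 30 °C) ppm, 2 Hz wide,
  0.5 proton-equivalents; the linear temperature model is
  literature-informed and only qualitatively calibrated — its constants
  are configuration values, not measured claims;
- **TMS** (2 proton-equivalents) at 0 ppm and **residual CHCl₃** (0.2) at
  7.26 ppm;
- **noise**: seeded complex Gaussian noise per time-domain point;
  `noise_sigma_for_snr` converts a target spectral S/N on a chosen signal
  (convention peak/(2·sd), B by default) into the time-domain σ via
  sd_spectrum = σ·√N;
- **free fatty acids**: a fraction q of unesterified chains scales the
  glycerol signals H and I by (1−q) while chain signals persist, so
  F/H = 1.5/(1−q) > 1.50 — the signature the F/H quality flag detects.
  The acid COOH proton (~11 ppm, exchangeable) is not rendered.

What the generator does **not** emulate: J-coupling multiplet structure,
shim-dependent lineshape distortions, radiation damping, receiver filter
roll-off, temperature gradients, and minor components (diglycerides,
sterols, aldehydes) beyond the F/H signature.  Passing round-trip tests
therefore demonstrate the correctness of the analysis chain under ideal
Lorentzian conditions, not instrument-grade robustness.

## Processing chain

1. **Transform** — zero fill to 32768 points (0.11 Hz/pt), FFT, no window
   function; the first time-domain point is halved to suppress the DC
   offset of the half-sided transform.
2. **Automatic phasing** — two stages.  A peak-based estimator finds the
   strongest magnitude peaks (magnitude being phase-invariant), reads the
   local phase error from the complex value at each apex — where the
   sharp local height (∝ area/line width) dominates the slowly decaying
   dispersive tails of even much larger neighbours — and fits
   φ0 + φ1·x through the samples after unwrapping.  A Nelder–Mead polish
   then minimises the squared intensity below −2·(noise sd): for an
   all-positive absorption spectrum this objective has its unique minimum
   at the true phase, and the noise-floor threshold prevents small
   misphases from being rewarded for covering negative noise dips with
   positive dispersive wings.  A derivative-entropy term can be blended
   in but is off by default — at the tiny negativity scale of near-correct
   phases even a weak entropy weight drags the optimum a few degrees along
   the φ0/φ1 trade-off trough.  Recovery of known dephasings is ≲0.1° on
   noiseless synthetic oils, ~0.1–0.5° at S/N 250.  If the result still
   leaves >25 % negative area (e.g. pure noise) the magnitude spectrum is
   used and `phase_fallback` flagged.
3. **Baseline** — Whittaker-smoothed asymmetric least squares
   (λ = 10⁷, second-difference penalty) fitted on signal-free points
   only: the known signal zones (methyl–bis-allylic 0.60–3.05 ppm,
   glycerol 3.90–4.60 ppm, olefinic 5.00–5.70 ppm, TMS, CHCl₃) are
   excluded as anchors with weight 0, and outside them points rising more
   than 4 noise-sd above the current fit are iteratively reclassified.
   Constant offsets and linear ramps carry no roughness penalty and are
   removed essentially exactly; peak tails are preserved.  Plain
   sign-based AsLS weights are deliberately not used: at 0.11 Hz/point
   the smoother would track the Lorentzian tails of the crowded 0.8–3 ppm
   region and bias the integrals by about one FAC point.
4. **TMS referencing** — tallest point within ±0.3 ppm of 0, refined by
   parabolic interpolation, shifted to exactly 0 ppm; absent TMS (below
   max(5·noise sd, 0.1 % of the global maximum)) flags `tms_missing` and
   leaves the axis unchanged.
5. **Quality** — S/N of signal B against the 250:1 floor (noise window
   9.5–10.5 ppm, convention peak/(2·sd); sd below 10⁻⁷ of the maximum is
   numerical residue and reports the infinite-S/N sentinel); TMS FWHM in
   Hz; digital resolution, which must not exceed half the line width.

## Integration

The ten windows (table above, defaults A 0.82–0.93 … J 5.28–5.50 ppm) are
configurable; the water exclusion is centred on the water model's δ(T)
with ±0.04 ppm half-width — narrow enough that signal D (1.61 ppm) keeps
its core outside it at 30 °C.  The base measurement is the trapezoid over
each window minus exclusion sub-windows, with segment bounds snapped to
the ppm grid.

By default a **lineshape-aware correction** is applied: with ~30–120 Hz
windows and 0.68 Hz Lorentzians, 1–2 % of every line's area falls outside
its window and, worse, the methyl signal A leaks a few tenths of a percent
of its large area into the adjacent narrow B window — enough to bias the
PUFA of low-linolenic oils by ~0.7 points.  The correction builds the
analytic coverage matrix of all ten signals plus the water line (Lorentzian
CDF over each measured interval, including the ¹³C satellite displacement)
at the line width measured on TMS, and solves the small least-squares
system for the underlying areas.  It assumes the nominal line positions of
the region table; `tail_correction=False` restores plain trapezoids (in
which case the optional `j_includes_sn2` mode integrates 5.10–5.50 ppm
jointly and subtracts one proton-equivalent H/4 for the sn-2 CH).
Solutions more negative than 0.5 % of the total are kept (they fail QC
downstream); smaller negatives are numerical and clamped to zero.

Separating D from water when the two overlap strongly (the water line
crosses 1.61 ppm near 26 °C) is ill-conditioned from integrals alone; D is
then recovered from its tails with a few-percent error.  D enters only the
%OP denominator, so the effect on IV stays below ~1 %.

## Composition and QC

Raw class fractions outside [−0.02, 1.02] abort the sample as
"implausible integrals"; negatives within the −2 % noise tolerance are
clamped to zero and flagged.  The F/H band defaults to 1.45–1.55.
Per-sample flags (`snr_fail`, `tms_missing`, `phase_fallback`,
`FH_out_of_range`, `negative_fraction_clamped`) accompany, never
suppress, the reported numbers; batch runs record failures per sample and
continue (exit codes: 0 all analysed, 2 partial, 3 none).

## Verification strategy and problem sizes

All tests run on synthetic data at the protocol's native size (16384
complex points, 32768 spectral points).  Oracles are independent of the
code paths they check: proton counts against an atom-by-atom chain
classifier; the composition equations against the forward model on a
0.05-step simplex grid (machine precision); phase recovery against the
known applied misphase; baseline behaviour against water-free or
ramp-free syntheses.  Noise robustness uses 50 seeded replicates of an
olive-like oil at the S/N 250 acceptance floor (ground truth recovered
within 1.5 percentage points; observed spread is ~0.5).  Noiseless
round-trips recover SFA/MUFA/PUFA within 0.5 points across olive-,
sunflower-, linseed- and arbequina-like compositions.

## Known limitations

- Single-Lorentzian signals: real multiplets spread across the windows;
  the coverage correction assumes the nominal centers, so strongly
  miscalibrated spectra should use `tail_correction=False` with widened
  windows instead.
- The water-shift constants are qualitative; at temperatures where water
  crosses signal D the D/water separation degrades (above).
- Only Bruker 1D directory layout is read; processed vendor data (`1r`),
  2D data and other formats are out of scope.
- The FAC partition covers the four modelled chain classes; individual
  fatty-acid speciation, sterols and oxidation markers are not analysed.
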