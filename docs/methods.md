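# Methods

## The screen being modelled

The pipeline reproduces, at desk scale, the computational side of a
function-based metagenomic screen for enzymes acting on GlcNAc-6-sulfate.
Clones of a fosmid library are lysed in 384-well plates with the fluorogenic
substrate 4MU-GlcNAc-6-SO4 plus an exogenous hexosaminidase that cannot act
while the sulfate is in place. A clone sulfatase therefore gates fluorophore
release (a coupled two-enzyme cascade), while a sulfate-tolerant clone
hexosaminidase releases 4MU from the sulfated substrate directly. Plates are
read ~six times over 48 h (defaults 1, 3, 6, 24, 30, 48 h) and hits are
called against empty-vector control lysates. Confirmed hits are profiled on
a small substrate panel, and purified candidate enzymes are characterized on
APTS-labelled N-glycans by capillary gel electrophoresis with laser-induced
fluorescence (xCGE-LIF).

## Assay kinetics

The cascade is modelled as irreversible first-order steps,

    S --k_sulf--> I --k_hex_exo--> P,     S --k_hex_direct--> P,

a pseudo-first-order approximation valid when substrate is well below Km.
Michaelis–Menten saturation is deliberately out of scope: the model only has
to generate realistic screen data, and the linear system has an exact
closed form, which keeps the generator fast and testable. With
a = k_sulf + k_hex_direct and b = k_hex_exo:

    S(t) = s0 e^{-a t}
    I(t) = s0 k_sulf (e^{-a t} - e^{-b t}) / (b - a)
    P(t) = s0 - S - I

The removable singularity at a = b is handled by the analytic limit
I = s0 k_sulf t e^{-a t}, switched when |a - b| < 1e-9 · max(a, b); at
k_sulf = k_hex_exo = k and k_hex_direct = 0 this gives the familiar
P = s0 (1 - e^{-kt}(1 + kt)). An independent LSODA integration
(rtol 1e-10, atol 1e-12) of the same system serves as the numerical oracle
in tests; the two agree to better than 1e-6 relative over a 500-point sweep
of rates in [0, 10]/h and times in [0, 48] h, including the degenerate case.

Observed fluorescence is RFU(t) = baseline + autofluor_rate·t +
f_yield·P(t) + noise. Autofluorescent false positives (riboflavin-pathway
clones accumulate fluorescent metabolites) are modelled as a linear RFU
drift with no substrate turnover — sufficient to make them trigger the hit
rules and light up the no-substrate control, which is all the downstream
logic needs.

## Synthetic screen generator

No raw plate data are deposited, so the generator is first-class, tested
code and defines the study conditions. Defaults: 384-well plates with 16
empty-vector control wells each (the control count per plate is not
published; 16 gives a stable per-plate SD), six timepoints as above,
additive Gaussian read noise with SD 5 RFU on a 100 RFU baseline (5% of
baseline; raw RFU magnitudes are not published), and planted first-order
rates drawn lognormally around 0.2/h so planted activity is unambiguous
within the 48 h window. The default class mix plants ~0.7% non-empty wells,
dominated by sulfatase+hexosaminidase combinations, mirroring the screen's
funnel (81 primary candidates, 24 confirmed, 0.2% confirmed rate from
11,520 lysates); a `full_scale_config()` preset reproduces the full
11,520-clone geometry (32 plates × 360 clone wells). Tests run a miniature
5-plate default to stay fast. The generator emulates background, kinetics,
noise and autofluorescence, but not plate spatial effects (edge rows,
gradients), pipetting covariance between timepoints, or lysate-to-lysate
expression variability — so passing tests show the statistical rules behave
as specified under their own assumptions, not that the screen's wet-lab
error structure is captured.

What each simulated well is, and the rates it carries, are recorded in a
truth table; the class label and the nonzero-rate pattern are locked to each
other by a fixed consistency map validated exhaustively.

## Hit calling

Control statistics are the sample mean and SD (n−1) of control-well RFU per
timepoint, per plate by default (plate effects dominate in practice) or
pooled batch-wide. The primary rule calls a well at RFU ≥ mean + 3·SD at
≥ 1 timepoint (inclusive, reading "3 standard deviations over ... in at
least one time point" liberally, as the screen intended); the secondary rule
requires RFU strictly over mean + 6·SD at ≥ 2 timepoints. Timepoints with
SD = 0 (degenerate identical controls) are excluded with a warning rather
than yielding infinite z-scores. Every call stores its per-timepoint
z-scores so the verdict is recomputable for audit.

The analytic companion `fpr_analytic(k, n, m)` is the binomial tail
P(X ≥ m), X ~ Binomial(n, Φ̄(k)), assuming independent timepoints — exact
for pure read noise, an approximation for autocorrelated kinetic curves,
which is why the calibration is done by Monte Carlo on simulated wells. For
(3, 6, 1) this gives ≈ 0.00807; for (6, 6, 2) ≈ 1.5e-17, so no secondary
false positive is expected in any feasible simulation. The null calibration
in the acceptance run thresholds at the *known* background mean/SD: the
analytic value assumes known thresholds, and a single estimated threshold
shared by 10^5 wells adds correlated error that a binomial standard error
does not describe. The estimated-statistics path is covered by its own
tests. At per-plate scope with 16 controls the empirical tail is inflated
structurally (the relevant statistic is Student-t with 15 df:
P(t15 > 2.91) ≈ 0.0054 per timepoint versus the Gaussian 0.00135); this is
a property of small-sample thresholding worth knowing when interpreting
primary hit counts, and one reason the screen's primary stage is treated as
deliberately liberal.

## Panel classification

Five endpoint conditions are thresholded at control mean + 3·SD (the
published panel calls are presence/absence; a σ threshold is this package's
codification): coupled assay, sulfated substrate alone, asulfated
4MU-GlcNAc, generic aryl sulfate 4MU-SO4, and no substrate. The boolean
pattern feeds a first-match rule table (precedence: no-substrate signal →
autofluorescent false positive; generic sulfate → general sulfatase;
coupled only → sulfo-specific sulfatase; direct without asulfated →
sulfate-dependent hexosaminidase; direct and asulfated → ambiguous
combination; asulfated only / residual → indeterminate; nothing →
inactive). The fired rule id is part of the output.

The (direct ∧ asulfated) pattern cannot distinguish one sulfate-tolerant
hexosaminidase from a sulfatase plus an ordinary hexosaminidase — the
underlying screen reached the same conclusion ("likely a combination") from
sequence data, which is out of scope here. The tiebreak reports the
combination label when the coupled condition is also positive and always
sets an ambiguity flag. In the generator both classes produce the identical
zero-noise pattern, so round-trip recovery is asserted for the five
non-ambiguous classes and the documented tiebreak for the other two.

Endpoint (48 h) RFU is used for panel thresholds; the screen monitored
kinetically but reported presence/absence, and the endpoint maximizes
signal for first-order kinetics.

## Electropherogram processing

Raw traces are uniform samplings of migration time vs intensity. Processing:

1. **Smoothing + detection.** The trace is convolved with a Gaussian kernel
   (default 8 grid samples, matching the default simulated peak width — a
   matched filter, optimal for locating peaks in white noise); local maxima
   above prominence and height floors (2% of trace maximum) are kept, and
   each apex is refined by a parabola through the three samples around the
   maximum. A symmetric kernel does not move a symmetric peak's apex; it
   does broaden peaks, so closely spaced structures trade apex precision
   against resolution through the kernel parameter.
2. **Normalization.** The two spiked standards are identified as the
   highest peak inside each declared raw-time search window, and the linear
   map fixing (t1 → M1, t2 → M2) is applied to all apexes, i.e.
   MTU = M1 + (M2 − M1)(t − t1)/(t2 − t1). Standards land exactly on their
   reference MTU″ values by construction; any positive-slope affine drift
   of the instrument time base cancels exactly. The proprietary software
   this emulates may use more anchors or piecewise fits; the two-anchor
   linear reading is implemented, and a mild quadratic distortion option in
   the generator exercises its robustness limits.
3. **Quantification.** Analyte peaks are expressed as percent of summed
   analyte height (standards excluded); heights, not areas, because the
   published electropherograms report relative peak height proportions.
4. **Assignment.** Nearest library entry within ±1.0 MTU″ (no published
   tolerance; 1.0 is an order of magnitude above the measured recovery
   error and an order below typical peak spacing); two entries within
   tolerance and within 0.1 MTU″ of each other in distance → ambiguous.

The bundled glycan library anchors FA2G0-SO4 at 150, paucimannose (M3) at
178, fucosylated paucimannose (FM3) at 207 and FA1G0 at 245 MTU″, the
positions quoted for the real migration-time scale; the remaining entries
(FA2G2S2-SO4 95, FA2G2-SO4 120, FA2G2 130, A2G0 230, FA2G0 265) are
synthetic fixture positions, chosen only to be distinct and bracketed by
the standards. The two standards themselves (STD-LOW 50, STD-HIGH 320
MTU″) are synthetic stand-ins for the proprietary normalization mix.

## Digest and binding inference

Enzymes are encoded as substrate → product transition rules (F1-like
sulfatase: FA2G0-SO4 → FA2G0, terminal GlcNAc-6-SO4 only; F10-like
hexosaminidase: FA2G0-SO4 → FA1G0, removing the intact sulfated GlcNAc;
broad β-GlcNAcase: collapse of terminal-GlcNAc structures to M3/FM3). Trace
activity of the F10-like enzyme on asulfated GlcNAc under large enzyme
excess is reported unquantified in the source work and is fixed at zero
here. Comparing pre/post annotated peak tables, a substrate is *hydrolyzed*
if its relative height drops by ≥ 20% of its pre value and the rule's
product appears or grows by the same fraction; *unchanged* below threshold;
*depleted_no_product* when it drops with no product. The 20% default
quantifies the source's unquantified "no significant change" and is
configurable; raw deltas are always reported alongside.

The calcium-free binding call mirrors the proteinase-K control design: the
apo-enzyme binds the sulfated glycan and the complex is lost in clean-up,
so the substrate peak is depleted in the directly cleaned arm but restored
when the enzyme is first destroyed by proteinase K. Verdict *binding*
requires direct-arm depletion ≥ 20% with the proteinase-K arm within ±20%
of the control; a rule product counts as *hydrolysis* evidence only when it
is absent from the control — depletion renormalizes co-run reference peaks
upward, so growth of a pre-existing peak is not diagnostic. Relative (not
absolute) heights are compared throughout, matching how the published
traces are quantified; this also means depletion of a sole analyte is
invisible, so binding experiments need an inert co-run glycan, as the
simulated fixtures include. `concentration_response` checks that substrate
height is non-increasing in enzyme amount (≥ 3 amounts including zero;
single increases within a 5-percentage-point noise slack tolerated) and
reports the depletion span.

## Problem sizes and determinism

Test and acceptance runs use a miniature 5-plate screen for pipeline
checks, a 280-plate pure-noise screen (103,040 clone wells ≥ the 10^5
needed for a 3-SE FPR comparison) for the null calibration, 500 kinetics
sweep points, ten random-warp trace recoveries, and the four digest/binding
fixtures. Every random draw flows from an explicit seed through
`numpy.random.default_rng`; identical seeds reproduce datasets and run
summaries byte-for-byte, and the whole suite runs in about a minute on one
CPU.

## Known limitations

- First-order kinetics only; no saturation, product inhibition, enzyme
  depletion, or temperature/pH dependence. Calcium dependence is handled
  qualitatively in the binding logic, not kinetically.
- No plate spatial-effect correction or FDR control — the screen's rules
  are implemented as stated, not improved upon.
- Peak deconvolution of overlapping structures and baseline drift
  correction are out of scope; peaks closer than ~3 effective widths merge.
- The classifier cannot resolve the documented (direct ∧ asulfated)
  ambiguity without sequence information, by design.
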