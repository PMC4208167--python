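# Methods

## The dynamic S/N statistic

The reader's job is to reproduce a known grayscale signal faithfully. With
reference levels `M_i` (the five standard patches 247, 249, 251, 253, 255)
and measured grayscales `y_i`, the instrument is modelled as zero-point
proportional, `y = β·M`, the standard form for a dynamic (signal-following)
quality characteristic: a black scene must read black, so the line is
forced through the origin. The fit is

- `β = Σ M_i y_i / Σ M_i²` (closed-form through-origin least squares),
- `Sd = sqrt(Σ (y_i − β M_i)² / (n − 1))`,

and the per-run quality characteristic is `S/N = −10·log10(Sd²/β²) =
20·log10(|β|/Sd)` in dB, larger-the-better: it rises with proportionality
(|β| per unit of residual scatter) and falls with noise. An intercept-form
fit (`through_origin=False`, `n − 2` divisor) is available for diagnostic
use. `Sd = 0` is reported as the distinguished unbounded outcome
(`math.inf`), not an error: exactly proportional data are a perfect fit.
Residual norms below ~1e−12 of the signal norm are snapped to zero so that
exact proportionality survives floating-point rounding.

**Signal scale.** Scaling both `M` and `y` by a constant leaves β and every
level effect unchanged and shifts all runs' S/N by the same constant, so
screening conclusions never depend on the scale. Absolute dB values do:
the conventional reporting scale here is the normalized one (grayscale
divided by 255), under which a near-ideal 8-bit reader has β ≈ 1,
Sd ≈ 0.005 and S/N in the 40–50 dB range. `run_response(..., scale=255)`
selects it; the raw scale sits exactly `20·log10(255) ≈ 48.13` dB lower.

## Designs

The catalogue holds L4(2^3) and L8(2^7) (Sylvester–Hadamard construction,
first column dropped) and L12(2^11) built by the Plackett–Burman cyclic
construction (generator row `+ + − + + + − − − + −`, eleven cyclic shifts,
closing all-low row). All three are balanced and pairwise orthogonal —
every column pair shows each level combination `n/4` times — which the test
suite verifies exhaustively. `generate_orthogonal_array` returns the
smallest design that fits the factor count; ten camera parameters land on
L12 with one spare column that stays unassigned as the error column.

L12 is non-regular: two-factor interactions are partially confounded with
*every* column rather than aliased onto specific ones. That is what makes
it a good main-effect screen and a poor interaction estimator, so
`interaction_cells` always emits `ConfoundedInteractionWarning` on L12 and
the documented workflow for a suspected interaction is a dedicated 2×2
full factorial follow-up (re-levelling the factor if needed), not a
reinterpretation of the screening runs.

## Response table, ANOVA, level selection

The response table holds per-column level means of run S/N, the effect
(level-2 mean − level-1 mean), its absolute value (range), and ranks by
descending range with ties broken by column order. On any balanced design
the average of a column's two level means equals the grand mean; this is
asserted to 1e−9 as a structural invariant.

ANOVA assigns each two-level column `SS = (n_runs/4)·effect²` with one
degree of freedom. The error term always contains the unassigned columns;
the pooling rule may add assigned factors:

- `"none"` — unassigned columns only;
- `"below-error"` (default) — additionally pool factors whose range falls
  below the largest unassigned-column range (columns that behave like the
  noise column are noise);
- `("range-below", x)` — prescreen-then-confirm: pool every factor with
  range < x dB and F-test only the large-effect candidates. With x = 3 on
  the reference camera study this screens exactly the backlight-
  compensation, gamma and sharpness factors above 95%;
- `"half"` — classical heuristic, pool smallest-SS factors until the error
  pool holds about half the total dof;
- an explicit list of factor ids.

Factor confidence is `100·(1 − P(F > f))` with `f = MS_factor/MS_error` on
`(1, error dof)` degrees of freedom; `significant_factors` keeps non-pooled
factors strictly above the threshold (default 95%), ordered by descending
F. Note that with a single error dof the F distribution's tail is so heavy
that only very large effects clear 95% — pooling choices genuinely matter,
which is why the rule is an explicit, reported parameter rather than a
hidden default.

`select_optimal` is deliberately baseline-preserving: only factors that
passed the screen move to their better level; everything else keeps its
baseline setting. The predicted S/N is the additive-model value
`grand_mean + Σ_significant (chosen-level mean − grand_mean)`. On the
reference study's printed level means with {A, F, I} significant this
evaluates to 50.51 dB, within 0.1 dB of the measured 50.5 dB confirmation.

## Densitometry

Images are converted with BT.601 luma (0.299 R + 0.587 G + 0.114 B,
rounded half-up); the lane profile is the per-row mean grayscale (flow axis
along rows). Band calling: background starts at the profile median, rows
more than `min_depth` (default 5 grayscale units) below it are flagged,
and the median is re-taken over unflagged rows (two passes, so a dark band
cannot drag the background down). Maximal flagged runs are candidate
bands; the `expected` deepest (default 2) are kept, ordered along the flow
axis. The band centre is the midpoint of the called extent — robust on
flat-bottomed bands, where the deepest pixel wanders under noise. Roles
follow geometry: the band nearest the absorbent-pad end is the control
line (`orientation="control-bottom"` by default, configurable). A strip
with no control band is invalid; a control-only strip is a valid blank.

**Polarity.** A darker test line has *lower* raw grayscale, so the raw
band mean decreases with concentration while the background-corrected
`net_signal = background − mean_gray` increases with it. Both conventions
are reported per band; `measured_grayscale` follows the configured
polarity, default `net`, and calibration accepts either monotone
orientation. The lane is taken from configuration rather than
auto-registered: the use case is a fixed strip carrier, where geometry is
known; auto-registration is out of scope.

## Synthetic strips and simulated experiments

The generator emulates the features the reading pipeline depends on, not
the optics: a uniform membrane (default gray 220) with additive Gaussian
pixel noise (default sd 1 grayscale unit — chosen so the default
calibration study lands in the single-digit-CV regime a well-adjusted
reader achieves), a fixed control band (depth 80), and a test band with a
linear dose–response, `depth = 60·min(c/50, 1)`: proportional over the
assay's 0–50 mIU/mL working range, absent at zero, clamped above 50 (a
stand-in for saturation/hook behaviour; no binding kinetics are modelled).
Bands are rectangular (8 rows); real bands have soft edges and real
membranes have texture and illumination gradients, so passing tests show
the pipeline's logic is correct, not that it is robust to every field
artefact.

The camera model applies, in a fixed documented order: exposure (scale) →
gain (scale plus amplified read noise) → brightness (offset) → contrast
(gain about mid-gray 128) → gamma (`255·(x/255)^(1/γ)`) → white balance
(phenomenological R/B scaling against a 6500 K neutral) → hue/saturation
(luma-preserving YIQ chroma rotation/scaling — a no-op on achromatic
scenes, which is physically right for a gray strip and mirrors the
empirical insignificance of those two parameters) → sharpness (3×3
unsharp mask) → backlight compensation (highlight compression above a
225 knee), then clipping to [0, 255] and half-up rounding to 8 bits.
Rendering is bit-identical for fixed (spec, params, seed).

**Simulated screening experiments.** `simulate_l12` does *not* push factor
levels through the pixel pipeline: camera transforms have uncontrolled,
configuration-dependent effects on the fitted S/N, which would make
ground truth unknowable. Instead the factor effects are injected directly
on the S/N scale: each run's target S/N is `base + Σ effect_j·x_j` (±1/2
contrast coding, so the response-table effect equals the declared value in
expectation, optional product terms for interactions) plus Gaussian
run-to-run noise (default 0.5 dB); the five reference patches are then
rendered at `M_i + e_i` where the residual vector `e` is drawn orthogonal
to `M` and scaled to an exact sample sd of `10^(−S/N/20)` (normalized
scale), and measured back through the densitometry profile. The fitted
slope and spread therefore recover the injected values up to 8-bit
quantization and patch-averaging error (≲0.3 dB). Patches are rendered
under a fixed 0.9 baseline exposure so the brightest standard keeps
headroom below the 8-bit ceiling; since this scales β and Sd jointly it
leaves every run's S/N untouched. Default effects mirror the reference
camera study: A +3.15 dB, F −7.36 dB, I +3.87 dB as the influential trio
(|effect| ≥ 3 dB) over a 40 dB base, all other factors null.

## Calibration

Classical calibration: signal is regressed on concentration (OLS via
`scipy.stats.linregress`), and unknowns are obtained by algebraic
inversion `(signal − intercept)/slope`. The model is a straight line over
6.25–50 mIU/mL — adequate for this range; a log-concentration option
exists but is off by default. R² is `1 − SS_res/SS_tot`; the residual sd
uses the `n − 2` divisor. Inversion outside the fitted concentration
range is flagged (`in_range=False`) rather than refused. Precision is
summarized per level on back-calculated concentrations: CV = 100·sd/mean
(n−1 divisor; flagged NaN for a single replicate) and percent error of
the mean against nominal — the "<10%" style headline figures are defined
on this scale. Degenerate inputs (single concentration, flat signal) are
rejected with distinct errors; slope exactly 0 is non-invertible.

## Problem sizes and numerical choices

- Default simulated studies: L12 (12 runs × 5 patches of 24×24 px), and
  5 calibration levels × 3 replicate strips of 120×40 px; the recovery
  property is evaluated over 100 seeds. These sizes make every result in
  the test suite and acceptance script reproducible in seconds while
  leaving the statistics comfortably powered.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); no hidden global state.
- Tolerances: reproduced response-table effects are compared at ±0.0005
  (printed rounding of reference values); structural identities (grand
  mean, ANOVA decomposition, inversion round trip) at 1e−6 to 1e−9.
- Tie-breaks: response-table rank ties keep column order; best-level ties
  report level 1; interaction best-cell ties take the lexicographically
  smallest level pair.

## Known limitations

- No optical physics (gold-nanoparticle plasmonics), membrane-flow
  kinetics, illumination-field flattening, perspective correction or
  colour-card normalization; lane geometry must be supplied.
- Only two-level arrays; no mixed-level or inner/outer noise-array
  designs; no static S/N characteristics.
- The L12 interaction analysis is screening-grade by design (see the
  confounding caveat); definitive interaction estimates need a follow-up
  factorial.
- Calibration is strictly linear in the working range; 4PL/5PL sigmoid
  fitting and blank-based LOD/LOQ rules are out of scope.
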