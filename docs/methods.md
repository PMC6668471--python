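# Methods

## The statistical model

The workflow rests on one physical fact and one design choice.  The fact:
¹H NMR resonance intensity is proportional to molar concentration when
spectra are acquired identically on identically concentrated samples.  The
choice: microfractions are pooled so each constituent's concentration varies
smoothly over several consecutive fractions.  Together they mean that every
spectral variable belonging to compound *k* is, up to noise, a scalar
multiple of *k*'s concentration profile — so variables of the same compound
are collinear across fractions, and variables of an activity-carrying
compound co-vary with the bioassay response.

For a window ("package") of *n* consecutive fractions with bucket matrix
`X (n × p)` and response `y (n)`:

* covariance `cov_j = Σ_i (x_ij − x̄_j)(y_i − ȳ) / (n − 1)`
* correlation `r_j = cov_j / (s_j · s_y)`

HetCA takes `y` = activity; STOCSY takes `y` = the driver bucket's
intensities.  Both run through the single kernel
`elina.correlate.cov_corr_kernel`, which is also reused for LC-MS AUC
correlation — one implementation, property-tested once.

Conventions, each deliberate:

* **Sample (n − 1) denominator.**  With n = 3 this changes covariance
  magnitude (not correlation or labels) versus a population denominator;
  stated so users can reconcile against other software.
* **Zero-variance buckets are undefined (NaN), never 0.**  An empty bucket
  is absence of evidence; mapping it to r = 0 would fabricate
  "uncorrelated" evidence.  Undefined buckets are always `neutral`.
* **Driver self-correlation is pinned to exactly 1.0** when the driver
  varies; floating point would otherwise report 1 ± 1 ulp.
* **Labels**: `hot` ⇔ r ≥ t, `cold` ⇔ r ≤ −t, else `neutral`; default
  t = 0.8 — an explicit, reported parameter chosen so that with n = 3 only
  near-collinear buckets qualify, while plots keep the full continuous
  colour map (labels and colours are independent renderings of r).
* **Driver resolution**: nearest bucket centre; an equidistant tie goes to
  the lower-ppm bucket.
* **Package selection is manual-first.**  `enumerate_packages` annotates
  every window with its activity variance, but nothing auto-selects: a
  window with no activity contrast yields an all-neutral result (with a
  warning), and the workflow aborts with a variance ranking if no package
  is declared.

## Preprocessing

* Baseline: quartic polynomial in *raw* ppm (coefficients A–E reported in
  ppm units; callers may rescale x for conditioning but the stored model is
  in ppm).  Anchors are manual, or selected by an iterative low-quantile
  scheme: fit to all points, keep residuals ≤ q·(1.4826·MAD), refit; q = 1,
  max 20 iterations, stop when the anchor set stabilises or would drop
  below the 5 points a quartic needs.  Lorentzian tails are fat, so near
  tall peaks the recovered floor sits slightly high; the tests bound this
  at < 0.2 % of peak height away from peaks.
* Bucketing *sums* points (never averages) over half-open intervals
  `[left, left + width)`, final bucket right-closed — an exhaustive,
  exclusive partition that conserves total in-range signal.  The bucket
  count is `round((high − low)/width)` so the inexact binary representation
  of widths like 0.0005 still yields the intended 13,000 buckets for
  δ 0.5–7.0.
* No between-fraction normalization by default (samples are assumed equally
  concentrated, which is what keeps bucket sums proportional to molarity);
  an optional total-sum flag exists for unequal loadings.
* Series assembly interpolates linearly onto a user-supplied shared grid;
  extrapolation is an error, since spectra from one campaign share
  acquisition conditions and a coverage gap indicates a data problem.
  Digital resolution is not assumed — the grid spec is the caller's.

## Masses

The embedded table uses IUPAC standard atomic weights (conventional single
values: C 12.011, H 1.008, O 15.999, N 14.007, S 32.06, …) for average
molecular weights, and most-abundant-isotope masses for monoisotopic m/z.
Adducts [M+H]⁺ and [M+Na]⁺ include the electron mass (proton
1.007276 u, Na⁺ 22.989221 u).  Display rounding is round-half-even at two
decimals; full precision is kept internally.  The test suite cross-checks
monoisotopic values against an independent mass library.

## Dereplication filters

Filters are pure set logic over boolean feature tags supplied with the
candidate table — the module encodes the expert decision layer, not
substructure perception.  Retention is order-independent
(`required ⊆ hot ∧ cold ∩ excluded = ∅ ∧ other ⊆ allowed`); only the
audit's "first failing filter" uses the fixed A→B→C order.  Filter C is an
allow-list: the caller passes the feature tags for which the pseudo-spectrum
shows evidence, and anything else disqualifies.  Consequences that follow
from the set logic — idempotence, monotone shrinkage under tightening — are
property-tested.

## The synthetic campaign

`simulate_campaign` draws everything from one integer seed:

| parameter | default | why |
|---|---|---|
| lineshape | Lorentzian (area-normalised) | solution-state NMR lineshape |
| half-width | 0.004 ppm | ~2 Hz at 500 MHz |
| elution profile | Gaussian in fraction index, spread ≥ 1.5 | smooth unimodal stand-in for flash-chromatography bands, pooled to spread constituents |
| spectral noise sd | 0.05 (peak heights run ~10–250) | cryoprobe-grade SNR |
| activity noise sd | 3 percentage points | ~5 % of peak activity |
| activity | clamped (≤ 100 %) linear sum of active concentrations | additivity assumption, exposed as a config point; no synergy/antagonism modelled |
| AUC | 5·10⁴ × concentration | proportional ionisation for MS-visible compounds |
| baseline | one quartic shared by all fractions | slow instrumental drift; note a *shared* baseline cancels identically in covariance |

The documented fixture (`default_fixture`, seed 2019) is a 32-fraction
campaign with seven constituents: one active triterpene-like compound
(resonances at 5.57, 5.12, 1.65, 1.60, 0.92 ppm; activity coefficient 65 %
per unit concentration; eluting last, peak at fraction index 14), an
inactive hydroxylated congener carrying the 4.05 ppm cold feature, a matrix
triterpene, two sugar-region constituents eluting early (3.0–4.0 ppm), a
phenolic trace and a fatty matrix component.  All inactive constituents
elute *before* the active one, so across the documented analysis window
(fractions F13–F15, the rising activity limb, chosen manually for its clear
activity variance) their concentrations fall while activity climbs — the
configuration in which hot/cold labelling is well-posed.  Windows on the
falling limb would invert the sign of every inactive compound's correlation;
that is a property of the method, not of this implementation, and is why
package choice is manual.

What the simulator does **not** emulate — and hence what passing tests do
not certify about real campaigns: J-coupling multiplets, chemical-shift
drift between fractions (pH/matrix effects), rolling or fraction-dependent
baselines, co-eluting actives, peak-shape changes, non-additive
(synergistic/antagonistic) bioactivity, and MS ionisation suppression.
Recovery results on the fixture demonstrate correctness of the statistics
under the model's assumptions, not robustness to their violation.

## Numerical choices and problem sizes

* Correlations are computed via centred sums with a guarded divide; agreement
  with an explicit two-pass loop implementation is enforced to 12
  significant digits in the tests.
* Degenerate inputs fail loudly: < 2 package members, zero-variance STOCSY
  drivers, anchors below 5 distinct ppm values, grids not covering a
  requested range, duplicate ppm values or fraction IDs.
* Test and acceptance runs use the fixture at full spectral resolution
  (26,001 grid points, 13,000 buckets, 32 fractions) — a few hundred ms per
  campaign; the Monte-Carlo noise-degradation check runs 50 seeds at halved
  resolution, which does not change the statistic being compared.
* CSV writers emit shortest-round-trip float representations and readers
  parse with round-trip precision, so save/load and rerun outputs are
  byte-identical.

## Known limitations

* With three-fraction packages, n = 3 correlations are extremely coarse:
  pure-noise buckets exceed |r| = 0.8 with appreciable probability, so
  isolated hot/cold buckets are meaningless in the noise floor —
  `hot_cold_report` therefore requires runs of ≥ 2 buckets and ranks by
  covariance magnitude, which noise buckets lack.  Interpret hot/cold labels
  jointly with the covariance pseudo-spectrum, never alone.
* An inactive compound co-eluting with the active one (both rising through
  the chosen window) is statistically indistinguishable from it in a single
  package; comparing packages along the series is the practical remedy.
* The A/B/C filters are only as good as the supplied feature tags; no
  structure perception is attempted.
* Bruker/vendor raw data ingestion is out of scope; inputs are delimited
  text (two-column spectra or a ppm × fraction matrix).
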