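# Methods

## The calling decision

Each well-channel is decided from the baseline-corrected trace (first reading
subtracted; raw traces carry an arbitrary optical offset). Two times matter:
the end point EP (default 600 s, the end of the 10-minute detection step) and
the judging point JP (default 300 s); both are per-well-channel parameters of
the `ThresholdSet`.

1. **Negative threshold.** If F(EP) < FNT the channel is negative with reason
   `below_FNT`; the signal ratio is left undefined. F(EP) == FNT proceeds to
   stage 2 ("not less than").
2. **Signal ratio.** SR = F(JP)/F(EP). The channel is positive iff SR > RPT,
   strictly; SR == RPT is negative.

The instrument's own SR formula is published only as a figure equation, so the
definition here is a design choice: SR = F(JP)/F(EP) operationalizes "reaction
efficiency" — an invasive-cleavage cascade running on abundant matched
amplicon saturates well before EP, so it has reached most of its end-point
signal by JP (SR → 1), whereas slow nonspecific drift accrues linearly
(SR → JP/EP = 0.5). An alternative late-rise definition,
(F(EP)−F(JP))/F(JP), is available behind the `definition` switch of
`compute_sr` (note it inverts the ordering of the two shapes, so it would pair
with a *smaller-than* threshold); nothing else in the package uses it.

**Well validity.** The published decision chart is silent about the wild-type
channel. By default a test well whose channels *both* fall below FNT is flagged
`invalid` — nothing amplified, so the negative mutant channel carries no
information. `--strict-paper` (or `validity_gating=False`) disables this gate
and reports such wells as plain negatives. A sample is `invalid` only when at
least one test well is invalid and no well is positive; any positive well makes
the sample `mutant` and all detected mutations are reported together (the panel
deliberately represents co-occurring KRAS/PIK3CA mutations, including two
mutations in one gene).

## Threshold calibration

- **FNT** = mean + k·sd (sample sd, ddof = 1; k = 3) of no-template end-point
  signals — the usual limit-of-blank construction. At least 3 controls.
- **RPT** = geometric mean of max(SR | 0% mutant) and min(SR | 5% mutant),
  per target. The geometric midpoint is used because SR is a ratio; the
  arithmetic midpoint is an option. If the two SR classes overlap, calibration
  fails loudly with both boundary values — a threshold inside overlapping
  classes would be meaningless. By construction the calibrated thresholds
  separate their own training runs perfectly; that is asserted, not assumed.
  Library calls accept any non-empty class; the CLI requires 3 replicates per
  class.

## The kinetic simulator

The simulator reproduces the *observable* (plateauing fluorescence and its
titration behaviour), not the enzymology; a full Michaelis–Menten cascade
would be overfit to unpublished rate constants. Stages:

1. **Template.** Copies = mass / (length · 650 g·mol⁻¹·bp⁻¹ / N_A); 1 fg of
   the 4.2 kb assay plasmid gives 221 copies (instrument documentation rounds
   to ~210; the ~5% gap comes from the mass-per-bp convention and is accepted).
   Mutant copies are drawn binomially at the nominal fraction — the dominant
   noise source at limiting dilution. Carrier human genomic DNA adds wild-type
   target copies (3.3 pg per haploid genome, ≈ 303 copies/ng).
2. **PCR.** Logistic growth n ← n + e·n·(1−n_total/cap) per cycle with the two
   allele pools sharing one plateau (`amplicon_cap`), so allele fractions are
   preserved and the plateau divides by input fraction. Pools under 50 copies
   duplicate binomially (seeded); larger pools use the deterministic
   expectation (relative variance ≲ 2%). Default 35 cycles at efficiency 0.9
   brings every template input from 1 fg to 100 fg to the plateau — which is
   exactly why the assay's sensitivity is mass-independent over that range and
   why the mutant-channel background is flat from 1 to 100 ng of carrier.
3. **Read-out.** Channel signal = gain·A_matched·(1−e^(−k_match·t)) +
   gain·A_other·(1−e^(−k_mismatch·t)) + drift·t + baseline + N(0, σ²), sampled
   at 1 s. The mismatch leak models the near-inability of the flap
   endonuclease to cut a one-base-mismatched probe: small but non-zero.

Defaults (arbitrary fluorescence units): cap 10¹², gain 5·10⁻⁹ per amplicon
(≈ 5000-unit full plateau), k_match 0.02 s⁻¹ (saturated well before JP),
k_mismatch 10⁻⁵ s⁻¹ (≈ 30-unit end-point leak at full wild-type plateau),
drift 0.05 units/s, noise σ = 2, baseline 100. These are stand-ins chosen once
for qualitative realism: a 5%-mutant well yields ≈ 250 signal units (SR ≈ 0.9)
against an FNT near 40, a wild-type-only well has SR ≈ 0.5, and the calibrated
RPT lands near 0.7. The resulting detection limit at the ≥ 95%-of-replicates
criterion is a 5% mutant fraction, with sporadic detection at 0.5–1% — the
"clearly detected at 5%, at best 0.5%" regime. The 95% criterion itself is a
package choice; "clearly detected" has no published definition.

**Sanger comparator.** Direct sequencing reads the mutant fraction as a
secondary electropherogram peak; the simulated peak-height ratio equals the
fraction plus Gaussian noise (σ = 0.02) and is called at ≥ 25% of the primary
peak (boundary inclusive). Under the same 95%-of-replicates criterion noise
makes the effective limit sit at or above 25%, which is the point of the
comparison: an order of magnitude less sensitive than the chip.

## Concordance statistics

- κ = (p_o − p_e)/(1 − p_e) with p_e from the table margins; undefined (raised)
  when p_e = 1. Verified against an independent reference implementation by
  enumerating every 2×2 table with n ≤ 20.
- A single κ spanning frozen and FFPE strata can be pooled several ways;
  `kappa_variants` reports per-table, pooled-count and mean-of-table values
  side by side and none is claimed to match any externally printed κ (the
  published pooling rule is unstated). The published "statistical power"
  values likewise have no stated model and are not reproduced.
- Clone error rate ER = alterations / (insert length × clones) × 100, in
  percent per base. The mutant-vs-error test is a one-sided exact binomial
  tail P[X ≥ k], X ~ Binomial(n clones, ER/100) — the most literal per-base
  reading of ER; clone sets pool by summing k and n. Cross-checked against
  brute-force pmf summation.
- Cohort summaries aggregate samples to patients; paired samples with
  discrepant mutation sets are flagged and resolved by union, since the less
  sensitive preparation is the one expected to miss low-fraction mutations.
- Sequencing failures are excluded from tables with an explicit per-gene
  excluded count, never silently.

## Synthetic data: what a green test establishes

The fixture generator and simulator emulate saturating positive traces, linear
background drift, template-sampling noise and mutant-fraction titrations, all
bit-reproducible from one seed. They do **not** emulate FFPE fragmentation,
cross-reactivity between non-target mutations, probe thermodynamics, optical
cross-talk, or inter-lot variation. Green simulation tests therefore establish
that the calling algorithm and calibration behave correctly *given* the stated
signal model — not that the model matches any particular instrument's physics.
Published clinical counts (the per-gene 2×2 tables, call-rate counts, the
multiple-mutation list, the 41-sample automated-run margins) are shipped as
data and exercised as statistical inputs; where per-sample detail was never
published, reconstructions are labelled synthetic.

## Numerical choices and degenerate inputs

- Traces with non-monotone timestamps are rejected, not sorted (sorting hides
  acquisition faults); decision times must be inside the sampled range, no
  extrapolation. Baseline-correcting twice raises.
- F(EP) ≤ 0 after correction is a degenerate trace and raises rather than
  producing a meaningless ratio.
- All randomness flows from explicit seeds through `numpy.random.SeedSequence`
  spawning; trace files round-trip via fixed-format text so fixture bundles
  are byte-identical per seed.
- Flatness of the carrier-mass background is asserted as < 10 fluorescence
  units of spread across 1–100 ng — a few percent of the ≈ 280-unit 5%-mutant
  signal — plus the stronger operational check that every background well is
  called negative.

## Known limitations

Rate constants are stand-ins (unpublished); mutant-fraction quantification
from SR is deliberately out of scope (the assay calls presence/absence only);
the chip-to-mutation well map is user configuration (no canonical layout is
published); no cross-run fluorescence normalization is attempted.
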