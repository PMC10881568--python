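# Methods

This note documents the models behind `httcag`: what the synthetic data
emulate, how each analysis stage is defined, the defaults that matter, and
what the package's passing tests do and do not establish about real data.

## Population allele model

Constitutional HTT CAG allele sizes are drawn from a truncated, discretized
log-normal on integer repeats 9–55, parameterized by its mode (17 repeats)
and log-scale spread σ = 0.25, giving ≈ 6.0% of alleles in the intermediate
band (27–35) — in line with reported population frequencies of HTT
intermediate alleles — and a mean allele of ≈ 18.7 repeats. This
distribution is a stand-in: no individual-level allele frequencies are
published for the cohorts the package emulates, and every analysis accepts a
custom `AlleleModel`.

Two devices make cohort construction exact rather than merely
expected-value-correct:

- **Forced carrier counts.** When a group specifies k intermediate-allele
  carriers, exactly k individuals receive one allele drawn from the model
  conditioned on 27–35 and one conditioned on ≤ 26; all other individuals
  draw both alleles conditioned on ≤ 26. Published cohort tables report
  exact counts, so the generator reproduces counts exactly, not in
  expectation.
- **Exact mean shifts.** A per-allele shift δ is applied at the distribution
  level: the pmf is moved by ⌊δ⌋ and ⌊δ⌋+1 with probabilities (1−frac(δ),
  frac(δ)), extending the support range as needed. The expectation of each
  allele then changes by exactly δ and of the per-individual sum by 2δ.
  When both a shift and forced carriers are requested, conditioning applies
  to the shifted pmf, preserving exact counts; the shift in the conditioned
  draw is then approximate (truncation bias), so recovery experiments use
  unconstrained groups.

Seeding: one parent `SeedSequence` spawns an independent child stream per
group, so editing one group's spec never perturbs another group's draws, and
the ledger records the spawn keys.

## Peak-profile measurement model

Simulation starts at the peak level — (position, height) pairs as exported
by fragment-analysis software — not at raw fluorescence. For each allele
copy with main height H (default 1000 RFU):

- **Stutter** (left): heights H·s^k at −k repeats, k = 1..depth
  (s = 0.30, depth 3).
- **Somatic expansion** (right): heights H·λ·e^(k−1) at +k repeats,
  truncated below 1 RFU (λ = 0.20, e = 0.45).
- Contributions landing in the same repeat bin add (a homozygote's two
  copies sum; stutter of a long allele merges into a nearby short allele).
- **Noise**: zero-mean Gaussian height noise (SD 30 RFU), sparse baseline
  peaks (Poisson rate 2, heights |N(0, 30)|+1), Gaussian bp-position jitter
  (SD 0.15 bp), and clipping to (0, 32000] RFU.
- Repeat r maps to fragment size `flank_bp + 3r`; two primer-set profiles
  ("lund": 54 bp, "bochum": 87 bp) stand in for the two assays' non-repeat
  amplicon lengths, which are configuration values, not published constants.
- A GeneScan-500-style ladder (16 fragments, 35–500 bp) is co-emitted per
  lane; an affine bp→raw transform (defaults 9.6 units/bp, offset 2400)
  produces instrument-space tables for the calibration stage to undo.

Stutter is modelled only leftward and expansion only rightward: the
expansion index considers only right-side peaks, and somatic contraction is
outside the analytic scope. Ladder peaks are emitted noise-free — the
internal standard is the sizing reference, assumed confidently identified
upstream; calibration robustness to ladder noise is not the simulator's
concern.

**Calibration of defaults.** Stutter and mosaicism magnitudes are not
published for the emulated assays. The defaults were fixed by two
requirements: the end-to-end calling contract (≥ 99% of alleles < 45 repeats
called within ±1) must hold, and the default simulated control-group mean EI
should fall in the 0.10–0.13 range reported for real control cohorts (it is
≈ 0.12 at the defaults). They are stand-ins, not estimates of any
instrument's stutter chemistry.

## Calibration and allele calling

Raw-space positions are mapped to bp by monotone piecewise-linear
interpolation through the (ladder peak, standard fragment) pairs, with
linear extrapolation beyond the end knots; an affine migration model is
therefore recovered exactly. bp converts to integer repeats by
`round((bp − flank_bp)/3)` with ties to even — the package's documented
rounding convention, standing in for unpublished clinical rounding routines.

Calling anchors on the modal (highest) peak, ties to the larger repeat. The
second allele is the tallest peak that survives three screens relative to
the anchor height h₁: a detection floor (< 10% of h₁ is never a candidate),
a stutter mask (within 3 repeats left of a called allele and < 50% of h₁),
and an expansion mask (right of the anchor and < 50% of h₁). The cuts are
set so that default-simulated stutter (30% per repeat) is always masked
while balanced heterozygous peaks never are; all are config keys. If nothing
survives, the call is homozygous with a flag — single-allele dropout is
indistinguishable from homozygosity in a peak table, and diagnostic
convention reports two alleles. A surviving second allele inside the stutter
window below 75% of the anchor is flagged `adjacent-allele-ambiguity`;
masked peaks taller than 35% of the anchor are flagged for review.
Downstream statistics use the integer point estimates with no propagation of
the ±1-repeat assay error.

## Expansion index

`compute_expansion_index` implements the EI defined in the README: modal
anchor, relative retention threshold c = 0.20 applied to the height *ratio*
(exact at the boundary for integer heights), normalization over the retained
set including the modal peak — which makes EI = 0 exact in the no-expansion
case and bounds the weights. Instability-index dialects differ on both the
threshold and the denominator; both choices are recorded in every result and
c is a config key.

For per-sample pipeline use, the statistic is anchored on the **larger
called germline allele** (`expansion_index_for_allele`): the table is first
restricted to repeats ≥ that allele. In a heterozygote the globally modal
peak is often the shorter allele, and without the restriction the longer
germline allele itself would be retained as a huge spurious "expansion"
peak. Anchoring on the expanded-allele region matches how instability
indices are computed around the progenitor allele in repeat-disease assays,
and yields EI ≡ 0 when mosaicism is switched off (λ = 0).

The reference control subset used by the emulated study (250 consecutively
selected controls) enters only as a comparison group for EI summaries; no
per-sample normalization against controls is applied, since none is
specified for the statistic itself.

## Statistical layer

Group summaries are mean and sample SD (n−1) of the per-individual sum of
repeats. Comparisons use the pooled-variance Student t-test (the printed
p-value of the emulated analysis is consistent with the pooled, not the
Welch, form recomputed from its printed summaries), two-sided, with a 95% CI
on the mean difference. Bonferroni correction is implemented as threshold
adjustment — raw p compared against α/m — matching the "p < 0.017"
convention for m = 3 subgroup comparisons. The without-IA sensitivity
re-analysis removes every individual with any allele in 27–35 and is
evaluated against the unadjusted α = 0.05, as a single follow-up comparison.
Intermediate-carrier percentages are rounded to one decimal (Python's
round-half-even; for every published cell except one this is
indistinguishable from half-up — see limitations).

Recomputing the MLH1-vs-controls test from the published rounded summaries
(n = 60, 35.40 ± 3.6 vs n = 559, 36.89 ± 4.5) gives p ≈ 0.013 and CI
(−2.670, −0.310) against the published p = 0.014, CI (−2.766, −0.310).
Exact reproduction of the third decimal is impossible from two-decimal
summaries; the package's tests assert the decision (p < 0.017) and CI
agreement to ±0.1.

## Problem sizes used by the test suite and acceptance script

Calling accuracy: 1200 samples (2400 alleles) at default trace parameters.
EI oracle equivalence: 1000 random ≤ 8-peak tables against an exact-rational
brute-force enumeration. Shift recovery: 100 replicate two-group cohorts
(559 + 60) with δ = −0.75 per allele, compared to the analytic −1.5 sum
difference within 2 Monte-Carlo SE. Type-I calibration: 1000 replicates of
two 40-individual groups, empirical rejection rate checked against the
binomial 95% band around 0.05. The full default pipeline (730 samples,
simulate → call → EI → stats) runs in about two seconds.

## Known limitations

- The allele model, stutter/mosaicism magnitudes and primer flank lengths
  are plausible stand-ins, not fitted to any instrument or population;
  passing tests establish internal consistency of the pipeline under this
  measurement model, not accuracy on any particular laboratory's data.
- One published carrier-fraction cell (MSH6, 1 carrier of 23) prints as 4.4%
  although 1/23 = 4.348 → 4.3 at one decimal; the tally reproduces the
  arithmetic (4.3), so that single cell intentionally disagrees with the
  printed table.
- No CAA-interruption or sequence-level modelling: a canonical
  glutamine-encoding repeat structure is assumed throughout.
- No somatic contraction modelling and no contraction index.
- EI is age-dependent in real cohorts; the simulator draws no ages and
  applies no age adjustment, so group EI contrasts here reflect only the
  configured trace parameters.
- Homozygous calls conflate true homozygosity with allelic dropout; the
  simulator does not model dropout, so this ambiguity is flagged but never
  exercised.
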