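# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical and design decisions that were genuinely
open.

## Estimands and estimators

The causal parameter is the change in outcome log-odds per SD increase in
genetically predicted plasma protein level. Exposure betas are in SD units
per effect allele; binary-outcome betas are log-odds per allele.

**Wald ratio.** For one instrument, θ̂ = β_out/β_exp. The default SE is the
first-order delta approximation |se_out/β_exp|, which treats β_exp as known.
A second-order option adds the exposure-noise term,
se² = se_out²/β_exp² + β_out²·se_exp²/β_exp⁴. The first-order form is the
reporting default because it matches the convention of two-sample MR
summary pipelines; however, when the outcome GWAS is much larger than the
exposure panel the neglected term is material — under this package's default
cohort shapes (exposure n = 7213, outcome effective n ≈ 61,450) the
first-order 95% CI covers the true θ in only ~86% of synthetic replicates,
versus ~93–95% with the second-order SE. The Monte Carlo coverage diagnostic
therefore uses the second-order SE; p-values and reported intervals keep the
first-order default. Under a null causal effect the two coincide (β_out ≈ 0
kills the extra term), so test calibration is unaffected: measured type-I
error is ~4–6% at the nominal 5%.

**IVW.** With k ≥ 2 instruments, per-SNP ratios θᵢ with σᵢ = |se_outᵢ/β_expᵢ|
are pooled with weights 1/σᵢ² (fixed-effect). This equals the zero-intercept
WLS regression of β_out on β_exp weighted by 1/se_out², which the test suite
verifies against statsmodels. Fixed-effect rather than multiplicative
random-effects IVW was chosen because instrument counts here are small
(k ≤ 3) and heterogeneity is reported separately via Cochran's Q
(df = k−1, upper-tail χ² p). With k = 1 IVW reduces exactly to the Wald
ratio.

**Multiple testing.** Benjamini–Hochberg step-up q-values across the
per-outcome protein family. The family size m defaults to the number of
tested proteins but is a configuration parameter, since a screen that
pre-filters proteins before estimation may need the full family size
restored.

**OR reporting.** OR = exp(θ̂) with normal-theory CI using the exact 97.5%
normal quantile 1.959964 (not 1.96) so that CI↔SE↔p round-trips are
deterministic to full precision. `p_from_or_ci` inverts a printed OR/CI pair
back to its p-value; on published single-instrument rows this inversion
recovers the printed p within 2% even at p ~ 10⁻¹⁶.

## Instrument selection

Criteria, in any order before clumping (the filters commute): variants on
the gene's chromosome within 1 Mb of the gene *boundaries* (not TSS only);
p < 5×10⁻⁸ strictly; outside chr6:26,000,000–34,000,000 inclusive (the MHC,
where extreme LD and pervasive pleiotropy make instruments untrustworthy).
Greedy clumping then repeatedly emits the remaining variant with smallest p
(ties broken by smaller position, making output deterministic) and discards
everything at r² ≥ 0.001 with an emitted variant. Variants absent from the
LD panel are treated as independent and logged. The clump is verified
against a brute-force characterization of the greedy solution on small
instances.

**Variance explained and F.** No formula for per-SNP variance explained is
universal for summary data; this package defaults to the Z-based pseudo-R²,
R² = Z²/(Z²+n−2), because it needs only the association Z and n and is the
form Steiger-style direction tests use. A frequency-based alternative
2f(1−f)β² is provided. For binary traits the same pseudo-R² is applied on
the observed scale — a documented approximation adequate for the Pass/Fail
decisions it feeds. Instrument strength is F = (R²/(1−R²))·(n−k−1)/k; at the
discovery panel size this reproduces published F values from published R²
to ~0.05% (the residual is printed-R² rounding).

## Steiger directionality

Total instrument R² per trait is the sum of per-SNP pseudo-R² (instruments
are clumped, so near-independence makes the sum adequate; it is capped below
1). The comparison is a two-sample z-test on Fisher-transformed |r|:
z = (atanh r_exp − atanh r_out)/√(1/(n_exp−3) + 1/(n_out−3)), two-sided.
The direction verdict (r²_exp > r²_out) and the significance of the
comparison are reported separately; a candidate is excluded from grading
when the direction is wrong or the comparison is non-significant at 0.05.
Under the default study conditions (pQTL z ≥ 8, θ ≤ 0.5) the direction is
correct in ≥ 99% of synthetic replicates, so the filter costs essentially
no power while screening out reverse causation.

## Replication and meta-analysis

Replication re-derives the estimate in each alternative pQTL-panel ×
outcome-GWAS pairing with the same selection rules. Two pools are formed:
the replication-only pool decides replication pass/fail (pooled p < 0.05
and sign concordant with discovery), and the overall pool (discovery + all
replication pairings — four studies under the default design) is the
reported meta-analysis. Heterogeneity uses I² = max(0, (Q−df)/Q); strictly
above 50% switches pooling to DerSimonian–Laird random effects,
τ² = max(0, (Q−df)/(Σw − Σw²/Σw)), weights 1/(seᵢ²+τ²). Ties at exactly 50%
stay fixed-effect. When reproducing published rows, study SEs are recovered
from printed CIs as (ln hi − ln lo)/(2·1.959964); the native pipeline
carries SEs directly. No Hartung–Knapp adjustment is applied.

## Colocalization

Per SNP and trait, the Wakefield approximate Bayes factor
log ABF = ½·ln(se²/(se²+W)) + ½·z²·W/(se²+W), with prior effect SD 0.15
(trait-SD units) for the quantitative trait and 0.2 (log-odds) for the
binary trait — the conventional defaults, exposed as configuration. Under
the single-causal-variant assumption the five hypothesis weights are H0 ∝ 1,
H1 ∝ p1·ΣABF1, H2 ∝ p2·ΣABF2, H4 ∝ p12·Σ(ABF1·ABF2), and
H3 ∝ p1p2·(ΣABF1·ΣABF2 − Σ ABF1·ABF2), all accumulated in log space
(log-sum-exp; the H3 difference via log1p of the diagonal/total ratio), so
|z| up to 50 cannot overflow. A one-SNP region has H3 exactly 0. Posteriors
are verified against exhaustive configuration enumeration to 10⁻¹² on small
regions. PPH4 ≥ 0.8 (inclusive) is the stand-alone pass rule.

Known limitation: with two or more shared causal variants in one region the
H3 cross-configurations carry the same ABF magnitude as H4's diagonal and
PPH4 is diluted (observed around 0.7–0.8 on 30-SNP two-causal regions).
This is inherent to the single-causal-variant model, not a numerical
artifact; SuSiE-style multi-signal colocalization is out of scope.

## Evidence grading

Grading consumes the pipeline's own outputs plus three externally computed
flags (genome-wide Bayesian pleiotropy check, tissue-level TWAS validation,
drug-target PPI link) ingested from a TSV. Rules, in order: no replication
data → Excluded; pleiotropy check failed → Tier 4 (the check failing means
the association pattern is consistent with incoherent pleiotropy, which
trumps other support); PPH4 > 0.8 and replication and TWAS → Tier 1;
drug-target link plus replication or TWAS → Tier 2; any single line of
support → Tier 3; else Tier 4. Two thresholds deliberately coexist: the
stand-alone colocalization pass is inclusive (PPH4 ≥ 0.8) while the bar
inside the tier rules is strict (PPH4 > 0.8); both are configuration values.
The grade is monotone: turning any single flag from fail to pass never
worsens the tier (property-tested). One published evidence row (TNFSF8–BCC)
is labelled Tier 2 despite failing both replication and TWAS, contradicting
the published tier definitions; the literal rules are implemented (giving
Tier 3) and the discrepancy is asserted as a documented known-difference
test rather than reverse-engineered.

## Synthetic data generator

Summary statistics are simulated directly — no individual-level genotypes —
which suffices to exercise every downstream stage at desk scale. Per region:
effect-allele frequencies f ~ U(0.05, 0.95); block-diagonal exchangeable LD
(correlation ρ = 0.8 within blocks of 10, zero across; r² = ρ² = 0.64);
marginal effect means are the LD projection R·b of joint effects; observed
betas are one multivariate-normal draw with covariance D·R·D, D = diag(SE).
Exposure SE = 1/√(2f(1−f)·n); the binary outcome uses the effective sample
size n_eff = 4/(1/cases + 1/controls) — the standard approximation for
heavily imbalanced case–control GWAS. Default cohort shapes: discovery
exposure n = 7213, replication exposure n = 35,559, outcomes n = 275,911
with 16,328 cases (n_eff ≈ 61,450). Defaults: 55 proteins (5 causal),
100 SNPs per region, θ = 0.3 log-odds per SD, per-allele pQTL effect 0.15 SD
(or an exact target z when a test plants a specified instrument strength).
Shared-causal regions give the outcome joint effects θ·b at the exposure's
causal variants; distinct-causal regions place the outcome's causal variants
in LD blocks free of exposure signal. An optional pleiotropy fraction adds
independent outcome effects to a random subset of SNPs.

What the generator does *not* emulate: realistic allele-frequency spectra,
imputation noise, population structure or stratification, cross-region LD,
winner's-curse in the published pQTL panels, or sample overlap between
exposure and outcome. Passing calibration tests therefore demonstrates the
estimators' correctness under the stated model, not robustness to those
real-data pathologies.

Measured calibration under the defaults (1000 replicates unless noted):
type-I error 4–6% at nominal 5%; mean recovered θ̂ within ±0.005 of the
planted 0.3 (the residual ~2% attenuation is winner's-curse selection on the
instrument, visible because instruments are selected at p < 5×10⁻⁸ from the
same panel that supplies β_exp); second-order CI coverage 93–95%; Steiger
direction 100% correct; shared-causal PPH4 ≥ 0.8 in ~95–97% of 200
replicates and distinct-causal PPH3 dominant in ~98%.

## Harmonization policy

Matching alleles are kept; swapped alleles flip the outcome beta and
complement the outcome EAF; anything else is an allele mismatch (no silent
strand-complement rescue for non-palindromic variants — a C/T outcome row
against an A/G exposure row is dropped, not flipped, since it is as likely a
genotyping-reference difference as a strand difference). Palindromic (A/T,
C/G) variants are dropped when either trait's EAF is missing or within
0.5 ± 0.08; outside that window strand is inferred from frequency
concordance. The window and the frequency-alignment rule follow common
two-sample-MR practice; they are configuration values because no single
convention is authoritative. Harmonization is idempotent and invariant to
relabelling the outcome file's alleles with matching beta/EAF flips
(property-tested).

## Problem sizes

Defaults were chosen so a full synthetic study (simulate, discover,
replicate, colocalize, grade) finishes in seconds on one CPU and the entire
validation suite — including the 1000-replicate calibration loops and
200-replicate colocalization sweeps — in about a minute: regions of 30 SNPs
(blocks of 5) for estimator calibration, 500 SNPs (blocks of 10) for
colocalization discrimination, 55-protein studies for the end-to-end
drivers. These sizes leave every statistical conclusion at comfortable
Monte-Carlo precision (binomial SE ≈ 0.7 percentage points at 1000
replicates for a 5% rate).
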