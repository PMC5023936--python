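# Methods

## Scientific setting

`vtescan` models a two-stage rare-variant study design for venous
thromboembolism (VTE): first, discovery of a candidate thrombophilia
variant in a small exome-sequenced family of affected relatives; second,
population-level assessment of that variant by exact association
statistics against a case–control cohort and a larger background
population. The package ships a synthetic-data module that emulates
every input, so the full pipeline runs and is tested without any
external download.

## Family discovery cascade

The discovery model assumes a dominant-acting variant shared
identical-by-descent among the affected members, so each member carries
exactly one copy. The cascade applies five per-variant predicates in
order:

1. **Shared heterozygosity** — alternate-allele dosage exactly 1 in
   every affected member. A missing genotype in any member excludes the
   variant, because sharing cannot be established.
2. **Candidate genes** — position inside one of the configured
   coagulation-pathway regions (default panel: F5, PROC [Protein C],
   PROS1 [Protein S], F2 [prothrombin], SERPINC1 [antithrombin III],
   CBS, C4BPA, C4BPB). Intervals use BED half-open semantics and exact
   chromosome-label matching; `chr`-prefix normalization is an explicit
   reader option.
3. **Nonsynonymous consequence** — the change must alter the encoded
   amino acid. Unannotated variants are excluded with a warning.
4. **Population rarity** — reference minor allele frequency strictly
   below a threshold (default 0.02, i.e. double the conventional 1%
   rare-variant cutoff, so borderline-rare variants are retained) in a
   named reference population. A variant *absent* from the reference is
   retained and flagged rather than dropped: absence from a population
   panel is evidence of rarity, not of frequency.
5. **Deleteriousness** — SIFT and PolyPhen categories are attached to
   the survivors. By default this stage only annotates, because
   predictor categories are graded evidence rather than a crisp
   inclusion rule; an optional strict mode removes variants called
   tolerated/benign by *both* predictors, keeping variants with no
   predictions (no evidence either way).

Stages are pure per-variant predicates, so the final candidate set is
independent of stage order; the per-stage survivor counts recorded in
the `FilterTrace` are of course order-dependent. The suite verifies
commutativity over all 120 stage orderings on random fixtures and
equivalence with a single-pass brute-force predicate.

Out of scope by design: recessive/compound-heterozygote models, linkage
analysis, and contrasts against unaffected relatives.

## Exact association statistics

All association inference conditions on both margins of the
allele-count table

|          | minor | major |
|----------|-------|-------|
| cases    | a     | b     |
| controls | c     | d     |

under which `a` follows Fisher's noncentral hypergeometric distribution
with odds-ratio parameter ψ. Allele counts treat each heterozygote as
one minor allele out of two; missing genotypes drop out of both
numerator and denominator.

Everything is computed by direct enumeration of the finite support in
log space (`scipy.special.gammaln`/`logsumexp`), safe for table totals
up to 10⁶. Three standard two-sided constructions are implemented:

- **minlike** (the classical two-sided Fisher test): sum of
  probabilities of outcomes no more likely than the one observed, with
  the conventional 1 + 1e−7 relative tie tolerance;
- **central**: 2·min(lower tail, upper tail), capped at 1;
- **blaker**: sum of probabilities of outcomes whose smaller-tail
  acceptability does not exceed the observed one.

Point estimates: the sample odds ratio ad/bc (∞ or 0 with a flag on a
zero cell; no continuity correction) and the conditional MLE, the root
of E_ψ[a | margins] = a found by bisection on log ψ to 1e−10.
Confidence intervals invert the matching two-sided test over ψ
(bisection to 1e−8 on log ψ); observed counts at the support boundary
give 0 or ∞ endpoints. For minlike/blaker the p-value curve is treated
as unimodal in ψ, with the search pivoted on a point where p ≥ α (found
by walking toward the boundary when the CMLE is 0 or ∞); the curve has
roundoff-scale ripples and tie-driven jumps, so interval endpoints are
where p *crosses* α, which the tests verify by bracketing.

**Default pairing.** The package defaults to the minlike p-value *and*
the minlike-inversion CI. On the motivating study's tables this pairing
reproduces the published values exactly — (15, 597, 4, 736): p = 0.0041,
OR = 4.62, 95% CI 1.51–15.20; (15, 597, 48, 4358): p = 0.010, OR = 2.28,
95% CI 1.26–4.10 — whereas the central (Cornfield-type) interval for the
first table is (1.46, 19.22). All three methods are exposed and labelled
in every result.

**A note on orderings.** The often-quoted ordering
p_minlike ≤ p_central is *not* universal: when the observed cell is the
conditional mode, p_minlike = 1 by construction while the doubled tail
can fall just below 1, and off-mode counterexamples also exist (e.g.
table (4, 17, 0, 8): minlike 0.552 > central 0.504). Empirically about
2% of uniformly random small tables violate it. The ordering that does
hold universally, and that the suite asserts, is Blaker ≤ central.

Supporting statistics:

- **Exact binomial test** (sex distribution among case carriers):
  minimum-likelihood two-sided, same tie tolerance.
- **LD r²**: squared Pearson correlation of alternate-allele dosages
  over pairwise-complete subjects (the composite, genotype-based
  estimator). This is deterministic for unphased data; it is not the
  EM-phased haplotype r² and the two can diverge when phase is
  ambiguous. Monomorphic input is an error (r² undefined).
- **Logistic confounding model**: maximum likelihood by iteratively
  reweighted least squares; convergence at max |score| < 1e−8 or 100
  iterations; per-coefficient Wald z tests; rows with missing predictors
  excluded and counted; runaway coefficients (|β| > 30 on the logit
  scale, or a singular weighted normal matrix) are reported as
  separation, with no estimates.
- **Covariate comparisons**: Welch (unequal-variance) t-test for
  continuous covariates — chosen over the pooled test because arm
  variances are not assumed equal — and the exact minlike test on the
  2×2 level table for binary categorical covariates. Covariates constant
  in both arms are skipped with a note.
- **Subcohort homogeneity**: for each arm, all pairwise exact tests of
  the minor/major allele split between subcohorts.
- **Multiple testing**: none anywhere; the pipeline reports
  single-variant, unadjusted results.

## Synthetic-data generator

The generator encodes the study conditions as defaults: 3 affected
family members; a 306-case / 370-control cohort with expected
heterozygote-carrier counts 15 and 4 (carrier frequencies 15/306 and
4/370); a background population of 2,203 subjects with 48 carriers
(reference MAF 1.09%, which is also the planted variant's reference AF);
case/control subcohort splits of 173/133 and 134/236 between a
"warfarin" and a "biovu" subcohort.

**Family exomes.** One causal variant is planted in the PROS1 region —
heterozygous in every member, nonsynonymous, reference AF 0.0109,
SIFT "damaging" / PolyPhen "possibly damaging" — among `n_decoy_variants`
decoys (default 60; the raw input size of a real candidate-panel filter
is not pinned down by the study design, so this is an order-of-magnitude
choice). Every decoy is engineered to fail at least one stage, with at
least one decoy per failure class (not shared-heterozygous; outside the
panel; synonymous; reference AF ≥ 0.02), so each stage removes
something and the cascade provably returns exactly the planted variant.
Decoy positions are drawn uniformly within the synthetic gene regions
(collisions redrawn); panel coordinates are round-number stand-ins on
the genes' real chromosomes, not real gene boundaries.

**Cohorts.** Carriers are simulated as heterozygotes,
Bernoulli(carrier frequency) per subject, because the emulated reference
counts are carrier counts; a `hwe_genotypes` flag switches to
Hardy–Weinberg dosage sampling, Binomial(2, q) with q = carrier_freq/2.
Covariates: sex ~ Bernoulli(0.5); age, height, weight ~ normal with
per-arm means (defaults: cases 48 y / 167 cm / 95 kg, controls 64 y /
170 cm / 86 kg, SDs 12 / 9 / 20) chosen so the confounded regime the
covariate checks are meant to exercise — older controls, shorter and
heavier cases — is present by default; set the arm means equal for an
unconfounded regime.

All randomness flows through one `numpy.random.Generator` seeded from
the config (the cohort stream is offset by +1 from the family stream);
identical configs give byte-identical artifacts.

**What the generator does not emulate**, and therefore what passing
tests do not show about real data: read-level sequencing error, genotype
uncertainty, LD structure between variants, population stratification,
relatedness beyond the three shared-heterozygote members, missing
covariates, and realistic covariate distributions. The planted-recovery
property validates the cascade's logic, not its yield on real exomes.

## Numerical and design choices

- Internal variant model is bi-allelic; multi-allelic VCF sites are
  split at read time into one record per alternate allele with
  per-allele dosage recoding, because every downstream operation is
  per-allele. Phased separators are treated as unphased; any missing
  allele makes the call missing; non-diploid genotypes are a hard error
  naming site and sample.
- Rarity threshold comparison is strict (< 0.02); an AF exactly at the
  threshold is excluded.
- Problem sizes used by the shipped checks: the enumeration sweep covers
  every 2×2 table with total ≤ 60 and every binomial outcome with
  n ≤ 60 over a five-point p₀ grid; duality runs on 1,000 random small
  tables; the null-calibration check uses 2,000 replicate cohorts at the
  background carrier frequency in both arms; logistic recovery uses 200
  replicates at n = 5,000.
- Reports are JSON plus a rendered text summary; the single timestamp
  is isolated in one provenance field so identical configs produce
  otherwise byte-identical reports.

## Known limitations

- The exact machinery enumerates the conditional support; totals above
  10⁶ are refused rather than approximated (no mid-p, no asymptotics).
- Minlike/blaker interval inversion assumes a unimodal p-value curve;
  pathological multimodality beyond tie-jumps would be silently
  bracketed.
- The logistic model does not implement Firth correction, so separated
  data yield flags rather than estimates.
- Categorical covariate comparisons support binary levels only.
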