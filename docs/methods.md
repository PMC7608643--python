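# Methods

## Data model

The unit of analysis is a per-variant summary record in the gnomAD v2
export convention: for each ancestry group, an alt allele count `AC`, a
total called-allele count `AN`, a homozygous-alternate individual count
`nhomalt`, and sex-split allele counts `AC_*_male` / `AC_*_female`
(optionally `nhomalt_*_male/female`). Functional context rides along as a
consequence class, a protein change on a named isoform, SIFT and
PolyPhen-2 verdicts, a ClinVar assertion, and a QC flag. Two dialects —
VCF 4.2 (read via pysam, multi-allelic sites decomposed per alt with the
site-level `AN` duplicated) and a flat TSV with the same names as columns —
load to identical record lists; loading validates
`0 ≤ 2·nhomalt ≤ AC ≤ AN ≤ 2N` per group and the sex-split sum, and either
raises or returns records plus explicit rejections, so no row is silently
dropped. Missing annotations map to explicit `missing`/`absent` values,
never to a default verdict.

The population panel lists each group's individual count and sex split;
total alleles per group are 2N (autosomal locus). A designated catch-all
group ("other"-type ancestry mixtures) is retained in files but excluded
from every analysis. The packaged default panel carries six analysed
groups totalling 122,678 exomes (67,709 / 17,296 / 15,308 / 9,197 / 8,128 /
5,040) plus a 3,070-individual catch-all; the catch-all's unpublished sex
split is assumed even, which only affects file-level bookkeeping, never an
analysed statistic.

## Pathogenicity classification

A fixed-order cascade assigns exactly one status per variant:

1. QC-flagged → excluded.
2. Not rare → excluded. Rarity is a *strict* per-group criterion: alt
   allele frequency `AC/AN < 1%` in every analysed group (a tie at exactly
   1% fails). The frequency is the alt-allele frequency without folding to
   the minor allele; below 1% the two coincide. Groups with `AN = 0`
   contribute frequency 0 and are flagged.
3. Protein consequence not on the canonical isoform → excluded.
4. Carriers only in the excluded catch-all group → excluded.
5. Synonymous → non-pathogenic; in-frame indels and other unscored classes
   (start/stop loss, `other`) → excluded.
6. Loss-of-function classes (stop gained, splice acceptor/donor,
   frameshift) → pathogenic.
7. Missense: ClinVar pathogenic/likely-pathogenic → pathogenic (the
   override also rescues variants benign in silico; `conflicting` never
   rescues); otherwise the in-silico rule decides. The combination rule is
   a policy knob (`both_damaging` default: SIFT deleterious AND PolyPhen-2
   probably/possibly damaging; `either_damaging`, `sift_only`,
   `polyphen_only` available) because concordance conventions differ
   between studies. A missense variant with no verdicts at all is
   non-pathogenic with an explicit `unscorable` reason, never an error.

Every call carries machine-readable reason codes. Classification is a pure
per-variant function — order-independent, idempotent, and monotone in the
rarity threshold (tightening it never adds pathogenic calls). `start_lost`
sits in the excluded classes by default but can be moved into the LOF set
by configuration.

## Carrier prevalence

Carrier counts are allele-derived because aggregate databases do not expose
genotypes: per variant and group, homozygous carriers = `nhomalt` and
heterozygous carriers = `AC − 2·nhomalt`; a compound heterozygote is
therefore counted once per variant. The carrier table satisfies, per row,
`mutated_alleles = het + 2·hom`, and the global row is the column-sum over
analysed groups. Frequencies are stored as full-precision fractions;
percentage rounding (2 dp) is confined to the report layer.

Homozygote sex attribution uses the dedicated `nhomalt_*_male/female`
fields when present; otherwise homozygotes are assigned to the sex whose
allele count can absorb them, male-first on ties. This convention is
documented because it is not derivable from the published tables alone.

A variant is *ethnic-specific* when its `AC` is nonzero in exactly one
analysed group; otherwise it is overlapping, and a variant unobserved in
all analysed groups lands in a separate bin rather than vanishing. The
fold difference between the highest- and lowest-prevalence groups is
reported twice: on display-rounded percentages (the convention under which
the published 5.8-fold figure arises from 3.26/0.56) and at full precision
(5.87).

Heterogeneity is tested with Pearson's chi-square on (mutated,
non-mutated) × groups tables, and carrier-vs-noncarrier × sex 2×2 tables
globally and per group, without continuity correction (exposed as a flag).
The p-value is the upper-tail chi-square probability, the standard
two-sided test for this statistic. Expected cells below 5 set a warning
flag; a zero marginal is an error for a direct call and a flagged skip
inside the per-group sweep; a p-value underflowing double precision is
displayed as `< 2.2e-308`, never as 0. The statistic is computed by
`scipy.stats.chi2_contingency`; the test suite checks it against an
independent brute-force marginal/expected summation at 1e-9 relative error
on 1,000 random tables.

## Domain burden

Only missense mutations are placed on the protein: truncating alleles
affect every downstream domain and are reported as a count instead.
Domains are non-overlapping, 1-based, inclusive intervals; residues between
domains fall into an implicit linker bin, so the per-domain mutation counts
partition the placed mutations. Per domain the module reports distinct
mutations, distinct mutated residues (`n_positions ≤ n_mutations` since
several derived alleles can hit one residue), carrier-individuals
(het + hom per variant), `pct_mutant_aa = 100·n_positions/length` and
`pct_individuals = 100·n_individuals/length`. The individuals percentage is
deliberately normalised by domain length, not by carriers, and can exceed
100% — a short domain carried by many individuals is the signal the
statistic is designed to surface. A sterol-sensing-domain aggregate sums
the flagged member domains.

The packaged NPC1 model has 27 domains on a 1,278-residue protein: 13
transmembrane segments (TD1–TD13) interleaved with 14 luminal/cytoplasmic
loops labelled alphabetically in sequence order (LDA, CDB, LDC, …, CDN),
with TD3–TD7 forming the sterol-sensing domain. Boundary coordinates are
approximate — they follow the protein's membrane topology, with the lengths
that the burden statistics pin down exactly (CDL 29, CDN 30, CDJ 7, TD4 and
TD7 20 residues) fixed, and are marked as such in the file. Domain models
are inputs, not constants: any non-overlapping interval table loads.

## Constraint metrics

Per mutation class (synonymous, missense, LOF) with observed count O and
expected count E > 0 (expected counts are inputs from a sequence-context
mutation model, not recomputed here):

* **o/e** = O/E with an exact Poisson-rate 90% CI: gamma quantiles
  `[Γ(O).ppf(0.05), Γ(O+1).ppf(0.95)]/E`, lower bound 0 at O = 0. The CI
  width shrinks as counts grow at fixed o/e.
* **Z** = (E − O)/√E, positive for depletion. Published per-gene Z values
  are conventionally rescaled by per-class constants fitted on a whole-exome
  corpus; those constants are corpus-specific and not recoverable from a
  single gene, so the default divisor is 1 (raw Z) and per-class divisors
  are accepted as configuration.
* **pLI** comes from the three-class Poisson mixture
  P(O | k) = Poisson(O; f_k·E) with depletion factors
  f = (1.0, 0.463, 0.089) for the null, recessive, and haploinsufficient
  classes. With one gene the posteriors are a single Bayes update under
  fixed (default uniform) priors; with a gene table the mixture weights are
  estimated by EM (E-step: posterior responsibilities; M-step: mean
  responsibilities), in log space with log-sum-exp throughout. Convergence
  is declared when the log-likelihood improves by less than `tol`
  (default 1e-8, relative); the trace is returned and is non-decreasing
  every iteration; non-convergence at `max_iter` returns the best iterate
  flagged. Factor re-estimation is out of scope.

Labels: `lof_tolerant` (pLI ≤ 0.1), `lof_intolerant` (pLI ≥ 0.9),
synonymous/missense significance at |Z| > 3.71 / 3.09 with the sign giving
direction, and `strong_lof_intolerance` when the LOF o/e CI upper bound is
below 0.35.

For the packaged NPC1 counts (O/E = 314/290.7, 637/719.4, 21/62.2) this
yields o/e 1.08 (0.98–1.19), 0.89 (0.83–0.95), 0.34 (0.23–0.49), raw Z
−1.37 and 3.07, and pLI ≈ 1e-5 → 0.00: the LOF depletion is real but far
better explained by the recessive class than by haploinsufficiency. The
pLI is insensitive to the prior at these counts (the recessive class is
favoured by a likelihood ratio near e^11).

## Synthetic cohorts

The generator emulates the structure the pipeline consumes, not the
biology of any particular gene. Defaults are the study conditions: the
six-group panel above; per-class variant counts matching the published
census on the LOF side (34 frameshift, 6+6 splice, 13 stop gained) with
647 missense of which a fraction 355/647 is truth-pathogenic, plus 150
synonymous and 5 in-frame indels; 82% of variants specific to a single
group (chosen with probability proportional to group size, the remainder
spread over 2–3 groups); rare alt-copy totals drawn zipf-like
(exponent 1.5) on {1..30}, which keeps every rare variant below 1% in
every group; 10% of benign missense made common (1.5–5% frequency) as
negatives for the rarity filter; homozygotes realised per group as
Binomial(N, q²) under Hardy–Weinberg (clipped so 2·nhomalt ≤ AC); sex
splits binomial with the group's male fraction; a ClinVar-rescue rate of
2/355 reproducing the two in-silico-benign/ClinVar-pathogenic missense
variants; and 1%/1%/0.6% rates of QC-flagged, non-canonical-isoform, and
catch-all-only variants to exercise each exclusion path. Annotation noise
(verdicts contradicting truth) defaults to 0 so classification recovers the
truth labels exactly; raising it degrades recovery, which the tests use as
a negative control.

One `SeedSequence(seed)` is spawned per variant index, so a cohort is
deterministic under its seed and extending it preserves earlier variants.
The generator does not attempt linkage, realistic site-frequency spectra
beyond the stated distribution, sequence context, or compound-genotype
structure — so passing tests demonstrate the pipeline's arithmetic and
bookkeeping on realistic table shapes, not calibration against any real
population.

The constraint-gene generator draws each gene's class from the mixture
priors, lognormal expected counts (default meanlog 3, sdlog 1; mean E ≈ 33),
and observed counts Poisson(f_class·E); the EM recovers priors
(0.5, 0.3, 0.2) on 2,000 genes to within ±0.03 across seeds, with
class-argmax accuracy above 90% for genes with E ≥ 20.

## Problem sizes and determinism

The default test suite simulates cohorts of ~60–900 variants and EM fits of
up to 2,000 genes ×5 seeds, and runs the 1,000-table chi-square oracle and
1,000-replicate type-I-error checks; the whole suite completes in seconds.
Property tests (hypothesis) run derandomised. The CLI's `run-all` writes a
manifest with SHA-256 digests of all inputs and outputs; reruns with the
same seed and inputs are byte-identical, with display rounding (2 dp
percentages, 1 dp fold changes, 2 dp o/e and pLI) applied only in the
report layer.

## Known limitations

* Carrier counts are allele-derived; compound heterozygotes inflate
  heterozygous-carrier counts and cannot be resolved without genotypes.
* The per-group sex splits of homozygotes rely on an attribution convention
  when the dedicated fields are absent.
* Published rescaled Z values and grid-search o/e CIs from whole-exome
  pipelines can differ from the raw Z and exact gamma CI in the last
  rounded digit; they are configuration (divisors) or documented
  differences, not targets.
* The packaged NPC1 domain boundaries are topology-based approximations;
  analyses sensitive to exact boundaries should supply a curated model.
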