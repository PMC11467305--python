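# Methods

## Scope and model

`pedscreen` implements the computational arm of a dominant-pedigree
germline study: set-based variant filtering over a genotyped family,
recurrence screening of structural-variant (SV) events, a validation-cohort
carrier statistic, expression/enrichment analysis of an engineered
candidate, and the quantitative models for the downstream functional assays
(limiting dilution, qPCR, xenograft volume). The filtering stages are
deterministic set intersections, not hypothesis tests; no multiple-testing
correction applies to them, and this is deliberate — the output is a
shortlist for orthogonal validation (Sanger sequencing, a cohort screen),
not a calibrated discovery set.

## SNV cascade

A variant is described by population allele frequencies (any subset of
named databases may be present), categorical SIFT/PolyPhen-2 calls, and a
diploid alt-allele count per family member. The three rules:

* **Frequency** — every *present* AF must be strictly `< max_af`
  (default 0.01). A variant absent from all consulted databases is treated
  as novel and passes by default. Absence of an annotation is evidence of
  rarity, not commonness; it is never coerced to AF = 0, and unannotated
  variants are counted in the log.
* **Segregation** — carriers are members with alt count ≥ 1 (dominant
  model; homozygous alt counts as a carrier). Defaults: ≥ 5 carriers among
  MPLC members, ≥ 8 among nodule members, 0 among unaffected; UNKNOWN-class
  members are ignored. The 8-of-9 nodule default is an incomplete-penetrance
  tolerance, configurable rather than hard-coded. Missing genotypes are a
  distinct state: by default they count as non-carrier (conservative for a
  presence requirement, with a warning); a per-variant member-exclusion
  policy is available.
* **Deleteriousness** — default `either`: SIFT deleterious or PolyPhen-2 in
  {probably, possibly} damaging. Variants with neither call are removed and
  logged. Whether the predictors should be combined conjunctively is a
  genuine design choice; `both`, `sift_only`, `polyphen_only` are provided.

The three predicates are pure, so the cascade commutes and is monotone in
each rule (tests assert both). The cohort statistic is `k/n` with an exact
Clopper–Pearson interval computed from beta quantiles
(`B(α/2; k, n−k+1)`, `B(1−α/2; k+1, n−k)`), with percentage rendering by
decimal half-up rounding to one place.

## SV recurrence screen

`rec` of an event in a phenotype group is the number of group members whose
presence flag is set. An event passes when every required group meets its
threshold (≥; defaults 5 cancer / 9 nodule) and — by default — no excluded
(control) member carries it. Requiring *absence* in the control, rather
than merely ignoring control carriers, is the stricter of two defensible
readings of "excluding the control group"; `require_absent_in_excluded=False`
gives the other. Event identity is taken from the input table's ids;
cross-caller breakpoint merging is out of scope. Retained events are
region-flagged (exonic / non-exonic / unknown) rather than filtered, so an
exonic hit is surfaced, not silently dropped.

## Expression and enrichment

Differential expression is threshold-only: `log2((mean_b + c)/(mean_a + c))`
on linear-scale values with pseudocount `c` (default 1.0; the log of the
ratio, not a difference of logs, so representable fold changes hit the
boundary exactly), and `is_de ⇔ |log2FC| > 1` with a strict inequality.
There is no dispersion-based test because the emulated design has single
profiles per condition; this reproduces that design faithfully and is not a
recommendation. The matrix is assumed pre-normalized; no size-factor or TPM
normalization is applied.

Over-representation of curated gene sets in a DE list is the upper
hypergeometric tail with the measured genes as universe. GSEA uses the
weighted KS running sum (hit increment `|s|^p` normalized over in-set mass,
default `p = 1`; miss decrement `1/(N−|S|)`), ES the signed maximum
deviation, ties in the ranking broken by gene label for determinism. The
permutation null draws random same-size gene sets without replacement
(gene-label permutation — phenotype permutation is impossible with one
profile per condition, a documented deviation from sample-permuting GSEA
implementations). The one-sided p uses the add-one correction
`(1 + #{null ≥ obs})/(n_perm + 1)` for positive ES, mirrored for negative,
so p ∈ (0, 1]; because the null of the signed extreme is symmetric, the
mirrored one-sided p lives on roughly (0, ½] and `2p` is the uniform
two-sided quantity (this is what the null-calibration test checks).
Default significance: ES > 0.4 and p < 0.05 at 1000 permutations.

## Assay models

**Limiting dilution.** Single-hit model `P(pos|d) = 1 − e^{−fd}`, binomial
likelihood across doses. The MLE solves the score equation by Brent
bracketing (the likelihood is concave in `f`), which reproduces the
single-dose closed form `f = −ln(1 − k/n)/d` to better than 1e−10 relative.
The default 95% interval inverts the likelihood-ratio statistic at
χ²₁ = 3.84 on log f (tolerance 1e−8); a Wald interval on log f is optional.
Boundary tables do not fail: all-negative gives `f̂ = 0` with a one-sided
upper limit (`f_up = 1.92/Σ n_i d_i`, analytic), all-positive gives an
infinite-MLE flag with a one-sided lower limit. The two-group comparison is
the LR test of shared-vs-separate `f`, referred to χ²₁ and flagged
approximate when a group fit is at a boundary. The model is also a binomial
GLM with complementary log-log link and `log d` offset; the test suite uses
statsmodels' GLM as an independent oracle of the MLE.

**qPCR.** Technical replicates sharing a sample label are averaged (mean
Ct) before `ΔCt = Ct_target − Ct_reference`; `ΔΔCt` is the condition mean
ΔCt minus the control-condition mean; fold change `2^−ΔΔCt`, control ≡ 1.

**Tumor volume.** `length × width²/2`; negative inputs are errors, width >
length only warns (caliper-swap tolerance).

## Synthetic data

The generators define the study conditions the tests run under.

* `simulate_pedigree` uses a two-generation topology (carrier founder ×
  non-carrier spouse, remaining members their children). Planted variants
  are heterozygous in the founder and transmitted with probability ½ per
  child; background variants are Hardy–Weinberg draws at a Beta(0.3, 3)
  allele frequency (a rare-skewed site-frequency spectrum). Phenotypes must
  honor both an exact class-count design and a penetrance model; members
  are therefore drawn into classes sequentially, without replacement, with
  weights equal to their penetrance probability given carrier status. With
  a 0/1 penetrance this reduces to deterministic labelling; infeasible
  combinations raise a configuration error. Default penetrance: carrier →
  0.35 MPLC / 0.55 nodule / 0.10 unaffected; non-carrier → 0.95 unaffected,
  matching a 13-of-15-carrier, one-non-carrier-nodule pattern qualitatively.
* `build_paper_fixture` is deterministic (fixed internal seed): 15 members
  (5 MPLC / 9 nodule / 1 unaffected; the single non-carrier nodule member
  is `NODULE_9`, since the source pedigree's identity for this member is
  ambiguous), three heterozygous candidate SNVs at chr17 40/41/42 Mb
  carried by exactly the 13 carriers, 210 background SNVs each violating at
  least one cascade rule by construction, and an SV table with two fully
  group-recurrent non-exonic events plus 40 background events that are
  under-recurrent or control-positive. Exact topology beyond the class
  structure is a stand-in: segregation logic depends only on the
  genotype-by-phenotype pattern.
* Expression is simulated on the log2 scale (baseline U(3,10) + condition
  shifts + N(0, σ), default σ = 0.25) and returned linear; dilution
  outcomes are exact draws from the single-hit model.

What the synthetic data does **not** emulate: linkage disequilibrium,
recombination, realistic site-frequency spectra beyond a Beta shape,
sequencing/genotyping error, annotation error, count-distribution noise
(negative binomial) in expression, or caller-dependent SV breakpoint
uncertainty. Passing tests therefore demonstrate correctness of the
*arithmetic and decision rules* under the assumed models, not robustness of
the workflow to real-data artifacts.

## Numerical and design notes

* Coordinates are 1-based inclusive (VCF convention) everywhere in memory.
* Multiallelic VCF records are split per alt allele; the genotype is the
  count of that allele.
* All randomness flows from per-call `numpy` Generators; the pipeline's one
  seed fans out to per-stage child seeds via `SeedSequence` spawn keys, so
  toggling a stage never perturbs another stage's draws.
* Report rows are ordered by (chrom, pos, ref, alt) with a stable sort;
  repeated runs are byte-identical.
* Test problem sizes (500 dilution replicates for interval coverage, 200
  permutation repetitions for null uniformity, 1000 simulated offspring for
  transmission) were chosen to give ~3-sigma resolution on the quantities
  checked while keeping the suite quick to run locally.

## Known limitations

* The DE caller has no variance model; with replicates available, a
  dispersion-based method (DESeq2/limma) should replace it.
* The gene-label permutation null ignores gene-gene correlation and is
  anti-conservative on correlated sets.
* The LR chi-square reference for the two-group dilution comparison is
  asymptotic and approximate near boundaries (flagged in the result).
* The cascade's carrier definition ignores phase and de novo status;
  linkage (LOD) analysis is out of scope.
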