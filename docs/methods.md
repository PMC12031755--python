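# Methods

This note documents the statistical model behind `cfhl`, the default
parameters and their rationale, the design decisions that resolve
ambiguities in the workflow, and the limitations of the synthetic
generator. Nothing here claims an empirical result that is not computed by
the test suite or `scripts/acceptance.py`.

## 1. Problem setting and model assumptions

Plasma cfDNA of a lymphoma patient is modelled as a mixture of
tumor-derived fragments (fraction `tf`, the tumor fraction) and normal
fragments (`1 - tf`). Under this admixture:

- a heterozygous clonal somatic variant has expected
  `VAF ≈ tf · m / (tf · c_t + (1 - tf) · 2)` for multiplicity `m` and
  tumor copy number `c_t`; for the diploid, single-copy case used
  throughout, `VAF ≈ tf / 2` times the clonal fraction;
- a genomic bin with integer tumor copy number `cn` has expected log2
  read-depth ratio `log2((tf·cn + (1-tf)·2) / 2)` against a diploid
  reference (`cn = 2` ⇒ 0 for every `tf`; `cn = 0` at `tf = 1` ⇒ −∞).

No matched tumor or germline sample exists, so somatic status must be
inferred from plasma alone (the "tumor-naive" setting). Germline SNPs
(VAF ≈ 0.5 or 1.0), sequencing artifacts and clustered-call redundancy are
the main error sources the filter cascade targets.

## 2. Filter cascade semantics

The cascade is defined in `cfhl.variants`; the README lists the rules.
Decisions that fix otherwise ambiguous semantics:

- **Strict inequalities.** Every threshold is exclusive: depth > 100,
  VAF > 0.01, mutant reads > 7, base quality > 25, population allele
  frequency removal at > 0.001, high-VAF flag at > 0.20, follow-up cutoff
  > 0.004. A variant exactly at a cutoff fails.
- **Consensus record.** The merged VAF is the median across supporting
  callers; depth, mutant depth and base quality come from the supporting
  record with the greatest read depth (the deepest evidence for the call).
- **Rule order and audit.** Rules apply in the fixed order
  `read_depth, vaf, alt_depth, base_quality, panel_of_normals,
  mnv_overlap, functional_effect, population_af,
  high_vaf_in_population_db, indel_length, indel_gc, cosmic_recurrence`.
  Every input locus leaves the cascade labelled PASS or with the *first*
  failing rule plus the trace of rules evaluated, so the per-rule removal
  counts in the audit table sum to the number of removed loci.
- **Unlisted ≠ zero.** A missing population frequency (NaN) means "not
  listed": it never triggers the > 0.001 removal, and it never triggers
  the high-VAF rule. A listed frequency of exactly 0 also does not
  trigger the high-VAF rule (only *positive* listings count).
- **MNV overlap.** An SNV is removed when its position lies inside the
  closed reference span of an MNV reported by a *different* caller of the
  same sample; a caller never invalidates its own calls, and the MNV
  itself is retained (subject to the other rules). Equal-length
  substitutions shorter than 20 bp are MNVs; 20 bp or longer fall under
  the InDel class.
- **Panel of normals.** Exact-allele matching (chrom, pos, ref, alt) on
  the union of loci emitted by any caller in any control sample; a locus
  seen in several controls counts once.
- **InDel length/GC.** The InDel length is `|len(ref) − len(alt)|` and GC
  content is computed over the inserted or deleted bases only.
- **Cohort recurrence.** A variant that survives the per-sample rules in
  the *baseline* samples of two or more distinct patients and is absent
  from COSMIC is removed in every sample. An alternative within-sample
  (multi-allelic position) scope is available via
  `FilterConfig(cosmic_recurrence_scope="within_sample")` but is not the
  default.
- **Tracking mode.** `FilterConfig.followup()` lowers the VAF cutoff to
  0.004 and disregards the functional-effect rule; the first available
  timepoint keeps the 0.01 cutoff but also disregards the effect filter,
  so synonymous anchor variants can be tracked.

## 3. CNV profiling and the ETF estimator

- Bins exceeding ±0.08 in log2 ratio are aberrant (gain above, loss
  below, boundary exclusive); 0.08 is the noise ceiling observed in
  copy-number-neutral control plasma (see `control_threshold`, which
  recomputes it as the max |log2| across controls). Maximal runs of
  same-direction aberrant bins form segments; runs never cross
  chromosomes. FGA = aberrant bins / total bins.
- The estimated tumor fraction inverts the admixture model by grid search
  over `tf ∈ {0, 0.001, …, 1}`: each segment is assigned the integer copy
  number `cn ∈ {0..4}` whose expected log2 is nearest its mean, and the
  bin-weighted squared residual is minimized. `max_cn = 4` reflects the
  low-level gains and losses seen in this disease; it also caps the
  inversion ambiguity.
- **Degeneracy tie-break.** A lone gain with mean `log2(1.5)` is
  explained *exactly* by `cn = 3, tf = 1` and by `cn = 4, tf = 0.5`. A
  complexity penalty `1e-6 · n_bins · (cn − 2)²` prefers copy numbers
  near diploid, resolving the tie toward `cn = 3, tf = 1` while remaining
  numerically negligible (three orders of magnitude below the residual
  scale at the 0.001 grid) whenever the data discriminate at all. A
  multi-segment profile pins `tf` without the penalty.
- **Pre-treatment reconciliation.** When FGA = 0 but the estimator
  reports `tf > 0` in a pre-treatment sample, the ETF is set to 0
  (`etf_adjusted = True`): with no called segment the estimate is noise.
  Follow-up samples are never adjusted, so longitudinal series remain
  comparable.
- Parameter recovery (checked in the acceptance suite): over 100
  synthetic profiles with `tf ∈ [0.05, 0.8]`, one gain and one loss
  segment and bin noise SD 0.02, the median |t̂f − tf| is ≤ 0.03
  (typically ≈ 0.003).

## 4. Quantification and tracking

- Median VAF is defined over PASS **SNVs** only and is `None` (not 0)
  when a sample has no PASS SNV — "no detectable ctDNA" is distinct from
  "ctDNA at VAF 0".
- `hGE/mL = mean VAF × cfDNA concentration (pg/mL) / 3.3`, 3.3 pg being
  the mass of one haploid human genome. Worked identity:
  `0.05 × 6,600 / 3.3 = 100`.
- A tracked variant must be called at the patient's first available
  timepoint and re-occur later with VAF > 0.004. At timepoints where a
  tracked variant is not re-detected it contributes VAF 0 to the mean
  (configurable), so the tracked mean reflects residual-disease decline.
  Missing cfDNA concentrations yield a missing (NaN) hGE/mL with an
  explicit flag, never a silent zero.

## 5. Clusters and statistics

- Cluster label = EBV status × presence of ≥ 1 PASS *SOCS1* variant.
  Samples without PASS variants or with unknown EBV status are
  unassigned. The EBV-positive/SOCS1-wild-type combination is supported
  for robustness but not generated by default (not observed in practice).
- SNV load comparisons between SOCS1-defined clusters exclude *SOCS1*
  variants themselves to avoid circularity; a median-VAF overlap-matching
  step (window = [min of mutated-cluster medians, max of wild-type
  medians], endpoints inclusive) restricts comparisons to samples with
  comparable ctDNA levels.
- Two groups: two-sided Wilcoxon rank-sum (reported statistic is the
  Mann-Whitney U of the first group; exact distribution up to n = 25
  without ties, tie-corrected normal approximation otherwise). Three or
  more groups: Kruskal–Wallis. Correlations: Spearman with pairwise
  deletion of missing values (≥ 3 complete pairs required). α = 0.05, no
  multiplicity correction. Null calibration over 1,000 simulations is
  part of the acceptance suite.

## 6. Reporting conventions

- Percentages are computed against the full cohort n and rounded
  **half-up** to one decimal (`Decimal`, not float/bankers rounding:
  6.25 % → 6.3). Means/SD to one decimal; missing values appear as
  explicit "Missing k (p%)" rows.
- Mutation matrix ordering: genes by descending total SNV count (ties by
  name), samples by EBV status (positive first), then *SOCS1* status
  (mutated first), then descending SNV load, ties by sample id. Samples
  without any PASS variant are excluded. The sort is stable under input
  permutation.

## 7. Synthetic cohort generator

Defaults in `SimulationConfig` *are* the study conditions: 44 patients,
7 plasma controls, 4 callers, three-timepoint follow-up for 8 patients of
whom 2 lack the pre-treatment draw. The generator emulates:

- a miniature genome (3 × 100 Mb chromosomes, 1 Mb bins) carrying an
  18-gene stand-in for a targeted lymphoma panel, with per-gene mutation
  propensities shaped like the frequencies reported for this disease
  (SOCS1 highest);
- three patient clusters with negative-binomial SNV loads (means 8/15/5,
  dispersion 4, proportions 0.2/0.4/0.4) and lognormal tumor fractions
  (medians 0.11/0.17/0.08, σ = 0.45, clipped at 0.8); 9.5 % of patients
  carry no detectable ctDNA. The load means and the no-ctDNA rate were
  calibrated so the cohort median somatic load is ~7 variants per patient
  and ~10 % of samples are unassignable, matching the targeted cohort
  scale; calibration used only generator-level summaries, never test
  outcomes;
- four caller models with logistic detection curves (VAF midpoints
  0.006–0.012), depth ~ Normal(2000, 400) truncated at 150, binomial
  allele counts, a shared germline SNP pool (120 loci, population
  frequencies log-uniform on [0.002, 0.5]) and a recurrent artifact pool
  (50 low-VAF loci) that controls see densely — which is what makes the
  panel of normals work;
- MNV handling: some callers merge adjacent somatic substitutions into
  MNVs while others emit the component SNVs (truth category
  `mnv_decomposition`), generating the MNV-overlap redundancy the cascade
  must remove;
- copy-number truth as 5–20-bin segments with `cn ∈ {0,1,3,4}`, bin noise
  SD 0.02; clinical covariates (cfDNA concentration, sTARC, MTV, stage,
  subtype, relapse) coupled to tumor fraction on the log scale; responders
  decay tumor fraction ×0.1 per timepoint, refractory patients fluctuate
  (lognormal jitter, σ = 0.6).

Generation is byte-identical for a fixed seed and config.

**Not emulated:** read-level data (FASTQ/BAM), alignment and UMI error
profiles, GC/mappability bias (bins arrive pre-corrected), subclonal
structure beyond a single clonal fraction, fragmentomics, real genome
coordinates, and caller-specific error signatures beyond detection
curves. Per-gene VAF has no hotspot structure; positions are uniform
within gene footprints.

## 8. Verification strategy

- Independent brute-force oracles (`tests/oracles.py`) re-derive the full
  cascade as one monolithic predicate and the per-bin segment mask; the
  composed implementation must agree on fuzzed instances.
- `make_rule_violation_cohort` plants exactly k violations per rule, each
  failing its rule and nothing earlier, so per-rule audit counts are
  checked exactly.
- Generator-level invariants: every emitted caller record traces to
  exactly one truth category; callers drop loci but never invent them;
  zero-tumor-fraction patients emit no somatic record.
- Estimator checks: ETF parameter recovery, rank-test type-I error,
  direction recovery of the four cluster contrasts (SNV load, median VAF,
  ETF, FGA higher in the EBV-negative/SOCS1-mutated cluster) at default
  effect sizes.

## 9. Limitations

- The cascade's sensitivity/specificity trade-off is inherited from fixed
  published-style thresholds, not re-optimized; sensitivity collapses by
  design below VAF ≈ 0.01 at baseline (0.004 in follow-up).
- The ETF estimator assumes clonal integer copy numbers ≤ 4 and a shared
  tumor fraction across segments; focal high-level amplification or
  strong subclonality would bias it.
- hGE/mL inherits the assumption that mean tracked VAF scales linearly
  with tumor genome count; it is a relative, not absolute, measure when
  fragment-size selection biases cfDNA extraction.
- Cluster comparisons are unadjusted for multiplicity, matching the
  descriptive analysis style; p-values should be read accordingly.
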