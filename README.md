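# cfhl — cell-free DNA molecular profiling for classic Hodgkin lymphoma

`cfhl` analyzes plasma cell-free DNA (cfDNA) sequencing of classic Hodgkin
lymphoma, where the malignant Hodgkin Reed–Sternberg cells are too rare in
tissue for conventional genotyping and circulating tumor DNA (ctDNA) is the
practical window into the tumor genome. The package implements a complete
tumor-naive workflow:

- **Variant filtering** — somatic single-nucleotide variants (SNVs),
  multi-nucleotide variants (MNVs) and InDels are called from plasma without
  a matched normal. Per-caller VCFs from four independent callers are merged
  into consensus records, and specificity comes from an auditable filter
  cascade: evidence thresholds, a panel of normals (PoN) from control
  plasma, MNV-overlap deduplication, functional-effect and population
  allele-frequency filters, InDel heuristics and a cohort-level recurrence
  filter against COSMIC.
- **CNV profiling** — bin-level log2 read-depth ratios are segmented into
  gains and losses, summarized as the fraction of genome altered (FGA), and
  inverted into an estimated tumor fraction (ETF) with a grid-search
  mixture estimator.
- **Quantification and tracking** — ctDNA burden as the median VAF of PASS
  SNVs and as haploid genome equivalents per mL plasma
  (`hGE/mL = mean VAF × cfDNA pg/mL ÷ 3.3`); longitudinal disease tracking
  with relaxed follow-up calling rules (VAF > 0.004, functional-effect
  filter disregarded).
- **Clustering** — patients are grouped by tumor-cell EBV status and
  *SOCS1* mutation status; clusters are compared with rank-based statistics
  (Wilcoxon rank-sum, Kruskal–Wallis, Spearman).
- **Reporting** — a Table-1 style cohort summary with half-up percentage
  rounding, an oncoplot-style gene × sample mutation matrix with
  reproducible ordering, and per-bin CNV gain/loss frequencies.
- **Synthetic cohorts** — a fully specified generator produces cohorts with
  ground truth (default: 44 patients, 7 controls, 4 callers) for
  validation, calibration and worked examples.

## The filter cascade

Each consensus variant `v` of a sample is kept only if all of the following
hold (strict inequalities throughout), and is otherwise labelled with the
first failing rule:

1. `depth(v) > 100`, `VAF(v) > 0.01`, `altreads(v) > 7`, `baseq(v) > 25`
   (consensus VAF is the median across supporting callers; depth, mutant
   depth and base quality come from the deepest supporting record);
2. `v ∉ PoN`, the exact-allele union of loci seen in control plasma;
3. `v` is not an SNV lying inside an MNV reported by a different caller;
4. `v` has a predicted functional effect (synonymous, UTR, intronic and
   2 kb flanking calls are removed — disregarded during follow-up
   tracking);
5. population allele frequency ≤ 0.001 in gnomAD and 1000 Genomes; and a
   variant with `VAF > 0.20` is removed whenever it is listed with any
   positive population frequency (likely germline);
6. InDels > 20 bp removed; 10–20 bp InDels removed when the inserted or
   deleted bases exceed 60 % GC; equal-length substitutions < 20 bp are
   reclassified as MNVs and kept;
7. a variant seen in the baselines of ≥ 2 patients and absent from COSMIC
   is removed everywhere (recurrent artifact).

For follow-up samples the VAF cutoff drops to 0.004 and rule 4 is
disregarded; a variant is *tracked* when it is called at the patient's
first timepoint and re-occurs later above the follow-up cutoff. Undetected
tracked variants contribute VAF 0, so the mean tracked VAF reflects
residual-disease decline rather than detection survivorship.

## Worked example

Generate a small synthetic cohort and run every stage:

```sh
$ cfhl simulate --out demo --seed 7 --patients 6
wrote bundle for 6 patients to demo

$ cfhl filter --bundle demo --out demo_filtered
filtered 16 samples -> demo_filtered

$ head -3 demo_filtered/pass_variants.tsv
sample_id  chrom  pos      ref  alt  gene   variant_class  vaf     read_depth  alt_depth  callers
P02_mid    chr1   5000337  A    C    SOCS1  SNV            0.0172  2664        45         lofreq,mutect2,sinvict,vardict
P02_mid    chr1   5001099  A    C    SOCS1  SNV            0.0324  2439        68         lofreq,mutect2,sinvict,vardict

$ cat demo_filtered/audit.tsv
rule              removed_count
alt_depth         1
base_quality      4
functional_effect 47
mnv_overlap       7
panel_of_normals  233
population_af     11
vaf               58

$ cfhl cnv --bins demo/bins/P04_pre.bins.tsv      # FGA + ETF for one sample
$ cfhl track --bundle demo --patient P02           # longitudinal hGE/mL
patient_id sample_id timepoint order_index n_tracked n_detected mean_vaf hge_per_ml ...
P02        P02_mid   mid       0           14        14         0.035929 133.312621 ...
P02        P02_post  post      1           14        14         0.094793 454.531613 ...

$ cfhl cluster --bundle demo                       # per-sample cluster table
$ cfhl report --bundle demo --out-dir demo_report  # summary, matrix, CNV track
```

The same stages are available as a library:

```python
from cfhl import SimulationConfig, simulate_cohort, pipeline

truth, bundle = simulate_cohort(SimulationConfig(seed=7))
analysis = pipeline.analyze_bundle(bundle)
table = pipeline.cluster_table(analysis)   # cluster, SNV load, median VAF, FGA, ETF
```

## Layout

```
src/cfhl/
  simulate.py   synthetic cohort generator with ground truth
  variants.py   VCF I/O, consensus merge, PoN, filter cascade
  cnv.py        segmentation, FGA, grid-search ETF estimator
  quantify.py   median VAF, hGE/mL, longitudinal tracking
  clusters.py   EBV/SOCS1 clustering and rank statistics
  report.py     cohort summary, mutation matrix, CNV frequencies
  pipeline.py   end-to-end orchestration
  cli.py        `cfhl` command-line interface
docs/methods.md  model assumptions, parameters and design rationale
```

See `docs/methods.md` for the statistical model, parameter defaults and
the limitations of the synthetic generator.
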