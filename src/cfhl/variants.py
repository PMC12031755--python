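"""Tumor-naive variant consensus and filtering for cfDNA panel sequencing.

Somatic variants are called from plasma without a matched normal, so
specificity comes from a cascade of filters applied to the merged output
of several independent callers:

1. primary evidence thresholds — read depth > 100, VAF > 1%, mutant reads
   > 7, mean base quality > 25 (strict inequalities);
2. a panel of normals (PoN) built from control plasma samples;
3. removal of SNVs that fall inside a multi-nucleotide variant (MNV)
   reported by a different caller for the same sample;
4. annotation filters — no predicted functional effect (synonymous, UTR,
   intronic, 2 kb flanking) excluded; population allele fraction > 0.001
   in gnomAD or 1000 Genomes excluded; VAF > 0.20 excluded whenever the
   variant is listed with any positive population frequency;
5. InDel heuristics — InDels longer than 20 bp removed, 10–20 bp InDels
   removed when the inserted/deleted bases exceed 60% GC; equal-length
   substitutions shorter than 20 bp are reclassified as MNVs and kept;
6. a cohort-level recurrence filter — identical variants found in the
   baseline samples of two or more patients and absent from COSMIC are
   removed everywhere.

Every input locus leaves the cascade either as PASS or labelled with the
first rule that removed it, so filtering decisions are fully auditable.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from statistics import median
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from pydantic import BaseModel, Field

__all__ = [
    "LocusKey",
    "CallerVariant",
    "AnnotatedVariant",
    "PanelOfNormals",
    "FilterConfig",
    "SampleFilterResult",
    "CohortFilterResult",
    "RULE_ORDER",
    "classify_alleles",
    "gc_fraction",
    "read_caller_vcf",
    "write_caller_vcf",
    "build_pon",
    "consensus_merge",
    "annotate_variants",
    "apply_primary_thresholds",
    "apply_annotation_filters",
    "apply_indel_mnv_rules",
    "remove_pon_and_mnv_overlaps",
    "run_cascade",
    "apply_cosmic_recurrence_filter",
    "filter_cohort",
    "read_annotations",
]

LocusKey = tuple[str, int, str, str]

NONFUNCTIONAL_EFFECTS = frozenset(
    {"synonymous", "utr5", "utr3", "intronic", "flanking_2kb"}
)

RULE_ORDER = (
    "read_depth",
    "vaf",
    "alt_depth",
    "base_quality",
    "panel_of_normals",
    "mnv_overlap",
    "functional_effect",
    "population_af",
    "high_vaf_in_population_db",
    "indel_length",
    "indel_gc",
    "cosmic_recurrence",
)

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


class FilterConfig(BaseModel):
    """Thresholds of the filter cascade.

    Defaults are the published values; ``min_vaf`` drops to 0.004 and
    ``disregard_functional_effect`` is switched on for follow-up samples
    during disease tracking.
    """

    min_read_depth: int = 100
    min_vaf: float = 0.01
    min_alt_depth: int = 7
    min_base_quality: float = 25.0
    max_population_af: float = 0.001
    high_vaf: float = 0.20
    indel_gc_max: float = 0.60
    indel_gc_min_len: int = 10
    indel_max_len: int = 20
    mnv_max_len: int = 20
    min_callers: int = Field(default=1, ge=1)
    disregard_functional_effect: bool = False
    cosmic_recurrence_scope: Literal["cross_patient", "within_sample"] = "cross_patient"

    @classmethod
    def followup(cls, **overrides) -> "FilterConfig":
        """Relaxed configuration for tracking follow-up samples."""
        kwargs = dict(min_vaf=0.004, disregard_functional_effect=True)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class CallerVariant:
    """One variant record emitted by one caller for one sample."""

    sample_id: str
    caller_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    read_depth: int
    alt_depth: int
    vaf: float
    base_quality: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        if not (0 <= self.alt_depth <= self.read_depth):
            raise ValueError(
                f"alt depth {self.alt_depth} exceeds read depth "
                f"{self.read_depth} at {self.chrom}:{self.pos}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF out of [0, 1] at {self.chrom}:{self.pos}")

    @property
    def key(self) -> LocusKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> str:
        return classify_alleles(self.ref, self.alt)

    @property
    def ref_span(self) -> tuple[int, int]:
        """Closed 1-based reference interval covered by the REF allele."""
        return (self.pos, self.pos + len(self.ref) - 1)


@dataclass
class AnnotatedVariant:
    """Consensus variant with annotations and a filter audit trail."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    callers: tuple[str, ...]
    vaf: float
    read_depth: int
    alt_depth: int
    base_quality: float
    gene: str = ""
    effect_class: str | None = None
    gnomad_af: float = float("nan")  # NaN = not listed
    kg_af: float = float("nan")
    in_cosmic: bool = False
    variant_class: str = "SNV"
    filter_status: str = "PASS"
    rule_trace: list[str] = field(default_factory=list)

    @property
    def key(self) -> LocusKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def base_length_difference(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def max_base_length(self) -> int:
        return max(len(self.ref), len(self.alt))

    @property
    def indel_length(self) -> int:
        """Net inserted/deleted length, |len(ref) - len(alt)|."""
        return self.base_length_difference

    @property
    def gc_content(self) -> float:
        """GC fraction of the inserted/deleted bases (0 for non-InDels)."""
        if len(self.alt) > len(self.ref):
            return gc_fraction(self.alt[len(self.ref):])
        if len(self.ref) > len(self.alt):
            return gc_fraction(self.ref[len(self.alt):])
        return 0.0

    @property
    def passed(self) -> bool:
        return self.filter_status == "PASS"


def classify_alleles(ref: str, alt: str) -> str:
    """SNV (both length 1), MNV (equal lengths, < 20 bp) or InDel."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) == len(alt) and len(ref) < 20:
        return "MNV"
    return "InDel"


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for b in seq.upper() if b in "GC") / len(seq)


# ---------------------------------------------------------------------------
# VCF I/O


def read_caller_vcf(
    path: str | Path,
    sample_id: str | None = None,
    caller_id: str | None = None,
) -> list[CallerVariant]:
    """Parse one per-caller VCF into ``CallerVariant`` records.

    The caller name is taken from the ``##source`` header and the sample
    name from the genotype column unless overridden.  Depth and mutant
    depth come from FORMAT DP/AD; mean base quality from INFO MBQ.
    """
    path = Path(path)
    records: list[CallerVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        header_caller = None
        for hrec in vcf.header.records:
            if hrec.key == "source":
                header_caller = hrec.value
        caller = caller_id or header_caller or path.stem
        vcf_samples = list(vcf.header.samples)
        sample = sample_id or (vcf_samples[0] if vcf_samples else path.stem)
        for i, rec in enumerate(vcf):
            try:
                alt = rec.alts[0] if rec.alts else None
                if alt is None or not _ALLELE_RE.match(alt) or not _ALLELE_RE.match(rec.ref):
                    raise ValueError("non-sequence alleles")
                fmt = rec.samples[vcf_samples[0]]
                dp = int(fmt["DP"])
                ad = fmt["AD"]
                alt_depth = int(ad[1])
                mbq = float(rec.info.get("MBQ", 30.0))
                records.append(
                    CallerVariant(
                        sample_id=sample,
                        caller_id=caller,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        read_depth=dp,
                        alt_depth=alt_depth,
                        vaf=alt_depth / dp if dp else 0.0,
                        base_quality=mbq,
                    )
                )
            except (KeyError, TypeError, ValueError, IndexError) as exc:
                raise ValueError(
                    f"malformed VCF record in {path} (record {i + 1}): {exc}"
                ) from exc
    return records


def write_caller_vcf(
    records: Sequence[CallerVariant],
    path: str | Path,
    caller_id: str,
    sample_id: str,
    contigs: Mapping[str, int],
) -> None:
    """Write records as a minimal VCFv4.2 file (FORMAT DP/AD, INFO MBQ)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={caller_id}",
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=MBQ,Number=1,Type=Float,Description="Mean base quality of variant-supporting reads">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
    ]
    contig_order = {name: i for i, name in enumerate(contigs)}
    for r in sorted(records, key=lambda v: (contig_order.get(v.chrom, 99), v.pos, v.ref, v.alt)):
        ref_depth = r.read_depth - r.alt_depth
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
            f"MBQ={r.base_quality:.1f}\tGT:DP:AD\t0/1:{r.read_depth}:{ref_depth},{r.alt_depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the annotation sidecar TSV keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "effect_class", "gnomad_af", "kg_af", "cosmic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Panel of normals


@dataclass(frozen=True)
class PanelOfNormals:
    """Exact-allele blacklist of loci observed in control plasma samples."""

    loci: frozenset[LocusKey]

    def __contains__(self, key: LocusKey) -> bool:
        return key in self.loci

    def __len__(self) -> int:
        return len(self.loci)


def build_pon(
    control_records: Iterable[Sequence[CallerVariant] | str | Path],
) -> PanelOfNormals:
    """Union of all locus keys across the control samples' caller VCFs."""
    loci: set[LocusKey] = set()
    n = 0
    for item in control_records:
        n += 1
        records = read_caller_vcf(item) if isinstance(item, (str, Path)) else item
        loci.update(r.key for r in records)
    if n == 0:
        raise ValueError("panel of normals requires at least one control sample")
    return PanelOfNormals(frozenset(loci))


# ---------------------------------------------------------------------------
# Consensus merge


def consensus_merge(caller_records: Sequence[CallerVariant]) -> list[AnnotatedVariant]:
    """Merge per-caller records of one sample into consensus variants.

    One record per distinct (chrom, pos, ref, alt); the consensus VAF is
    the median across supporting callers, while depth, mutant depth and
    base quality are taken from the supporting record with the greatest
    read depth (the deepest evidence for the call).
    """
    if not caller_records:
        return []
    samples = {r.sample_id for r in caller_records}
    if len(samples) > 1:
        raise ValueError(f"consensus_merge received records from samples {sorted(samples)}")
    by_key: dict[LocusKey, list[CallerVariant]] = defaultdict(list)
    for r in caller_records:
        by_key[r.key].append(r)
    merged: list[AnnotatedVariant] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda r: r.caller_id)
        best = max(group, key=lambda r: (r.read_depth, r.caller_id))
        merged.append(
            AnnotatedVariant(
                sample_id=group[0].sample_id,
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                callers=tuple(r.caller_id for r in group),
                vaf=float(median(r.vaf for r in group)),
                read_depth=best.read_depth,
                alt_depth=best.alt_depth,
                base_quality=best.base_quality,
                variant_class=classify_alleles(key[2], key[3]),
            )
        )
    return merged


def annotate_variants(
    variants: Sequence[AnnotatedVariant], annotations: pd.DataFrame | None
) -> None:
    """Attach gene/effect/population annotations in place.

    Loci absent from the sidecar keep NaN population frequencies (treated
    as "not listed") and a ``None`` effect class, which no rule removes.
    """
    if annotations is None or annotations.empty:
        return
    lookup: dict[LocusKey, tuple] = {}
    for row in annotations.itertuples(index=False):
        lookup[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = row
    for v in variants:
        row = lookup.get(v.key)
        if row is None:
            continue
        v.gene = "" if pd.isna(row.gene) else str(row.gene)
        v.effect_class = None if pd.isna(row.effect_class) else str(row.effect_class)
        v.gnomad_af = float("nan") if pd.isna(row.gnomad_af) else float(row.gnomad_af)
        v.kg_af = float("nan") if pd.isna(row.kg_af) else float(row.kg_af)
        v.in_cosmic = bool(row.cosmic)


# ---------------------------------------------------------------------------
# Individual rules (each returns the failing rule name or None)


def apply_primary_thresholds(v: AnnotatedVariant, cfg: FilterConfig) -> str | None:
    if not v.read_depth > cfg.min_read_depth:
        return "read_depth"
    if not v.vaf > cfg.min_vaf:
        return "vaf"
    if not v.alt_depth > cfg.min_alt_depth:
        return "alt_depth"
    if not v.base_quality > cfg.min_base_quality:
        return "base_quality"
    return None


def _mnv_spans_by_caller(
    caller_records: Sequence[CallerVariant],
) -> dict[str, list[tuple[str, int, int]]]:
    spans: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    for r in caller_records:
        if r.variant_class == "MNV":
            lo, hi = r.ref_span
            spans[r.caller_id].append((r.chrom, lo, hi))
    return spans


def _snv_in_foreign_mnv(
    v: AnnotatedVariant, mnv_spans: Mapping[str, list[tuple[str, int, int]]]
) -> bool:
    """True when an SNV sits inside an MNV reported by a non-supporting caller."""
    if v.variant_class != "SNV":
        return False
    supporters = set(v.callers)
    for caller, spans in mnv_spans.items():
        if caller in supporters:
            continue
        for chrom, lo, hi in spans:
            if chrom == v.chrom and lo <= v.pos <= hi:
                return True
    return False


def apply_annotation_filters(v: AnnotatedVariant, cfg: FilterConfig) -> str | None:
    if (
        not cfg.disregard_functional_effect
        and v.effect_class in NONFUNCTIONAL_EFFECTS
    ):
        return "functional_effect"
    gnomad_listed = not np.isnan(v.gnomad_af)
    kg_listed = not np.isnan(v.kg_af)
    if (gnomad_listed and v.gnomad_af > cfg.max_population_af) or (
        kg_listed and v.kg_af > cfg.max_population_af
    ):
        return "population_af"
    listed_positive = (gnomad_listed and v.gnomad_af > 0) or (kg_listed and v.kg_af > 0)
    if v.vaf > cfg.high_vaf and listed_positive:
        return "high_vaf_in_population_db"
    return None


def apply_indel_mnv_rules(v: AnnotatedVariant, cfg: FilterConfig) -> str | None:
    if v.variant_class != "InDel":
        return None
    if v.indel_length > cfg.indel_max_len:
        return "indel_length"
    if v.indel_length > cfg.indel_gc_min_len and v.gc_content > cfg.indel_gc_max:
        return "indel_gc"
    return None


def remove_pon_and_mnv_overlaps(
    variants: Sequence[AnnotatedVariant],
    pon: PanelOfNormals,
    caller_records: Sequence[CallerVariant],
) -> list[AnnotatedVariant]:
    """Convenience wrapper returning only survivors of the PoN and
    MNV-overlap rules (the cascade applies both with audit trails)."""
    mnv_spans = _mnv_spans_by_caller(caller_records)
    out = []
    for v in variants:
        if v.key in pon:
            continue
        if _snv_in_foreign_mnv(v, mnv_spans):
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# Cascade


@dataclass
class SampleFilterResult:
    sample_id: str
    variants: list[AnnotatedVariant]  # every input locus, audited

    @property
    def passed(self) -> list[AnnotatedVariant]:
        return [v for v in self.variants if v.passed]

    @property
    def rule_counts(self) -> Counter:
        return Counter(v.filter_status for v in self.variants if not v.passed)

    def audit_table(self) -> pd.DataFrame:
        counts = self.rule_counts
        return pd.DataFrame(
            {"rule": list(RULE_ORDER), "removed_count": [counts.get(r, 0) for r in RULE_ORDER]}
        )


def run_cascade(
    caller_records: Sequence[CallerVariant],
    pon: PanelOfNormals,
    annotations: pd.DataFrame | None,
    cfg: FilterConfig | None = None,
) -> SampleFilterResult:
    """Apply the full per-sample cascade (all rules except the cohort-level
    COSMIC recurrence filter) and return every variant with its audit."""
    cfg = cfg or FilterConfig()
    merged = consensus_merge(caller_records)
    annotate_variants(merged, annotations)
    mnv_spans = _mnv_spans_by_caller(caller_records)
    sample_id = caller_records[0].sample_id if caller_records else ""

    for v in merged:
        failing: str | None = None
        trace: list[str] = []

        def check(rule: str, failed: bool) -> bool:
            trace.append(rule)
            return failed

        if len(v.callers) < cfg.min_callers:
            failing = "min_callers"
            trace.append("min_callers")
        else:
            primary = apply_primary_thresholds(v, cfg)
            for rule in ("read_depth", "vaf", "alt_depth", "base_quality"):
                trace.append(rule)
                if primary == rule:
                    failing = rule
                    break
            if failing is None and check("panel_of_normals", v.key in pon):
                failing = "panel_of_normals"
            if failing is None and check("mnv_overlap", _snv_in_foreign_mnv(v, mnv_spans)):
                failing = "mnv_overlap"
            if failing is None:
                ann = apply_annotation_filters(v, cfg)
                for rule in ("functional_effect", "population_af", "high_vaf_in_population_db"):
                    trace.append(rule)
                    if ann == rule:
                        failing = rule
                        break
            if failing is None:
                indel = apply_indel_mnv_rules(v, cfg)
                for rule in ("indel_length", "indel_gc"):
                    trace.append(rule)
                    if indel == rule:
                        failing = rule
                        break
        v.filter_status = failing or "PASS"
        v.rule_trace = trace
    return SampleFilterResult(sample_id=sample_id, variants=merged)


def apply_cosmic_recurrence_filter(
    results: Mapping[str, SampleFilterResult],
    baseline_samples: Mapping[str, str],
    cfg: FilterConfig | None = None,
) -> None:
    """Remove recurrent non-COSMIC baseline variants across the cohort.

    ``baseline_samples`` maps baseline sample ids to patient ids.  In the
    default ``cross_patient`` scope a variant that survives the per-sample
    cascade in the baselines of >= 2 distinct patients and is not in COSMIC
    is failed (everywhere) with rule ``cosmic_recurrence``.  The
    ``within_sample`` scope instead removes non-COSMIC variants sharing a
    position with another allele in the same baseline sample (multi-allelic
    recurrence) — provided for the alternative reading of "non-unique".
    """
    cfg = cfg or FilterConfig()
    if cfg.cosmic_recurrence_scope == "cross_patient":
        patients_by_key: dict[LocusKey, set[str]] = defaultdict(set)
        for sample_id, patient_id in baseline_samples.items():
            result = results.get(sample_id)
            if result is None:
                continue
            for v in result.passed:
                patients_by_key[v.key].add(patient_id)
        recurrent = {k for k, pats in patients_by_key.items() if len(pats) >= 2}
        for result in results.values():
            for v in result.variants:
                v.rule_trace.append("cosmic_recurrence")
                if v.passed and v.key in recurrent and not v.in_cosmic:
                    v.filter_status = "cosmic_recurrence"
    else:
        for sample_id in baseline_samples:
            result = results.get(sample_id)
            if result is None:
                continue
            pos_counts = Counter((v.chrom, v.pos) for v in result.variants if v.passed)
            for v in result.variants:
                v.rule_trace.append("cosmic_recurrence")
                if v.passed and pos_counts[(v.chrom, v.pos)] >= 2 and not v.in_cosmic:
                    v.filter_status = "cosmic_recurrence"


@dataclass
class CohortFilterResult:
    results: dict[str, SampleFilterResult]
    pon: PanelOfNormals

    def passed(self, sample_id: str) -> list[AnnotatedVariant]:
        return self.results[sample_id].passed

    def rule_counts(self) -> Counter:
        total: Counter = Counter()
        for r in self.results.values():
            total.update(r.rule_counts)
        return total


def filter_cohort(
    records_by_sample: Mapping[str, Sequence[CallerVariant]],
    pon: PanelOfNormals,
    annotations: pd.DataFrame | None,
    baseline_samples: Mapping[str, str],
    cfg: FilterConfig | None = None,
) -> CohortFilterResult:
    """Per-sample cascades followed by the cohort recurrence filter."""
    cfg = cfg or FilterConfig()
    results = {
        sid: run_cascade(recs, pon, annotations, cfg)
        for sid, recs in records_by_sample.items()
    }
    apply_cosmic_recurrence_filter(results, baseline_samples, cfg)
    return CohortFilterResult(results=results, pon=pon)


def passed_table(result: SampleFilterResult) -> pd.DataFrame:
    """PASS variants of one sample as a tidy DataFrame."""
    rows = [
        {
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "variant_class": v.variant_class,
            "vaf": v.vaf,
            "read_depth": v.read_depth,
            "alt_depth": v.alt_depth,
            "callers": ",".join(v.callers),
        }
        for v in result.passed
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chrom", "pos", "ref", "alt", "gene",
            "variant_class", "vaf", "read_depth", "alt_depth", "callers",
        ],
    )
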