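"""Synthetic cfDNA cohorts with known ground truth.

Real plasma sequencing data for this disease setting are not publicly
deposited, so every downstream stage of the pipeline is exercised against
simulated cohorts whose somatic variants, germline polymorphisms,
sequencing artifacts, copy-number segments and longitudinal tumor-fraction
trajectories are all known exactly.

The generator emulates, at desk scale:

* a miniature genome (3 chromosomes x 100 one-megabase bins) carrying a
  targeted panel of B-cell-lymphoma genes;
* three biological clusters defined by tumor-cell EBV status and SOCS1
  mutation status (EBV+ & SOCS1-mutated, EBV- & SOCS1-mutated,
  EBV- & SOCS1-wild-type), with cluster-specific somatic variant loads
  and tumor-fraction distributions;
* four variant "callers" as independent logistic detection curves in VAF
  with caller-specific midpoints and small depth/VAF jitter, reproducing
  the partial-overlap structure a consensus merge must handle (the real
  callers' internals are not modelled);
* germline SNPs drawn from a common-polymorphism pool at population
  frequency, recurrent low-VAF sequencing artifacts shared with the
  control samples used for the panel of normals, and occasional MNVs that
  some callers decompose into their constituent SNVs;
* bin-level log2 ratios from the diploid-admixture forward model
  log2((tf*cn + (1-tf)*2)/2) plus Gaussian noise, with maxCN = 4;
* clinical covariates (cfDNA concentration, serum TARC, metabolic tumor
  volume, stage, subtype, relapse) correlated with tumor fraction, and
  follow-up timepoints with responder (x0.1 per timepoint) or refractory
  (fluctuating) tumor-fraction dynamics.

Identical configuration and seed produce byte-identical output bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .cnv import CNBin, expected_log2, write_bin_table
from .variants import CallerVariant, write_caller_vcf

__all__ = [
    "GeneInterval",
    "CallerModel",
    "ClusterParams",
    "SimulationConfig",
    "TrueVariant",
    "TrueSegment",
    "PatientTruth",
    "GroundTruth",
    "SampleData",
    "CohortBundle",
    "simulate_cohort",
    "read_bundle",
    "default_gene_panel",
    "default_clusters",
    "default_callers",
    "make_rule_violation_cohort",
    "STARC_ELEVATED_PG_ML",
]

NUCS = "ACGT"
CLUSTER_NAMES = ("EBV_pos_SOCS1m", "EBV_neg_SOCS1m", "EBV_neg_SOCS1wt")

# serum TARC level regarded as elevated, pg/mL
STARC_ELEVATED_PG_ML = 1000.0


class GeneInterval(BaseModel):
    name: str
    chrom: str
    start: int = Field(ge=0)  # 0-based half-open
    end: int

    @model_validator(mode="after")
    def _order(self) -> "GeneInterval":
        if self.end <= self.start:
            raise ValueError(f"gene {self.name}: end must exceed start")
        return self


class CallerModel(BaseModel):
    """Logistic detection curve of one emulated variant caller."""

    name: str
    midpoint: float = Field(gt=0, description="VAF at 50% detection probability")
    steepness: float = Field(gt=0)
    vaf_jitter_sd: float = Field(default=0.08, ge=0)
    depth_jitter_sd: float = Field(default=0.05, ge=0)
    mnv_merge_prob: float = Field(default=0.7, ge=0, le=1)

    def detection_prob(self, vaf: float) -> float:
        return float(1.0 / (1.0 + np.exp(-(vaf - self.midpoint) / self.steepness)))


class ClusterParams(BaseModel):
    name: str
    ebv_status: Literal["positive", "negative"]
    socs1_mutated: bool
    snv_load_mean: float = Field(gt=0)
    snv_load_dispersion: float = Field(default=4.0, gt=0)  # negative-binomial size
    tf_log_mu: float  # lognormal location of tumor fraction
    tf_log_sigma: float = Field(gt=0)
    relapse_prob: float = Field(ge=0, le=1)


def default_gene_panel() -> list[GeneInterval]:
    """A compact stand-in for the 72-gene (244 kb) lymphoma panel.

    Eighteen genes recurrently mutated in B-cell lymphomas, laid out on the
    miniature three-chromosome genome with realistic kb-scale footprints.
    """
    layout = [
        ("SOCS1", "chr1", 5_000_000, 2_500),
        ("KMT2D", "chr1", 12_000_000, 6_000),
        ("B2M", "chr1", 21_000_000, 2_000),
        ("STAT6", "chr1", 34_000_000, 4_000),
        ("ARID1A", "chr1", 47_000_000, 5_000),
        ("XPO1", "chr1", 62_000_000, 3_500),
        ("TNFAIP3", "chr2", 8_000_000, 3_000),
        ("IGLL5", "chr2", 16_000_000, 1_500),
        ("GNA13", "chr2", 27_000_000, 2_500),
        ("CSF2RB", "chr2", 41_000_000, 3_000),
        ("BCL7A", "chr2", 55_000_000, 2_000),
        ("ITPKB", "chr2", 70_000_000, 3_000),
        ("CREBBP", "chr3", 6_000_000, 5_500),
        ("NOTCH2", "chr3", 18_000_000, 4_500),
        ("DUSP2", "chr3", 30_000_000, 1_500),
        ("ACTB", "chr3", 44_000_000, 2_000),
        ("TP53", "chr3", 58_000_000, 2_500),
        ("NFKBIA", "chr3", 72_000_000, 2_000),
    ]
    return [
        GeneInterval(name=n, chrom=c, start=s, end=s + ln) for n, c, s, ln in layout
    ]


def default_gene_weights() -> dict[str, float]:
    """Relative propensity of each panel gene to carry a somatic variant,
    shaped after the mutation frequencies reported for this lymphoma."""
    return {
        "SOCS1": 0.52, "KMT2D": 0.36, "TNFAIP3": 0.31, "IGLL5": 0.26,
        "GNA13": 0.24, "CREBBP": 0.21, "ARID1A": 0.19, "CSF2RB": 0.19,
        "STAT6": 0.19, "B2M": 0.17, "BCL7A": 0.17, "NOTCH2": 0.14,
        "XPO1": 0.10, "ITPKB": 0.10, "ACTB": 0.08, "DUSP2": 0.08,
        "TP53": 0.06, "NFKBIA": 0.06,
    }


def default_clusters() -> list[ClusterParams]:
    # tumor-fraction lognormals chosen so per-patient median VAF (~0.375*tf)
    # spans roughly 0.01-0.14 across the cohort
    return [
        ClusterParams(
            name="EBV_pos_SOCS1m", ebv_status="positive", socs1_mutated=True,
            snv_load_mean=8.0, tf_log_mu=float(np.log(0.11)), tf_log_sigma=0.45,
            relapse_prob=0.10,
        ),
        ClusterParams(
            name="EBV_neg_SOCS1m", ebv_status="negative", socs1_mutated=True,
            snv_load_mean=15.0, tf_log_mu=float(np.log(0.17)), tf_log_sigma=0.45,
            relapse_prob=0.35,
        ),
        ClusterParams(
            name="EBV_neg_SOCS1wt", ebv_status="negative", socs1_mutated=False,
            snv_load_mean=5.0, tf_log_mu=float(np.log(0.08)), tf_log_sigma=0.45,
            relapse_prob=0.05,
        ),
    ]


def default_callers() -> list[CallerModel]:
    return [
        CallerModel(name="mutect2", midpoint=0.006, steepness=0.0025),
        CallerModel(name="lofreq", midpoint=0.008, steepness=0.003),
        CallerModel(name="vardict", midpoint=0.010, steepness=0.003, mnv_merge_prob=0.9),
        CallerModel(name="sinvict", midpoint=0.012, steepness=0.004, mnv_merge_prob=0.3),
    ]


class SimulationConfig(BaseModel):
    """All knobs of the cohort generator; defaults are the study conditions."""

    n_patients: int = Field(default=44, ge=0)
    seed: int = 0
    cluster_proportions: tuple[float, float, float] = (0.2, 0.4, 0.4)
    clusters: list[ClusterParams] = Field(default_factory=default_clusters)
    include_ebv_pos_wt: bool = False  # never observed; robustness only
    gene_panel: list[GeneInterval] = Field(default_factory=default_gene_panel)
    gene_weights: dict[str, float] = Field(default_factory=default_gene_weights)
    callers: list[CallerModel] = Field(default_factory=default_callers)
    n_controls: int = Field(default=7, ge=1)

    # truth-level rates
    no_ctdna_prob: float = Field(default=0.095, ge=0, le=1)
    ebv_unknown_prob: float = Field(default=0.02, ge=0, le=1)
    artifact_rate: float = Field(default=5.0, ge=0)
    n_artifact_pool: int = Field(default=50, ge=0)
    n_snp_pool: int = Field(default=120, ge=0)
    somatic_mnv_prob: float = Field(default=0.07, ge=0, le=1)
    somatic_indel_prob: float = Field(default=0.08, ge=0, le=1)
    somatic_cosmic_prob: float = Field(default=0.35, ge=0, le=1)

    # sequencing model (deep targeted panel)
    depth_mean: float = Field(default=2000.0, gt=0)
    depth_sd: float = Field(default=400.0, ge=0)
    depth_min: int = Field(default=150, ge=1)

    # copy-number model
    chrom_lengths: dict[str, int] = Field(
        default_factory=lambda: {"chr1": 100_000_000, "chr2": 100_000_000, "chr3": 100_000_000}
    )
    bin_size: int = Field(default=1_000_000, gt=0)
    bin_noise_sd: float = Field(default=0.02, ge=0)

    # clinical covariates
    cfdna_log_mu: float = Field(default=float(np.log(8000.0)))  # pg/mL plasma
    cfdna_log_sigma: float = Field(default=0.5, gt=0)
    starc_log_mu: float = Field(default=float(np.log(20000.0)))  # pg/mL serum
    starc_log_sigma: float = Field(default=0.7, gt=0)
    starc_tf_coupling: float = Field(default=1.0, ge=0)
    mtv_log_mu: float = Field(default=float(np.log(160.0)))  # mL
    mtv_log_sigma: float = Field(default=0.9, gt=0)
    mtv_missing_prob: float = Field(default=0.07, ge=0, le=1)

    # longitudinal design
    n_followup_patients: int = Field(default=8, ge=0)
    followup_missing_pre: int = Field(default=2, ge=0)
    followup_timepoints: tuple[str, ...] = ("pre", "mid", "post")
    responder_decay: float = Field(default=0.1, gt=0)
    refractory_decay: float = Field(default=1.0, gt=0)
    refractory_jitter_sd: float = Field(default=0.6, ge=0)
    refractory_fraction: float = Field(default=0.5, ge=0, le=1)

    @field_validator("cluster_proportions")
    @classmethod
    def _props_sum(cls, v: tuple[float, float, float]) -> tuple[float, float, float]:
        if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must be non-negative and sum to 1")
        return v

    # n_followup_patients and followup_missing_pre are clamped to the cohort
    # size at generation time, so small test cohorts need no overrides


# ---------------------------------------------------------------------------
# Ground truth


@dataclass(frozen=True)
class TrueVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    vaf: float  # true VAF at baseline tumor fraction
    category: str  # somatic | germline | artifact | mnv_decomposition
    pop_af: float = float("nan")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class TrueSegment:
    chrom: str
    start: int
    end: int
    cn: int


@dataclass
class PatientTruth:
    patient_id: str
    cluster: str
    ebv_status: str
    socs1_mutated: bool
    relapse: bool
    timepoints: list[str]
    tumor_fraction: dict[str, float]
    somatic: list[TrueVariant] = field(default_factory=list)
    germline: list[TrueVariant] = field(default_factory=list)
    artifacts: list[TrueVariant] = field(default_factory=list)
    decompositions: list[TrueVariant] = field(default_factory=list)
    segments: list[TrueSegment] = field(default_factory=list)

    def all_truth_keys(self) -> set[tuple[str, int, str, str]]:
        out = set()
        for group in (self.somatic, self.germline, self.artifacts, self.decompositions):
            out.update(v.key for v in group)
        return out


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth]
    controls: dict[str, list[TrueVariant]]

    def to_json(self) -> str:
        payload = {
            "patients": {pid: asdict(pt) for pid, pt in sorted(self.patients.items())},
            "controls": {cid: [asdict(v) for v in vs] for cid, vs in sorted(self.controls.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True, allow_nan=True)


# ---------------------------------------------------------------------------
# In-memory bundle


@dataclass
class SampleData:
    sample_id: str
    patient_id: str
    timepoint: str
    order_index: int
    pretreatment: bool
    caller_records: dict[str, list[CallerVariant]]
    bins: list[CNBin]


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, in memory and writable to disk."""

    config: SimulationConfig
    samples: list[SampleData]
    controls: dict[str, dict[str, list[CallerVariant]]]
    annotations: pd.DataFrame
    clinical: pd.DataFrame

    def baseline_samples(self) -> dict[str, str]:
        """Map of each patient's first-available sample id -> patient id."""
        first: dict[str, SampleData] = {}
        for s in self.samples:
            cur = first.get(s.patient_id)
            if cur is None or s.order_index < cur.order_index:
                first[s.patient_id] = s
        return {s.sample_id: pid for pid, s in first.items()}

    def sample(self, sample_id: str) -> SampleData:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def write(self, out_dir: str | Path, truth: GroundTruth | None = None) -> Path:
        out = Path(out_dir)
        try:
            (out / "vcf").mkdir(parents=True, exist_ok=True)
            (out / "controls").mkdir(exist_ok=True)
            (out / "bins").mkdir(exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out}: {exc}") from exc
        contigs = self.config.chrom_lengths
        for s in self.samples:
            for caller, recs in s.caller_records.items():
                write_caller_vcf(
                    recs, out / "vcf" / f"{s.sample_id}.{caller}.vcf",
                    caller_id=caller, sample_id=s.sample_id, contigs=contigs,
                )
            write_bin_table(s.bins, out / "bins" / f"{s.sample_id}.bins.tsv")
        for cid, by_caller in self.controls.items():
            for caller, recs in by_caller.items():
                write_caller_vcf(
                    recs, out / "controls" / f"{cid}.{caller}.vcf",
                    caller_id=caller, sample_id=cid, contigs=contigs,
                )
        self.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
        (out / "config.json").write_text(
            json.dumps(self.config.model_dump(), indent=1, sort_keys=True) + "\n"
        )
        if truth is not None:
            (out / "truth.json").write_text(truth.to_json() + "\n")
        return out


def read_bundle(bundle_dir: str | Path) -> CohortBundle:
    """Reload a written cohort bundle (the inverse of ``CohortBundle.write``)."""
    from .cnv import read_bin_table
    from .variants import read_caller_vcf

    root = Path(bundle_dir)
    cfg = SimulationConfig(**json.loads((root / "config.json").read_text()))
    clinical = pd.read_csv(root / "clinical.tsv", sep="\t")
    annotations = pd.read_csv(root / "annotations.tsv", sep="\t")
    samples: list[SampleData] = []
    for row in clinical.itertuples(index=False):
        sid = str(row.sample_id)
        records: dict[str, list[CallerVariant]] = {}
        for path in sorted((root / "vcf").glob(f"{sid}.*.vcf")):
            caller = path.name[len(sid) + 1:-4]
            records[caller] = read_caller_vcf(path, sample_id=sid, caller_id=caller)
        samples.append(
            SampleData(
                sample_id=sid,
                patient_id=str(row.patient_id),
                timepoint=str(row.timepoint),
                order_index=int(row.order_index),
                pretreatment=bool(row.pretreatment),
                caller_records=records,
                bins=read_bin_table(root / "bins" / f"{sid}.bins.tsv"),
            )
        )
    controls: dict[str, dict[str, list[CallerVariant]]] = {}
    for path in sorted((root / "controls").glob("*.vcf")):
        cid, caller = path.name[:-4].split(".", 1)
        controls.setdefault(cid, {})[caller] = read_caller_vcf(
            path, sample_id=cid, caller_id=caller
        )
    return CohortBundle(config=cfg, samples=samples, controls=controls,
                        annotations=annotations, clinical=clinical)


# ---------------------------------------------------------------------------
# Generation internals


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(NUCS[i] for i in rng.integers(0, 4, size=n))


def _substitute(rng: np.random.Generator, ref: str) -> str:
    out = []
    for b in ref:
        choices = [c for c in NUCS if c != b]
        out.append(choices[rng.integers(0, 3)])
    return "".join(out)


class _PanelSampler:
    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.genes = {g.name: g for g in cfg.gene_panel}

    def sample_locus(self, gene: str | None = None, used: set | None = None) -> tuple[str, int]:
        if gene is None:
            g = self.cfg.gene_panel[self.rng.integers(0, len(self.cfg.gene_panel))]
        else:
            g = self.genes[gene]
        for _ in range(200):
            pos = int(self.rng.integers(g.start + 1, g.end + 1))  # 1-based
            if used is None or (g.chrom, pos) not in used:
                if used is not None:
                    used.add((g.chrom, pos))
                return g.chrom, pos
        raise RuntimeError(f"could not place a unique locus in gene {g.name}")

    def gene_of(self, chrom: str, pos: int) -> str:
        for g in self.cfg.gene_panel:
            if g.chrom == chrom and g.start < pos <= g.end:
                return g.name
        return ""


def _draw_snp_pool(cfg: SimulationConfig, rng: np.random.Generator, panel: _PanelSampler):
    """Common germline polymorphisms: loci, alleles, population AFs."""
    pool = []
    used: set = set()
    for _ in range(cfg.n_snp_pool):
        chrom, pos = panel.sample_locus(used=used)
        ref = _random_bases(rng, 1)
        alt = _substitute(rng, ref)
        # log-uniform AF in [0.002, 0.5]; all exceed the 0.001 filter
        af = float(np.exp(rng.uniform(np.log(0.002), np.log(0.5))))
        effect = ["synonymous", "intronic", "utr5", "utr3", "flanking_2kb", "coding_nonsynonymous"][
            rng.choice(6, p=[0.25, 0.3, 0.1, 0.1, 0.1, 0.15])
        ]
        pool.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "af": af,
             "gene": panel.gene_of(chrom, pos), "effect": effect}
        )
    return pool, used


def _draw_artifact_pool(cfg: SimulationConfig, rng: np.random.Generator,
                        panel: _PanelSampler, used: set):
    """Recurrent low-VAF sequencing artifacts shared by all samples."""
    pool = []
    for _ in range(cfg.n_artifact_pool):
        chrom, pos = panel.sample_locus(used=used)
        ref = _random_bases(rng, 1)
        alt = _substitute(rng, ref)
        pool.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
             "vaf_scale": float(np.exp(rng.normal(np.log(0.008), 0.5))),
             "bq_mean": float(rng.normal(28.0, 3.0)),
             "gene": panel.gene_of(chrom, pos),
             "effect": "coding_nonsynonymous" if rng.random() < 0.6 else "intronic"}
        )
    return pool


def _draw_true_segments(cfg: SimulationConfig, rng: np.random.Generator) -> list[TrueSegment]:
    """At least one gain and one loss per ctDNA-positive patient, placed on
    non-overlapping bin runs (5-20 bins each)."""
    segs: list[TrueSegment] = []
    chroms = list(cfg.chrom_lengths)
    n_gain = int(rng.integers(1, 3))
    n_loss = int(rng.integers(1, 3))
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for cn_choices, n in (((3, 4), n_gain), ((1, 0), n_loss)):
        for _ in range(n):
            cn = int(rng.choice(cn_choices, p=[0.75, 0.25]))
            for _ in range(50):
                chrom = chroms[rng.integers(0, len(chroms))]
                n_bins_total = cfg.chrom_lengths[chrom] // cfg.bin_size
                length = int(rng.integers(5, 21))
                if length >= n_bins_total:
                    continue
                start_bin = int(rng.integers(0, n_bins_total - length))
                lo, hi = start_bin, start_bin + length
                # keep a 1-bin gap between true segments
                if all(hi + 1 <= a or lo >= b + 1 for a, b in occupied[chrom]):
                    occupied[chrom].append((lo, hi))
                    segs.append(
                        TrueSegment(chrom, lo * cfg.bin_size, hi * cfg.bin_size, cn)
                    )
                    break
    return segs


def _emit_bins(cfg: SimulationConfig, rng: np.random.Generator,
               segments: Sequence[TrueSegment], tf: float) -> list[CNBin]:
    bins: list[CNBin] = []
    for chrom, length in cfg.chrom_lengths.items():
        n = length // cfg.bin_size
        cn = np.full(n, 2, dtype=int)
        for seg in segments:
            if seg.chrom == chrom:
                cn[seg.start // cfg.bin_size: seg.end // cfg.bin_size] = seg.cn
        noise = rng.normal(0.0, cfg.bin_noise_sd, size=n)
        for i in range(n):
            log2 = expected_log2(int(cn[i]), tf) + noise[i]
            bins.append(CNBin(chrom, i * cfg.bin_size, (i + 1) * cfg.bin_size, float(log2)))
    return bins


def _sample_depth(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    return int(max(cfg.depth_min, round(rng.normal(cfg.depth_mean, cfg.depth_sd))))


def _emit_caller_records(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    true_variants: Sequence[tuple[TrueVariant, float, float]],
    mnv_events: Sequence[tuple[TrueVariant, list[TrueVariant], float, float]],
) -> dict[str, list[CallerVariant]]:
    """Turn true variants into per-caller records with dropout and jitter.

    ``true_variants``: (variant, vaf_now, bq_mean) triples.
    ``mnv_events``: (mnv, decomposed_snvs, vaf_now, bq_mean); each caller
    either reports the merged MNV or its constituent SNVs.
    """
    out: dict[str, list[CallerVariant]] = {c.name: [] for c in cfg.callers}

    def emit(variant: TrueVariant, vaf_now: float, bq_mean: float,
             as_records: list[TrueVariant] | None = None) -> None:
        depth0 = _sample_depth(cfg, rng)
        alt0 = int(rng.binomial(depth0, min(vaf_now, 1.0)))
        obs_vaf = alt0 / depth0
        if alt0 == 0:
            # draw detection variates anyway to keep the stream aligned only
            # where it matters; nothing is emitted without supporting reads
            return
        for caller in cfg.callers:
            if rng.random() >= caller.detection_prob(obs_vaf):
                continue
            reported = [variant]
            if as_records is not None and rng.random() >= caller.mnv_merge_prob:
                reported = as_records
            depth_c = max(
                cfg.depth_min, int(round(depth0 * np.exp(rng.normal(0, caller.depth_jitter_sd))))
            )
            alt_c = int(np.clip(round(alt0 * np.exp(rng.normal(0, caller.vaf_jitter_sd))), 1, depth_c))
            bq = float(np.clip(rng.normal(bq_mean, 2.0), 10.0, 45.0))
            for rv in reported:
                out[caller.name].append(
                    CallerVariant(
                        sample_id=sample_id, caller_id=caller.name,
                        chrom=rv.chrom, pos=rv.pos, ref=rv.ref, alt=rv.alt,
                        read_depth=depth_c, alt_depth=alt_c,
                        vaf=alt_c / depth_c, base_quality=round(bq, 1),
                    )
                )
    for variant, vaf_now, bq in true_variants:
        emit(variant, vaf_now, bq)
    for mnv, parts, vaf_now, bq in mnv_events:
        emit(mnv, vaf_now, bq, as_records=parts)
    return out


def _lognormal(rng: np.random.Generator, mu: float, sigma: float) -> float:
    return float(np.exp(rng.normal(mu, sigma)))


def _clinical_row(cfg: SimulationConfig, rng: np.random.Generator, pt: PatientTruth,
                  sample_id: str, timepoint: str, order: int, tf: float,
                  stage: str, subtype: str) -> dict:
    cfdna = _lognormal(rng, cfg.cfdna_log_mu + 0.5 * np.log1p(10 * tf), cfg.cfdna_log_sigma)
    starc = STARC_ELEVATED_PG_ML * 0.1 + _lognormal(
        rng,
        cfg.starc_log_mu + cfg.starc_tf_coupling * (np.log(tf + 0.01) - np.log(0.11)),
        cfg.starc_log_sigma,
    )
    if rng.random() < cfg.mtv_missing_prob:
        mtv = np.nan
    else:
        mtv = _lognormal(
            rng, cfg.mtv_log_mu + 0.5 * (np.log(tf + 0.01) - np.log(0.11)), cfg.mtv_log_sigma
        )
    return {
        "patient_id": pt.patient_id,
        "sample_id": sample_id,
        "timepoint": timepoint,
        "order_index": order,
        "pretreatment": timepoint == "pre",
        "ebv_status": pt.ebv_status,
        "stage": stage,
        "subtype": subtype,
        "relapse": pt.relapse,
        "cfdna_conc_pg_ml": round(cfdna, 1),
        "starc_pg_ml": round(starc, 1),
        "mtv_ml": round(mtv, 1) if np.isfinite(mtv) else np.nan,
    }


def simulate_cohort(
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[GroundTruth, CohortBundle]:
    """Generate a full synthetic cohort (and optionally write the bundle).

    Returns the ground truth and an in-memory bundle; when ``out_dir`` is
    given the bundle is also written as per-sample per-caller VCFs, bin
    tables, an annotation sidecar, a clinical table, control VCFs for PoN
    construction, the configuration and the serialized truth.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    panel = _PanelSampler(cfg, rng)
    snp_pool, used_loci = _draw_snp_pool(cfg, rng, panel)
    artifact_pool = _draw_artifact_pool(cfg, rng, panel, used_loci)

    clusters = list(cfg.clusters)
    props = np.array(cfg.cluster_proportions, dtype=float)
    if cfg.include_ebv_pos_wt:
        clusters.append(
            ClusterParams(
                name="EBV_pos_SOCS1wt", ebv_status="positive", socs1_mutated=False,
                snv_load_mean=4.0, tf_log_mu=float(np.log(0.08)), tf_log_sigma=0.45,
                relapse_prob=0.05,
            )
        )
        props = np.array([p * 0.9 for p in cfg.cluster_proportions] + [0.1])
        props = props / props.sum()

    annotation_rows: dict[tuple, dict] = {}

    def annotate(v: TrueVariant, effect: str, gnomad: float, kg: float, cosmic: bool) -> None:
        annotation_rows.setdefault(
            v.key,
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "gene": v.gene, "effect_class": effect,
             "gnomad_af": gnomad, "kg_af": kg, "cosmic": cosmic},
        )

    # ---- patients -------------------------------------------------------
    patients: dict[str, PatientTruth] = {}
    samples: list[SampleData] = []
    clinical_rows: list[dict] = []

    n = cfg.n_patients
    cluster_idx = rng.choice(len(clusters), size=n, p=props) if n else np.array([], dtype=int)
    followup_ids = set(range(min(cfg.n_followup_patients, n)))
    missing_pre_ids = set(range(min(cfg.followup_missing_pre, len(followup_ids))))

    for i in range(n):
        cl = clusters[int(cluster_idx[i])]
        pid = f"P{i + 1:02d}"
        ebv = cl.ebv_status if rng.random() >= cfg.ebv_unknown_prob else "unknown"
        relapse = bool(rng.random() < cl.relapse_prob)
        no_ctdna = rng.random() < cfg.no_ctdna_prob
        tf0 = 0.0 if no_ctdna else float(
            np.clip(np.exp(rng.normal(cl.tf_log_mu, cl.tf_log_sigma)), 0.0, 0.8)
        )
        is_followup = i in followup_ids
        if is_followup:
            relapse = True  # follow-up sampling targets relapsed/refractory disease
            tf0 = max(tf0, 0.1)  # trackable disease at the first timepoint
            timepoints = list(cfg.followup_timepoints)
            if i in missing_pre_ids:
                timepoints = [t for t in timepoints if t != "pre"]
            refractory = rng.random() < cfg.refractory_fraction
            decay = cfg.refractory_decay if refractory else cfg.responder_decay
        else:
            timepoints = ["pre"]
            refractory, decay = False, 1.0

        # tumor fraction trajectory over the full treatment course
        full_course = list(cfg.followup_timepoints) if is_followup else ["pre"]
        tfs: dict[str, float] = {}
        for t_idx, tp in enumerate(full_course):
            base = tf0 * decay**t_idx
            if refractory and t_idx > 0:
                base *= float(np.exp(rng.normal(0.0, cfg.refractory_jitter_sd)))
            tfs[tp] = float(min(base, 0.9))
        tfs = {tp: tfs[tp] for tp in timepoints}

        pt = PatientTruth(
            patient_id=pid, cluster=cl.name, ebv_status=ebv,
            socs1_mutated=cl.socs1_mutated, relapse=relapse,
            timepoints=timepoints, tumor_fraction=tfs,
        )

        # --- somatic truth (baseline) ---
        used_patient: set = set(used_loci)
        if tf0 > 0:
            p_nb = cl.snv_load_dispersion / (cl.snv_load_dispersion + cl.snv_load_mean)
            n_som = int(rng.negative_binomial(cl.snv_load_dispersion, p_nb))
            if cl.socs1_mutated and n_som == 0:
                n_som = 1
            gene_names = list(cfg.gene_weights)
            weights = np.array([cfg.gene_weights[g] for g in gene_names], dtype=float)
            if not cl.socs1_mutated:
                weights[gene_names.index("SOCS1")] = 0.0
            weights = weights / weights.sum()
            chosen = [gene_names[j] for j in rng.choice(len(gene_names), size=n_som, p=weights)]
            if cl.socs1_mutated and n_som > 0 and "SOCS1" not in chosen:
                chosen[0] = "SOCS1"
            mnv_events: list[tuple[TrueVariant, list[TrueVariant], float, float]] = []
            for gene in chosen:
                chrom, pos = panel.sample_locus(gene=gene, used=used_patient)
                clone = rng.uniform(0.5, 1.0)
                vaf = float(np.clip(tf0 * clone / 2.0, 1e-4, 1.0))
                u = rng.random()
                bq = float(rng.normal(36.0, 1.5))
                if u < cfg.somatic_mnv_prob and pos + 2 <= panel.genes[gene].end:
                    k = int(rng.integers(2, 4))
                    ref = _random_bases(rng, k)
                    alt = _substitute(rng, ref)
                    for off in range(1, k):
                        used_patient.add((chrom, pos + off))
                    mnv = TrueVariant(chrom, pos, ref, alt, gene, vaf, "somatic")
                    parts = [
                        TrueVariant(chrom, pos + off, ref[off], alt[off], gene,
                                    vaf, "mnv_decomposition")
                        for off in range(k)
                    ]
                    pt.somatic.append(mnv)
                    pt.decompositions.extend(parts)
                    mnv_events.append((mnv, parts, vaf, bq))
                    cosmic = bool(rng.random() < cfg.somatic_cosmic_prob)
                    annotate(mnv, "coding_nonsynonymous", np.nan, np.nan, cosmic)
                    for p_ in parts:
                        annotate(p_, "coding_nonsynonymous", np.nan, np.nan, False)
                elif u < cfg.somatic_mnv_prob + cfg.somatic_indel_prob:
                    length = int(rng.integers(1, 9))
                    anchor = _random_bases(rng, 1)
                    if rng.random() < 0.5:  # insertion
                        ref, alt = anchor, anchor + _random_bases(rng, length)
                    else:
                        ref, alt = anchor + _random_bases(rng, length), anchor
                    tv = TrueVariant(chrom, pos, ref, alt, gene, vaf, "somatic")
                    pt.somatic.append(tv)
                    annotate(tv, "coding_nonsynonymous", np.nan, np.nan,
                             bool(rng.random() < cfg.somatic_cosmic_prob))
                else:
                    ref = _random_bases(rng, 1)
                    alt = _substitute(rng, ref)
                    tv = TrueVariant(chrom, pos, ref, alt, gene, vaf, "somatic")
                    pt.somatic.append(tv)
                    annotate(tv, "coding_nonsynonymous", np.nan, np.nan,
                             bool(rng.random() < cfg.somatic_cosmic_prob))
            pt.segments = _draw_true_segments(cfg, rng)
        else:
            mnv_events = []

        # --- germline truth ---
        for snp in snp_pool:
            carrier_p = snp["af"] * (2 - snp["af"])
            if rng.random() < carrier_p:
                hom = rng.random() < snp["af"] / (2 - snp["af"])
                vaf = 1.0 if hom else float(np.clip(rng.normal(0.5, 0.015), 0.35, 0.65))
                tv = TrueVariant(snp["chrom"], snp["pos"], snp["ref"], snp["alt"],
                                 snp["gene"], vaf, "germline", pop_af=snp["af"])
                pt.germline.append(tv)
                annotate(tv, snp["effect"], snp["af"], round(snp["af"] * 0.9, 6), False)

        # --- artifact truth ---
        n_art = int(rng.poisson(cfg.artifact_rate))
        if cfg.n_artifact_pool and n_art:
            picks = rng.choice(cfg.n_artifact_pool, size=min(n_art, cfg.n_artifact_pool),
                               replace=False)
            for j in sorted(int(x) for x in picks):
                a = artifact_pool[j]
                vaf = float(np.clip(a["vaf_scale"] * np.exp(rng.normal(0, 0.3)), 5e-4, 0.05))
                tv = TrueVariant(a["chrom"], a["pos"], a["ref"], a["alt"],
                                 a["gene"], vaf, "artifact")
                pt.artifacts.append(tv)
                annotate(tv, a["effect"], np.nan, np.nan, False)

        # --- per-timepoint emission ---
        stage = "I-II" if rng.random() < 0.5 else "III-IV"
        subtype = ["MC", "NOS", "NS"][rng.choice(3, p=[0.136, 0.227, 0.637])]
        for order, tp in enumerate(timepoints):
            tf_t = pt.tumor_fraction[tp]
            scale = tf_t / tf0 if tf0 > 0 else 0.0
            trues: list[tuple[TrueVariant, float, float]] = []
            mnvs_t: list[tuple[TrueVariant, list[TrueVariant], float, float]] = []
            mnv_keys = {m.key for m, *_ in mnv_events}
            for v in pt.somatic:
                if v.key in mnv_keys:
                    continue
                trues.append((v, float(np.clip(v.vaf * scale, 0.0, 1.0)),
                              float(rng.normal(36.0, 1.5))))
            for mnv, parts, vaf, bq in mnv_events:
                mnvs_t.append((mnv, parts, float(np.clip(vaf * scale, 0.0, 1.0)), bq))
            for v in pt.germline:
                trues.append((v, v.vaf, float(rng.normal(36.0, 1.5))))
            for v in pt.artifacts:
                trues.append((v, v.vaf, a_bq := float(rng.normal(28.0, 3.0))))
            sample_id = f"{pid}_{tp}"
            records = _emit_caller_records(cfg, rng, sample_id, trues, mnvs_t)
            bins = _emit_bins(cfg, rng, pt.segments, tf_t)
            samples.append(
                SampleData(sample_id=sample_id, patient_id=pid, timepoint=tp,
                           order_index=order, pretreatment=tp == "pre",
                           caller_records=records, bins=bins)
            )
            clinical_rows.append(
                _clinical_row(cfg, rng, pt, sample_id, tp, order, tf_t, stage, subtype)
            )
        patients[pid] = pt

    # ---- controls -------------------------------------------------------
    controls: dict[str, dict[str, list[CallerVariant]]] = {}
    control_truth: dict[str, list[TrueVariant]] = {}
    for c in range(cfg.n_controls):
        cid = f"C{c + 1}"
        trues: list[tuple[TrueVariant, float, float]] = []
        truth_list: list[TrueVariant] = []
        for snp in snp_pool:
            if rng.random() < snp["af"] * (2 - snp["af"]):
                hom = rng.random() < snp["af"] / (2 - snp["af"])
                vaf = 1.0 if hom else float(np.clip(rng.normal(0.5, 0.015), 0.35, 0.65))
                tv = TrueVariant(snp["chrom"], snp["pos"], snp["ref"], snp["alt"],
                                 snp["gene"], vaf, "germline", pop_af=snp["af"])
                truth_list.append(tv)
                trues.append((tv, vaf, float(rng.normal(36.0, 1.5))))
        if cfg.n_artifact_pool:
            # controls see the recurrent artifact pool densely, which is what
            # makes the panel of normals an effective artifact blacklist
            for j, a in enumerate(artifact_pool):
                if rng.random() < 0.6:
                    vaf = float(np.clip(a["vaf_scale"] * np.exp(rng.normal(0, 0.3)), 5e-4, 0.05))
                    tv = TrueVariant(a["chrom"], a["pos"], a["ref"], a["alt"],
                                     a["gene"], vaf, "artifact")
                    truth_list.append(tv)
                    trues.append((tv, vaf, float(rng.normal(28.0, 3.0))))
        records = _emit_caller_records(cfg, rng, cid, trues, [])
        controls[cid] = records
        control_truth[cid] = truth_list

    annotations = pd.DataFrame(
        [annotation_rows[k] for k in sorted(annotation_rows)],
        columns=["chrom", "pos", "ref", "alt", "gene", "effect_class",
                 "gnomad_af", "kg_af", "cosmic"],
    )
    clinical = pd.DataFrame(
        clinical_rows,
        columns=["patient_id", "sample_id", "timepoint", "order_index", "pretreatment",
                 "ebv_status", "stage", "subtype", "relapse",
                 "cfdna_conc_pg_ml", "starc_pg_ml", "mtv_ml"],
    )
    truth = GroundTruth(patients=patients, controls=control_truth)
    bundle = CohortBundle(config=cfg, samples=samples, controls=controls,
                          annotations=annotations, clinical=clinical)
    if out_dir is not None:
        bundle.write(out_dir, truth)
    return truth, bundle


# ---------------------------------------------------------------------------
# Rule-violation planting (per-rule removal-count checks)


def make_rule_violation_cohort(k: int = 3, seed: int = 0):
    """Build a two-patient mini-cohort planting exactly ``k`` variants per
    filter rule, each designed to fail that rule and nothing earlier.

    Returns ``(records_by_sample, pon_records, annotations, baseline_map,
    expected_counts)`` ready for :func:`cfhl.variants.filter_cohort`.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    pos_iter = iter(range(1_000, 1_000_000, 50))

    ann_rows: list[dict] = []
    rec: dict[str, list[CallerVariant]] = {"S1": [], "S2": []}
    pon_records: list[CallerVariant] = []
    expected: dict[str, int] = {}

    def add(sample: str, pos: int, ref: str, alt: str, depth: int, alt_depth: int,
            bq: float, effect: str = "coding_nonsynonymous",
            gnomad: float = np.nan, kg: float = np.nan, cosmic: bool = False,
            caller: str = "mutect2") -> None:
        rec[sample].append(
            CallerVariant(sample_id=sample, caller_id=caller, chrom=chrom, pos=pos,
                          ref=ref, alt=alt, read_depth=depth, alt_depth=alt_depth,
                          vaf=alt_depth / depth, base_quality=bq)
        )
        ann_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                         "gene": "SOCS1", "effect_class": effect,
                         "gnomad_af": gnomad, "kg_af": kg, "cosmic": cosmic})

    def snv(rng):
        ref = NUCS[rng.integers(0, 4)]
        alt = [c for c in NUCS if c != ref][rng.integers(0, 3)]
        return ref, alt

    for _ in range(k):
        # each block uses fresh positions so rules never interact
        r, a = snv(rng)
        add("S1", next(pos_iter), r, a, depth=90, alt_depth=9, bq=35)        # read_depth
        r, a = snv(rng)
        add("S1", next(pos_iter), r, a, depth=1000, alt_depth=8, bq=35)      # vaf (0.008)
        r, a = snv(rng)
        add("S1", next(pos_iter), r, a, depth=500, alt_depth=6, bq=35)       # alt_depth (vaf 0.012)
        r, a = snv(rng)
        add("S1", next(pos_iter), r, a, depth=500, alt_depth=25, bq=22)      # base_quality
        r, a = snv(rng)
        p = next(pos_iter)
        add("S1", p, r, a, depth=500, alt_depth=25, bq=35)                   # panel_of_normals
        pon_records.append(
            CallerVariant(sample_id="C1", caller_id="mutect2", chrom=chrom, pos=p,
                          ref=r, alt=a, read_depth=400, alt_depth=6, vaf=0.015,
                          base_quality=30)
        )
        # mnv_overlap: SNV from mutect2 inside a vardict MNV
        p = next(pos_iter)
        r, a = snv(rng)
        add("S1", p, r, a, depth=500, alt_depth=25, bq=35)
        mref = r + "AC"
        malt = a + "GT"
        add("S1", p, mref, malt, depth=500, alt_depth=25, bq=35, caller="vardict")
        r, a = snv(rng)
        add("S1", next(pos_iter), r, a, depth=500, alt_depth=25, bq=35,
            effect="synonymous")                                             # functional_effect
        r, a = snv(rng)
        add("S1", next(pos_iter), r, a, depth=500, alt_depth=25, bq=35,
            gnomad=0.01)                                                     # population_af
        r, a = snv(rng)
        add("S1", next(pos_iter), r, a, depth=500, alt_depth=150, bq=35,
            gnomad=5e-4)                                                     # high_vaf (0.30, listed)
        add("S1", next(pos_iter), "A", "A" + "T" * 25, depth=500, alt_depth=25, bq=35)  # indel_length
        add("S1", next(pos_iter), "A", "A" + "GCGCGCGCGCGCGC", depth=500, alt_depth=25, bq=35)  # indel_gc (14bp, 100% GC)
        # cosmic_recurrence: identical clean variant in both patients
        p = next(pos_iter)
        r, a = snv(rng)
        add("S1", p, r, a, depth=500, alt_depth=25, bq=35)
        add("S2", p, r, a, depth=500, alt_depth=25, bq=35)
        # and one clean PASS variant per patient
        r, a = snv(rng)
        add("S1", next(pos_iter), r, a, depth=500, alt_depth=25, bq=35, cosmic=True)
        r, a = snv(rng)
        add("S2", next(pos_iter), r, a, depth=500, alt_depth=25, bq=35, cosmic=True)

    expected = {
        "read_depth": k, "vaf": k, "alt_depth": k, "base_quality": k,
        "panel_of_normals": k, "mnv_overlap": k, "functional_effect": k,
        "population_af": k, "high_vaf_in_population_db": k,
        "indel_length": k, "indel_gc": k, "cosmic_recurrence": 2 * k,
    }
    annotations = pd.DataFrame(ann_rows).drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    baseline = {"S1": "PA", "S2": "PB"}
    return rec, pon_records, annotations, baseline, expected
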