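"""End-to-end orchestration over a cohort bundle.

Glues the stages together for the CLI, the acceptance script and the
integration tests: panel-of-normals construction, the per-sample filter
cascade with the cohort recurrence step, CNV profiling with pre-treatment
ETF reconciliation, per-sample median VAF, cluster assignment and the
per-patient tracking series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import clusters as cl
from . import quantify as qt
from .cnv import CNVProfile, profile_sample
from .simulate import CohortBundle
from .variants import (
    AnnotatedVariant,
    CohortFilterResult,
    FilterConfig,
    PanelOfNormals,
    build_pon,
    filter_cohort,
)

__all__ = ["CohortAnalysis", "analyze_bundle", "build_tracking_for_patient"]


@dataclass
class CohortAnalysis:
    bundle: CohortBundle
    pon: PanelOfNormals
    filtered: CohortFilterResult
    profiles: dict[str, CNVProfile]
    clinical: dict[str, qt.SampleRecord]
    median_vafs: dict[str, float | None]
    cluster_of: dict[str, str] = field(default_factory=dict)

    def passed(self, sample_id: str) -> list[AnnotatedVariant]:
        return self.filtered.passed(sample_id)

    def baseline_sample_of(self, patient_id: str) -> str:
        for sid, pid in self.bundle.baseline_samples().items():
            if pid == patient_id:
                return sid
        raise KeyError(patient_id)


def analyze_bundle(
    bundle: CohortBundle, cfg: FilterConfig | None = None
) -> CohortAnalysis:
    """Run PoN, cascade, CNV profiles, median VAFs and cluster labels."""
    cfg = cfg or FilterConfig()
    control_records = [
        [r for recs in by_caller.values() for r in recs]
        for by_caller in bundle.controls.values()
    ]
    pon = build_pon(control_records)
    records_by_sample = {
        s.sample_id: [r for recs in s.caller_records.values() for r in recs]
        for s in bundle.samples
    }
    baseline = bundle.baseline_samples()
    filtered = filter_cohort(records_by_sample, pon, bundle.annotations, baseline, cfg)
    clinical = {r.sample_id: r for r in qt.read_clinical(bundle.clinical)}
    profiles = {
        s.sample_id: profile_sample(s.sample_id, s.bins, is_pretreatment=s.pretreatment)
        for s in bundle.samples
    }
    median_vafs = {
        sid: qt.median_vaf(filtered.passed(sid)) for sid in records_by_sample
    }
    analysis = CohortAnalysis(
        bundle=bundle, pon=pon, filtered=filtered, profiles=profiles,
        clinical=clinical, median_vafs=median_vafs,
    )
    for sid in records_by_sample:
        analysis.cluster_of[sid] = cl.assign_cluster(clinical[sid], filtered.passed(sid))
    return analysis


def build_tracking_for_patient(
    bundle: CohortBundle,
    patient_id: str,
    baseline_cfg: FilterConfig | None = None,
    followup_cfg: FilterConfig | None = None,
) -> qt.TrackingSeries:
    """Run the relaxed tracking cascade for one patient's timepoints.

    The first available timepoint keeps the standard VAF cutoff but drops
    the functional-effect filter; later timepoints additionally lower the
    VAF cutoff to 0.004.  Presence at a timepoint means emission by any
    caller surviving those rules.
    """
    baseline_cfg = baseline_cfg or FilterConfig(disregard_functional_effect=True)
    followup_cfg = followup_cfg or FilterConfig.followup()
    patient_samples = sorted(
        (s for s in bundle.samples if s.patient_id == patient_id),
        key=lambda s: s.order_index,
    )
    if len(patient_samples) < 2:
        raise ValueError(f"patient {patient_id} has fewer than two timepoints")
    control_records = [
        [r for recs in by_caller.values() for r in recs]
        for by_caller in bundle.controls.values()
    ]
    pon = build_pon(control_records)
    first_order = patient_samples[0].order_index
    records_by_sample = {}
    cfg_by_sample = {}
    for s in patient_samples:
        records_by_sample[s.sample_id] = [
            r for recs in s.caller_records.values() for r in recs
        ]
        cfg_by_sample[s.sample_id] = baseline_cfg if s.order_index == first_order else followup_cfg
    from .variants import run_cascade

    calls_by_order: dict[int, dict] = {}
    etf_by_order: dict[int, float] = {}
    for s in patient_samples:
        result = run_cascade(
            records_by_sample[s.sample_id], pon, bundle.annotations, cfg_by_sample[s.sample_id]
        )
        calls_by_order[s.order_index] = {v.key: v.vaf for v in result.passed}
        # tracking keeps the unreconciled tumor-fraction estimate
        profile = profile_sample(s.sample_id, s.bins, is_pretreatment=False)
        etf_by_order[s.order_index] = profile.etf
    clinical = {r.sample_id: r for r in qt.read_clinical(bundle.clinical)}
    sample_records = [clinical[s.sample_id] for s in patient_samples]
    return qt.build_tracking_series(
        patient_id, sample_records, calls_by_order, etf_by_order
    )


def cluster_table(analysis: CohortAnalysis, pretreatment_only: bool = True) -> pd.DataFrame:
    """Per-sample table of cluster label, SNV load, median VAF, FGA, ETF."""
    rows = []
    for s in analysis.bundle.samples:
        if pretreatment_only and not s.pretreatment:
            continue
        passed = analysis.passed(s.sample_id)
        profile = analysis.profiles[s.sample_id]
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "cluster": analysis.cluster_of[s.sample_id],
                "snv_load_excl_socs1": cl.snv_load(passed, exclude_socs1=True),
                "snv_load": cl.snv_load(passed, exclude_socs1=False),
                "median_vaf": analysis.median_vafs[s.sample_id],
                "fga": profile.fga,
                "etf": profile.etf,
                "starc_pg_ml": analysis.clinical[s.sample_id].starc_pg_ml,
                "mtv_ml": analysis.clinical[s.sample_id].mtv_ml,
            }
        )
    return pd.DataFrame(rows)
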