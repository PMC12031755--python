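"""ctDNA quantification and longitudinal disease tracking.

Per-sample quantities:

* the median VAF of PASS SNVs of a pre-treatment sample (undefined, not
  zero, when the sample has no PASS SNV);
* haploid genome equivalents of ctDNA per mL plasma,
  ``hGE/mL = mean VAF x cfDNA concentration (pg/mL) / 3.3``,
  3.3 pg being the weight of one haploid human genome.

Disease tracking relaxes the calling rules in follow-up samples — the
functional-effect filter is disregarded and the VAF cutoff drops to
0.004 — and tracks the variants called at the patient's first available
timepoint that re-occur at one or more later timepoints.  At timepoints
where a tracked variant is not re-detected it contributes a VAF of 0 by
default, so the mean tracked VAF (and hGE/mL) reflects residual-disease
decline rather than detection survivorship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import AnnotatedVariant, LocusKey

__all__ = [
    "HAPLOID_GENOME_PG",
    "FOLLOWUP_VAF_CUTOFF",
    "SampleRecord",
    "TrackingSeries",
    "median_vaf",
    "hge_per_ml",
    "select_trackable",
    "build_tracking_series",
    "read_clinical",
]

HAPLOID_GENOME_PG = 3.3
FOLLOWUP_VAF_CUTOFF = 0.004


@dataclass(frozen=True)
class SampleRecord:
    """Clinical and assay metadata for one plasma sample."""

    patient_id: str
    sample_id: str
    timepoint: str
    order_index: int
    pretreatment: bool
    ebv_status: str  # positive | negative | unknown
    stage: str
    subtype: str
    relapse: bool
    cfdna_conc_pg_ml: float | None
    starc_pg_ml: float | None
    mtv_ml: float | None = None  # only measured with a positive PET scan

    def __post_init__(self) -> None:
        for name in ("cfdna_conc_pg_ml", "starc_pg_ml"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative for {self.sample_id}")


def read_clinical(path_or_df) -> list[SampleRecord]:
    """Read the clinical TSV into :class:`SampleRecord` objects."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df, sep="\t")
    records = []
    seen: dict[str, set[int]] = {}
    for row in df.itertuples(index=False):
        orders = seen.setdefault(row.patient_id, set())
        if row.order_index in orders:
            raise ValueError(
                f"duplicate order index {row.order_index} for patient {row.patient_id}"
            )
        orders.add(row.order_index)
        records.append(
            SampleRecord(
                patient_id=str(row.patient_id),
                sample_id=str(row.sample_id),
                timepoint=str(row.timepoint),
                order_index=int(row.order_index),
                pretreatment=bool(row.pretreatment),
                ebv_status=str(row.ebv_status),
                stage=str(row.stage),
                subtype=str(row.subtype),
                relapse=bool(row.relapse),
                cfdna_conc_pg_ml=None if pd.isna(row.cfdna_conc_pg_ml) else float(row.cfdna_conc_pg_ml),
                starc_pg_ml=None if pd.isna(row.starc_pg_ml) else float(row.starc_pg_ml),
                mtv_ml=None if pd.isna(row.mtv_ml) else float(row.mtv_ml),
            )
        )
    return records


def median_vaf(pass_variants: Sequence[AnnotatedVariant]) -> float | None:
    """Median VAF of the PASS SNVs of one sample; None when there is none.

    MNVs and InDels are excluded: the quantity is defined over single
    nucleotide variants only.
    """
    vafs = [v.vaf for v in pass_variants if v.passed and v.variant_class == "SNV"]
    if not vafs:
        return None
    return float(np.median(vafs))


def hge_per_ml(mean_vaf: float, cfdna_conc_pg_ml: float) -> float:
    """ctDNA load in haploid genome equivalents per mL plasma."""
    if mean_vaf < 0 or cfdna_conc_pg_ml < 0:
        raise ValueError("mean VAF and cfDNA concentration must be non-negative")
    return mean_vaf * cfdna_conc_pg_ml / HAPLOID_GENOME_PG


def select_trackable(
    calls_by_order: Mapping[int, Mapping[LocusKey, float]],
    followup_vaf_cutoff: float = FOLLOWUP_VAF_CUTOFF,
) -> set[LocusKey]:
    """Variants usable for tracking a patient over time.

    ``calls_by_order`` maps each timepoint's order index to the variants
    called there (locus key -> VAF) under the relaxed tracking rules.  A
    variant is trackable when it is called at the first available
    timepoint and re-occurs, with VAF above the follow-up cutoff, at one
    or more later timepoints.
    """
    if len(calls_by_order) < 2:
        raise ValueError("tracking requires at least two timepoints")
    orders = sorted(calls_by_order)
    first = orders[0]
    baseline = set(calls_by_order[first])
    recurring: set[LocusKey] = set()
    for t in orders[1:]:
        for key, vaf in calls_by_order[t].items():
            if key in baseline and vaf > followup_vaf_cutoff:
                recurring.add(key)
    if not recurring:
        warnings.warn("no trackable variants for this patient", stacklevel=2)
    return recurring


@dataclass
class TrackingSeries:
    """Longitudinal ctDNA quantification for one patient."""

    patient_id: str
    tracked: set[LocusKey]
    table: pd.DataFrame = field(repr=False)  # one row per timepoint


def build_tracking_series(
    patient_id: str,
    samples: Sequence[SampleRecord],
    calls_by_order: Mapping[int, Mapping[LocusKey, float]],
    etf_by_order: Mapping[int, float] | None = None,
    followup_vaf_cutoff: float = FOLLOWUP_VAF_CUTOFF,
    undetected_as_zero: bool = True,
) -> TrackingSeries:
    """Assemble the per-timepoint tracking table for one patient.

    The mean VAF at each timepoint averages the tracked variants; a
    tracked variant that is not re-detected contributes 0 when
    ``undetected_as_zero`` (the default), or is dropped from the mean
    otherwise.  hGE/mL is omitted (NaN) where the cfDNA concentration is
    missing; the ETF values are aligned unreconciled.
    """
    tracked = select_trackable(calls_by_order, followup_vaf_cutoff)
    etf_by_order = etf_by_order or {}
    rows = []
    for s in sorted(samples, key=lambda r: r.order_index):
        calls = calls_by_order.get(s.order_index, {})
        if tracked:
            vafs = []
            for key in sorted(tracked):
                if key in calls:
                    vafs.append(calls[key])
                elif undetected_as_zero:
                    vafs.append(0.0)
            mean_vaf = float(np.mean(vafs)) if vafs else 0.0
            n_detected = sum(1 for key in tracked if key in calls)
        else:
            mean_vaf, n_detected = np.nan, 0
        if s.cfdna_conc_pg_ml is None or not np.isfinite(mean_vaf):
            hge = np.nan
        else:
            hge = hge_per_ml(mean_vaf, s.cfdna_conc_pg_ml)
        rows.append(
            {
                "patient_id": patient_id,
                "sample_id": s.sample_id,
                "timepoint": s.timepoint,
                "order_index": s.order_index,
                "n_tracked": len(tracked),
                "n_detected": n_detected,
                "mean_vaf": mean_vaf,
                "hge_per_ml": hge,
                "hge_missing_conc": s.cfdna_conc_pg_ml is None,
                "etf": etf_by_order.get(s.order_index, np.nan),
                "starc_pg_ml": np.nan if s.starc_pg_ml is None else s.starc_pg_ml,
                "mtv_ml": np.nan if s.mtv_ml is None else s.mtv_ml,
            }
        )
    return TrackingSeries(patient_id=patient_id, tracked=tracked, table=pd.DataFrame(rows))
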