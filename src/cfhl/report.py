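"""Cohort reporting: summary table, mutation matrix, CNV frequency track.

The cohort summary mirrors a clinical Table-1 layout: categorical fields
as "count (percent)" with percentages rounded half-up to one decimal
against the full cohort size, numeric fields as mean (SD) and
median [min, max], and explicit Missing rows.  The mutation matrix is an
oncoplot-style gene x sample incidence table with a reproducible sort:
genes by descending SNV count, samples by EBV status, SOCS1 status and
descending SNV load, with lexicographic tie-breaks; samples without any
PASS variant are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnv import CNVProfile
from .quantify import SampleRecord
from .variants import AnnotatedVariant

__all__ = [
    "CohortSummary",
    "MutationMatrix",
    "round_percent",
    "summarize_cohort",
    "build_mutation_matrix",
    "cnv_frequency_track",
]


def round_percent(count: int, total: int) -> float:
    """100*count/total rounded half-up to one decimal (Table-1 convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _round1(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n: int
    table: pd.DataFrame = field(repr=False)  # columns: variable, statistic, value (strings)

    def percent(self, variable: str, level: str) -> float:
        """Recover the numeric percentage of one categorical level."""
        row = self.table[(self.table.variable == variable) & (self.table.statistic == level)]
        if row.empty:
            raise KeyError(f"{variable}/{level} not in summary")
        value = row.value.iloc[0]  # "19 (43.2%)"
        return float(value.split("(")[1].rstrip("%)"))

    def count(self, variable: str, level: str) -> int:
        row = self.table[(self.table.variable == variable) & (self.table.statistic == level)]
        if row.empty:
            raise KeyError(f"{variable}/{level} not in summary")
        return int(row.value.iloc[0].split(" ")[0])

    def to_tsv(self, path: str | Path | None = None) -> str:
        buf = StringIO()
        self.table.to_csv(buf, sep="\t", index=False)
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, source: str | Path) -> "CohortSummary":
        text = Path(source).read_text() if isinstance(source, Path) else source
        df = pd.read_csv(StringIO(text), sep="\t", dtype=str)
        n = int(df[df.variable == "_cohort"].value.iloc[0])
        return cls(n=n, table=df.reset_index(drop=True))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortSummary):
            return NotImplemented
        return self.n == other.n and self.table.equals(other.table)


def summarize_cohort(
    clinical: pd.DataFrame,
    categorical: Sequence[str] = ("ebv_status", "stage", "subtype", "relapse"),
    numeric: Sequence[str] = ("cfdna_conc_pg_ml", "starc_pg_ml", "mtv_ml"),
) -> CohortSummary:
    """Descriptive cohort summary over one row per patient/sample.

    Every categorical level (including an explicit Missing level when NA
    values occur) is reported as "k (p%)" with p computed against the full
    cohort n; numeric fields report "mean (sd)", "median [min, max]" and a
    Missing row.
    """
    if clinical.empty:
        raise ValueError("cannot summarize an empty clinical table")
    n = len(clinical)
    rows: list[dict] = [{"variable": "_cohort", "statistic": "N", "value": str(n)}]
    for col in categorical:
        series = clinical[col]
        counts = series.value_counts(dropna=True)
        for level in sorted(counts.index, key=str):
            k = int(counts[level])
            rows.append(
                {"variable": col, "statistic": str(level),
                 "value": f"{k} ({round_percent(k, n)}%)"}
            )
        n_missing = int(series.isna().sum())
        if n_missing:
            rows.append(
                {"variable": col, "statistic": "Missing",
                 "value": f"{n_missing} ({round_percent(n_missing, n)}%)"}
            )
    for col in numeric:
        series = pd.to_numeric(clinical[col], errors="coerce")
        valid = series.dropna()
        if len(valid):
            rows.append(
                {"variable": col, "statistic": "Mean (SD)",
                 "value": f"{_round1(valid.mean())} ({_round1(valid.std())})"}
            )
            rows.append(
                {"variable": col, "statistic": "Median [Min, Max]",
                 "value": f"{_round1(valid.median())} [{_round1(valid.min())}, {_round1(valid.max())}]"}
            )
        n_missing = n - len(valid)
        rows.append(
            {"variable": col, "statistic": "Missing",
             "value": f"{n_missing} ({round_percent(n_missing, n)}%)"}
        )
    return CohortSummary(n=n, table=pd.DataFrame(rows, columns=["variable", "statistic", "value"]))


@dataclass
class MutationMatrix:
    """Oncoplot-style gene x sample SNV incidence with ordering metadata."""

    matrix: pd.DataFrame = field(repr=False)  # genes (rows) x samples (cols), SNV counts
    gene_sample_counts: pd.Series = field(repr=False)  # samples mutated per gene
    sample_loads: pd.Series = field(repr=False)  # SNVs per sample
    sample_order_keys: pd.DataFrame = field(repr=False)


def build_mutation_matrix(
    pass_variants_by_sample: Mapping[str, Sequence[AnnotatedVariant]],
    clinical_by_sample: Mapping[str, SampleRecord],
) -> MutationMatrix:
    """Gene x sample SNV count matrix with the standard oncoplot sort.

    Genes descend by total SNV count (ties by name); samples group by EBV
    status (positive first), then SOCS1 mutation status (mutated first),
    then descending SNV load, ties by sample id.  Samples without any PASS
    variant (no detectable ctDNA) are excluded.
    """
    cells: dict[str, dict[str, int]] = {}
    keys = []
    for sample_id, variants in pass_variants_by_sample.items():
        passed = [v for v in variants if v.passed]
        if not passed:
            continue
        snvs = [v for v in passed if v.variant_class == "SNV" and v.gene]
        col = {}
        for v in snvs:
            col[v.gene] = col.get(v.gene, 0) + 1
        cells[sample_id] = col
        rec = clinical_by_sample[sample_id]
        keys.append(
            {
                "sample_id": sample_id,
                "ebv_rank": {"positive": 0, "negative": 1}.get(rec.ebv_status, 2),
                "socs1_rank": 0 if any(v.gene == "SOCS1" for v in passed) else 1,
                "snv_load": len(snvs),
            }
        )
    if not cells:
        empty = pd.DataFrame()
        return MutationMatrix(empty, pd.Series(dtype=int), pd.Series(dtype=int),
                              pd.DataFrame(columns=["sample_id", "ebv_rank", "socs1_rank", "snv_load"]))
    matrix = pd.DataFrame(cells).fillna(0).astype(int)
    gene_totals = matrix.sum(axis=1)
    gene_order = gene_totals.sort_index().sort_values(ascending=False, kind="stable").index
    key_df = pd.DataFrame(keys)
    key_df = key_df.sort_values(
        ["ebv_rank", "socs1_rank", "snv_load", "sample_id"],
        ascending=[True, True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    matrix = matrix.loc[gene_order, key_df.sample_id.tolist()]
    gene_sample_counts = (matrix > 0).sum(axis=1)
    sample_loads = matrix.sum(axis=0)
    return MutationMatrix(
        matrix=matrix,
        gene_sample_counts=gene_sample_counts,
        sample_loads=sample_loads,
        sample_order_keys=key_df,
    )


def cnv_frequency_track(profiles: Sequence[CNVProfile]) -> pd.DataFrame:
    """Per-bin gain/loss frequencies across samples.

    All profiles must share an identical bin grid; the result has one row
    per bin with the fraction of samples in which that bin lies inside a
    gain or a loss segment.
    """
    if not profiles:
        raise ValueError("need at least one CNV profile")
    grid = [(b.chrom, b.start, b.end) for b in profiles[0].bins]
    for p in profiles[1:]:
        if [(b.chrom, b.start, b.end) for b in p.bins] != grid:
            raise ValueError(f"bin grid of {p.sample_id} differs from the first profile")
    gain = np.zeros(len(grid))
    loss = np.zeros(len(grid))
    index = {g: i for i, g in enumerate(grid)}
    for p in profiles:
        for seg in p.segments:
            for b in p.bins:
                if b.chrom == seg.chrom and seg.start <= b.start and b.end <= seg.end:
                    i = index[(b.chrom, b.start, b.end)]
                    if seg.direction == "gain":
                        gain[i] += 1
                    else:
                        loss[i] += 1
    return pd.DataFrame(
        {
            "chrom": [g[0] for g in grid],
            "start": [g[1] for g in grid],
            "end": [g[2] for g in grid],
            "gain_freq": gain / len(profiles),
            "loss_freq": loss / len(profiles),
        }
    )
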