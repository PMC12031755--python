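"""Copy-number profiling of cell-free DNA from bin-level log2 ratios.

Bins (1,000 kbp in real use) carry log2 read-depth ratios relative to a
diploid reference.  Gains and losses are called as maximal runs of
consecutive bins breaching a symmetric log2 cutoff (default ±0.08, the
value calibrated on control plasma samples).  From the called segments the
module derives the fraction of genome altered (FGA) and an estimated tumor
fraction (ETF) — the fraction of cfDNA that is tumor-derived — via a
grid-search mixture estimator over integer copy numbers up to ``max_cn``.

The ETF estimator is NOT ichorCNA: it is a deliberately simple, fully
specified inversion of the diploid-admixture forward model

    log2 ratio = log2((tf * cn + (1 - tf) * 2) / 2)

validated by parameter recovery on synthetic profiles.  It shares the
pre-treatment reconciliation rule used in practice: when the FGA is zero
but the estimator still reports a positive tumor fraction, the ETF of a
pre-treatment sample is adjusted to zero (tracking samples are never
adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CNBin",
    "CNSegment",
    "CNVProfile",
    "expected_log2",
    "call_segments",
    "compute_fga",
    "estimate_tumor_fraction",
    "reconcile_etf",
    "profile_sample",
    "read_bin_table",
    "write_bin_table",
    "control_threshold",
    "counts_to_log2",
]

DEFAULT_THRESHOLD = 0.08
DEFAULT_MAX_CN = 4


@dataclass(frozen=True)
class CNBin:
    """One genomic bin (0-based, half-open) with its log2 depth ratio."""

    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"bin end must exceed start: {self}")


@dataclass(frozen=True)
class CNSegment:
    """A maximal run of same-direction aberrant bins."""

    chrom: str
    start: int
    end: int
    direction: str  # "gain" | "loss"
    n_bins: int
    mean_log2: float


@dataclass(frozen=True)
class CNVProfile:
    sample_id: str
    bins: tuple[CNBin, ...]
    segments: tuple[CNSegment, ...]
    fga: float
    etf: float
    etf_adjusted: bool = False


def expected_log2(cn: int, tf: float) -> float:
    """Expected bin log2 ratio for integer copy number ``cn`` at tumor
    fraction ``tf``, under a diploid-admixture model.

    ``cn = 2`` returns 0 for every tumor fraction; ``cn = 0`` at ``tf = 1``
    is ``-inf`` (total loss of all copies).
    """
    if not 0.0 <= tf <= 1.0:
        raise ValueError(f"tumor fraction out of [0, 1]: {tf}")
    if not 0 <= cn <= DEFAULT_MAX_CN:
        raise ValueError(f"copy number out of [0, {DEFAULT_MAX_CN}]: {cn}")
    with np.errstate(divide="ignore"):
        return float(np.log2((tf * cn + (1.0 - tf) * 2.0) / 2.0))


def _validate_bins(bins: Sequence[CNBin]) -> None:
    seen: dict[str, int] = {}
    for b in bins:
        prev_end = seen.get(b.chrom)
        if prev_end is not None and b.start < prev_end:
            raise ValueError(
                f"bins unsorted or overlapping on {b.chrom} at {b.start}"
            )
        seen[b.chrom] = b.end


def call_segments(
    bins: Sequence[CNBin], threshold: float = DEFAULT_THRESHOLD
) -> list[CNSegment]:
    """Group consecutive aberrant bins into maximal gain/loss segments.

    A bin is a gain when log2 > +threshold and a loss when log2 <
    -threshold; bins exactly at the cutoff are neutral.  Runs never extend
    across chromosomes or across a change of direction.
    """
    _validate_bins(bins)
    segments: list[CNSegment] = []
    run: list[CNBin] = []
    run_dir: str | None = None

    def flush() -> None:
        nonlocal run, run_dir
        if run:
            segments.append(
                CNSegment(
                    chrom=run[0].chrom,
                    start=run[0].start,
                    end=run[-1].end,
                    direction=run_dir,  # type: ignore[arg-type]
                    n_bins=len(run),
                    mean_log2=float(np.mean([b.log2_ratio for b in run])),
                )
            )
        run, run_dir = [], None

    for b in bins:
        if b.log2_ratio > threshold:
            direction = "gain"
        elif b.log2_ratio < -threshold:
            direction = "loss"
        else:
            direction = None
        if direction is None:
            flush()
            continue
        if run and (direction != run_dir or b.chrom != run[0].chrom):
            flush()
        run.append(b)
        run_dir = direction
    flush()
    return segments


def compute_fga(bins: Sequence[CNBin], segments: Sequence[CNSegment]) -> float:
    """Fraction of genome altered: aberrant bins over total bins."""
    if len(bins) == 0:
        raise ValueError("cannot compute FGA with zero bins")
    return sum(s.n_bins for s in segments) / len(bins)


def estimate_tumor_fraction(
    bins: Sequence[CNBin],
    max_cn: int = DEFAULT_MAX_CN,
    threshold: float = DEFAULT_THRESHOLD,
    grid_step: float = 0.001,
    cn_penalty: float = 1e-6,
) -> float:
    """Estimate the tumor fraction from called segments by grid search.

    For each candidate tf in {0, grid_step, ..., 1} every segment is
    assigned the integer copy number (0..max_cn) whose expected log2 ratio
    is nearest its mean; the score is the bin-weighted squared error plus a
    tiny complexity penalty ``cn_penalty * n_bins * (cn - 2)**2`` that
    breaks exact degeneracies (a lone gain of mean log2(1.5) is explained
    equally well by cn=3 at tf=1 and cn=4 at tf=0.5; the penalty prefers
    the copy number closest to diploid).  Returns 0 when no segment exists.
    """
    if len(bins) == 0:
        raise ValueError("cannot estimate tumor fraction with zero bins")
    segments = call_segments(bins, threshold=threshold)
    if not segments:
        return 0.0

    seg_means = np.array([s.mean_log2 for s in segments])
    seg_nbins = np.array([s.n_bins for s in segments], dtype=float)
    tf_grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    cns = np.arange(0, max_cn + 1)

    # expected log2 for every (cn, tf); cn=0 at tf=1 -> -inf, never nearest
    with np.errstate(divide="ignore"):
        exp = np.log2((tf_grid[None, :] * cns[:, None] + (1 - tf_grid[None, :]) * 2) / 2)

    # residuals: (segment, cn, tf)
    resid = np.abs(seg_means[:, None, None] - exp[None, :, :])
    # nearest copy number per segment per tf; ties resolved toward cn near 2
    tie_break = 1e-12 * (cns - 2) ** 2
    best_cn = np.argmin(resid + tie_break[None, :, None], axis=1)
    best_resid = np.take_along_axis(resid, best_cn[:, None, :], axis=1)[:, 0, :]
    best_resid = np.where(np.isfinite(best_resid), best_resid, np.inf)
    cost = (seg_nbins[:, None] * best_resid**2).sum(axis=0)
    cost = cost + cn_penalty * (seg_nbins[:, None] * (best_cn - 2) ** 2).sum(axis=0)
    return float(tf_grid[int(np.argmin(cost))])


def reconcile_etf(profile: CNVProfile, is_pretreatment: bool) -> CNVProfile:
    """Zero out the ETF of a pre-treatment sample whose FGA is zero.

    A positive tumor-fraction estimate without any called copy-number
    segment in a pre-treatment sample is treated as estimator noise and
    manually adjusted to zero.  Follow-up (tracking) samples are returned
    unchanged so longitudinal ETF values remain unaltered.
    """
    if is_pretreatment and profile.fga == 0 and profile.etf > 0:
        return replace(profile, etf=0.0, etf_adjusted=True)
    return profile


def profile_sample(
    sample_id: str,
    bins: Sequence[CNBin],
    threshold: float = DEFAULT_THRESHOLD,
    max_cn: int = DEFAULT_MAX_CN,
    is_pretreatment: bool = False,
) -> CNVProfile:
    """Run the full per-sample CNV workflow: segments, FGA, ETF, reconcile."""
    segments = call_segments(bins, threshold=threshold)
    fga = compute_fga(bins, segments)
    etf = estimate_tumor_fraction(bins, max_cn=max_cn, threshold=threshold)
    profile = CNVProfile(
        sample_id=sample_id,
        bins=tuple(bins),
        segments=tuple(segments),
        fga=fga,
        etf=etf,
    )
    return reconcile_etf(profile, is_pretreatment)


def read_bin_table(path: str | Path) -> list[CNBin]:
    """Read a BED-like TSV with columns chrom, start, end, log2_ratio."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "log2_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bin table {path} missing columns {sorted(missing)}")
    return [
        CNBin(str(r.chrom), int(r.start), int(r.end), float(r.log2_ratio))
        for r in df.itertuples(index=False)
    ]


def write_bin_table(bins: Sequence[CNBin], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "log2_ratio": [f"{b.log2_ratio:.6f}" for b in bins],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def control_threshold(control_bins: Iterable[Sequence[CNBin]]) -> float:
    """Calibrate the gain/loss cutoff from control samples.

    Returns the maximum absolute bin log2 ratio observed across the
    controls, the empirical noise ceiling of a copy-number-neutral cohort.
    The printed default of 0.08 remains the shipped cutoff.
    """
    values = [abs(b.log2_ratio) for sample in control_bins for b in sample]
    if not values:
        raise ValueError("no control bins supplied")
    return max(values)


def counts_to_log2(counts: Sequence[float]) -> np.ndarray:
    """Median-normalize raw bin read counts to log2 ratios (synthetic use).

    Real data arrive as GC/mappability-corrected log2 ratios from upstream
    binning; this helper only serves count-level synthetic inputs.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or np.median(arr) <= 0:
        raise ValueError("counts must be non-empty with positive median")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore"):
        return np.log2(arr / np.median(arr))
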