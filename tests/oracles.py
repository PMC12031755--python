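"""Independent brute-force re-implementations used as test oracles.

Deliberately written as flat, monolithic logic with no code shared with
the package internals, so agreement is meaningful.
"""

from __future__ import annotations

import math


def brute_force_filter(
    caller_records_by_sample: dict[str, list],
    pon_keys: set,
    ann: dict,  # key -> dict(effect, gnomad, kg, cosmic)
    baseline_patient_by_sample: dict[str, str],
    min_callers: int = 1,
    min_vaf: float = 0.01,
    disregard_effect: bool = False,
) -> dict[str, set]:
    """Return the PASS key set per sample by re-deriving every rule inline."""
    merged_by_sample: dict[str, dict] = {}
    for sample, records in caller_records_by_sample.items():
        groups: dict[tuple, list] = {}
        for r in records:
            groups.setdefault((r.chrom, r.pos, r.ref, r.alt), []).append(r)
        merged_by_sample[sample] = groups

    def vclass(ref, alt):
        if len(ref) == 1 and len(alt) == 1:
            return "SNV"
        if len(ref) == len(alt) and len(ref) < 20:
            return "MNV"
        return "InDel"

    def survives_sample_rules(sample, key, group) -> bool:
        chrom, pos, ref, alt = key
        if len({r.caller_id for r in group}) < min_callers:
            return False
        vafs = sorted(r.vaf for r in group)
        n = len(vafs)
        vaf = vafs[n // 2] if n % 2 else (vafs[n // 2 - 1] + vafs[n // 2]) / 2
        best = max(group, key=lambda r: (r.read_depth, r.caller_id))
        if not (best.read_depth > 100 and vaf > min_vaf and best.alt_depth > 7
                and best.base_quality > 25):
            return False
        if key in pon_keys:
            return False
        if vclass(ref, alt) == "SNV":
            supporters = {r.caller_id for r in group}
            for other in caller_records_by_sample[sample]:
                if other.caller_id in supporters:
                    continue
                if vclass(other.ref, other.alt) != "MNV":
                    continue
                if other.chrom == chrom and other.pos <= pos <= other.pos + len(other.ref) - 1:
                    return False
        a = ann.get(key, {})
        effect = a.get("effect")
        gnomad = a.get("gnomad", float("nan"))
        kg = a.get("kg", float("nan"))
        if not disregard_effect and effect in (
            "synonymous", "utr5", "utr3", "intronic", "flanking_2kb"
        ):
            return False
        g_listed = gnomad is not None and not math.isnan(gnomad)
        k_listed = kg is not None and not math.isnan(kg)
        if (g_listed and gnomad > 0.001) or (k_listed and kg > 0.001):
            return False
        if vaf > 0.20 and ((g_listed and gnomad > 0) or (k_listed and kg > 0)):
            return False
        if vclass(ref, alt) == "InDel":
            ilen = abs(len(ref) - len(alt))
            longer = alt[len(ref):] if len(alt) > len(ref) else ref[len(alt):]
            gc = sum(1 for b in longer.upper() if b in "GC") / len(longer) if longer else 0.0
            if ilen > 20:
                return False
            if ilen > 10 and gc > 0.60:
                return False
        return True

    stage1 = {
        sample: {k for k, g in groups.items() if survives_sample_rules(sample, k, g)}
        for sample, groups in merged_by_sample.items()
    }
    # cohort COSMIC-recurrence step over baseline samples
    patients_with_key: dict[tuple, set] = {}
    for sample, patient in baseline_patient_by_sample.items():
        for k in stage1.get(sample, set()):
            patients_with_key.setdefault(k, set()).add(patient)
    removed = {
        k for k, pats in patients_with_key.items()
        if len(pats) >= 2 and not ann.get(k, {}).get("cosmic", False)
    }
    return {sample: keys - removed for sample, keys in stage1.items()}


def brute_force_segment_mask(log2_values, threshold=0.08):
    """Per-bin aberration mask (+1 gain, -1 loss, 0 neutral)."""
    return [
        1 if v > threshold else (-1 if v < -threshold else 0) for v in log2_values
    ]
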