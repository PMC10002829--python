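"""De novo candidate selection from trio variants.

The cascade keeps a variant/alt-allele pair only if every rule holds:
enough depth in all three samples (default 20x), at least two
alternate-supporting reads in the proband, zero alternate reads and a
homozygous-reference genotype in both parents, proband VAF at most 0.70, the
key absent from the population blacklist and from every excluded region
class, and the GATK-style hard-filter annotations within the per-class
thresholds (SNV: MQ > 30, ReadPosRankSum > -8, FS < 60, QD > 2; indel:
ReadPosRankSum > -20, FS < 200, QD > 2).

Filters are conjunctive, so the survivor set is order-independent; the
audit records the rules in the order evaluated, stopping at the first
failure for rejected alleles. Missing annotations pass (annotation-free
records cannot be hard-filtered) and the pass is logged as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .io import PopulationBlacklist, RegionSet, TrioVariant

SNV = "SNV"
INDEL = "indel"

#: (metric key, comparison, threshold) per variant class.
DEFAULT_HARD_FILTERS: dict[str, tuple[tuple[str, str, float], ...]] = {
    SNV: (("MQ", ">", 30.0), ("ReadPosRankSum", ">", -8.0),
          ("FS", "<", 60.0), ("QD", ">", 2.0)),
    INDEL: (("ReadPosRankSum", ">", -20.0),
            ("FS", "<", 200.0), ("QD", ">", 2.0)),
}


class UndefinedVafError(ZeroDivisionError):
    pass


@dataclass
class FilterParams:
    """Thresholds of the de novo filter cascade (defaults as published)."""

    min_depth_all_samples: int = 20
    min_proband_alt_reads: int = 2
    max_parent_alt_reads: int = 0
    max_vaf: float = 0.70
    hard_filters: dict[str, tuple[tuple[str, str, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_HARD_FILTERS))

    def __post_init__(self) -> None:
        for thresholds in self.hard_filters.values():
            for name, op, value in thresholds:
                if not math.isfinite(value):
                    raise ValueError(f"non-finite threshold for {name}")
                if op not in ("<", ">"):
                    raise ValueError(f"unsupported comparison {op!r}")


@dataclass
class FilterDecision:
    filter: str
    passed: bool
    observed: object


@dataclass
class DeNovoCandidate:
    """A variant/alt pair that entered (and possibly survived) the cascade."""

    variant: TrioVariant
    alt_index: int
    vaf: float
    variant_class: str  # SNV | indel
    audit: list[FilterDecision] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def ref(self) -> str:
        return self.variant.ref

    @property
    def alt(self) -> str:
        return self.variant.alts[self.alt_index]

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def passed(self) -> bool:
        return all(d.passed for d in self.audit)

    @property
    def first_failure(self) -> str | None:
        for d in self.audit:
            if not d.passed:
                return d.filter
        return None


def compute_vaf(alt_reads: int, total_depth: int) -> float:
    """Variant allele fraction: alternate reads over total depth."""
    if total_depth < 1:
        raise UndefinedVafError("VAF undefined at zero depth")
    if not 0 <= alt_reads <= total_depth:
        raise ValueError(f"alt_reads {alt_reads} outside [0, {total_depth}]")
    return alt_reads / total_depth


def classify_variant_class(ref: str, alt: str) -> str:
    """SNV iff both alleles are single bases; everything else is routed to
    the indel hard filters (equal-length multi-base substitutions are
    decomposed into per-base substitutions by the pattern module)."""
    if not ref or not alt:
        raise ValueError("empty allele")
    return SNV if len(ref) == 1 and len(alt) == 1 else INDEL


def _hard_filter_decisions(variant: TrioVariant, variant_class: str,
                           params: FilterParams) -> list[FilterDecision]:
    out = []
    for name, op, threshold in params.hard_filters.get(variant_class, ()):
        observed = variant.site_metrics.get(name)
        if observed is None:
            # absent annotation: filter not applicable, passes (logged)
            out.append(FilterDecision(f"hard_filter:{name}", True, "missing"))
            continue
        ok = observed > threshold if op == ">" else observed < threshold
        out.append(FilterDecision(f"hard_filter:{name}", ok, observed))
    return out


def evaluate_candidate(variant: TrioVariant, alt_index: int,
                       params: FilterParams,
                       regions: list[RegionSet],
                       blacklist: PopulationBlacklist | None) -> DeNovoCandidate:
    """Run the full cascade for one variant/alt pair.

    The audit stops at the first failing rule; survivors carry a full
    all-pass audit.
    """
    alt = variant.alts[alt_index]
    variant_class = classify_variant_class(variant.ref, alt)
    audit: list[FilterDecision] = []
    proband = variant.samples["proband"]
    vaf = float("nan")
    if (proband.depth is not None and proband.alt_depths is not None
            and proband.depth >= 1):
        vaf = compute_vaf(proband.alt_depths[alt_index], proband.depth)

    def check(name: str, passed: bool, observed) -> bool:
        audit.append(FilterDecision(name, passed, observed))
        return passed

    while True:  # single pass; break at first failure
        if not check("usable_record", variant.usable,
                     variant.unusable_reason or "ok"):
            break
        parent_gts = {r: variant.samples[r].genotype for r in ("mother", "father")}
        missing_gt = [r for r, gt in parent_gts.items() if gt is None]
        if not check("parental_genotype_present", not missing_gt,
                     ",".join(missing_gt) or "present"):
            break
        homref = all(all(a == 0 for a in gt) for gt in parent_gts.values())
        if not check("parental_genotype_homref", homref,
                     {r: gt for r, gt in parent_gts.items()}):
            break
        min_depth = min(variant.samples[r].depth for r in variant.samples)
        if not check("min_depth_all_samples",
                     min_depth >= params.min_depth_all_samples, min_depth):
            break
        alt_reads = proband.alt_depths[alt_index]
        if not check("min_proband_alt_reads",
                     alt_reads >= params.min_proband_alt_reads, alt_reads):
            break
        parent_alt = max(variant.samples[r].alt_depths[alt_index]
                         for r in ("mother", "father"))
        if not check("max_parent_alt_reads",
                     parent_alt <= params.max_parent_alt_reads, parent_alt):
            break
        if not check("max_vaf", vaf <= params.max_vaf, round(vaf, 4)):
            break
        if blacklist is not None:
            key = (variant.chrom, variant.pos, variant.ref, alt)
            if not check("blacklist", key not in blacklist,
                         "hit" if key in blacklist else "absent"):
                break
        region_hit = next((rs.label for rs in regions
                           if rs.contains(variant.chrom, variant.pos)), None)
        if not check("excluded_region", region_hit is None,
                     region_hit or "none"):
            break
        for decision in _hard_filter_decisions(variant, variant_class, params):
            audit.append(decision)
            if not decision.passed:
                break
        break

    return DeNovoCandidate(variant=variant, alt_index=alt_index, vaf=vaf,
                           variant_class=variant_class, audit=audit)


def filter_trio(variants: list[TrioVariant], params: FilterParams | None = None,
                regions: list[RegionSet] | None = None,
                blacklist: PopulationBlacklist | None = None,
                ) -> tuple[list[DeNovoCandidate], pd.DataFrame]:
    """Apply the de novo cascade to every variant/alt pair.

    Returns the surviving candidates and an audit table with one row per
    variant x alt x evaluated filter.
    """
    params = params or FilterParams()
    regions = regions or []
    survivors: list[DeNovoCandidate] = []
    rows = []
    for variant in variants:
        for alt_index in range(len(variant.alts)):
            cand = evaluate_candidate(variant, alt_index, params, regions,
                                      blacklist)
            if cand.passed:
                survivors.append(cand)
            for d in cand.audit:
                rows.append({
                    "chrom": cand.chrom, "pos": cand.pos, "ref": cand.ref,
                    "alt": cand.alt, "variant_class": cand.variant_class,
                    "filter": d.filter,
                    "result": "pass" if d.passed else "fail",
                    "observed": str(d.observed),
                })
    audit = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                        "variant_class", "filter", "result",
                                        "observed"])
    return survivors, audit


GERMLINE_LOW = 0.3741
GERMLINE_HIGH = 0.6259


def germline_vs_mosaic_split(candidates: list[DeNovoCandidate],
                             germline_low: float = GERMLINE_LOW,
                             germline_high: float = GERMLINE_HIGH,
                             ) -> tuple[list[DeNovoCandidate],
                                        list[DeNovoCandidate],
                                        list[DeNovoCandidate]]:
    """Split survivors into germline (VAF in [low, high]), mosaic
    (VAF < low) and above-germline (high < VAF) buckets.

    The above-germline interval (62.59%, 70%] is retained and reported
    separately rather than merged into germline.
    """
    germline, mosaic, above = [], [], []
    for cand in candidates:
        if cand.vaf < germline_low:
            mosaic.append(cand)
        elif cand.vaf <= germline_high:
            germline.append(cand)
        else:
            above.append(cand)
    return germline, mosaic, above


def rejection_summary(audit: pd.DataFrame) -> pd.DataFrame:
    """Count rejected alleles per first-failing filter."""
    fails = audit[audit["result"] == "fail"]
    first = fails.drop_duplicates(subset=["chrom", "pos", "ref", "alt"],
                                  keep="first")
    counts = first.groupby("filter").size().rename("rejected").reset_index()
    return counts.sort_values("rejected", ascending=False, ignore_index=True)
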