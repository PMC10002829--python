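"""End-to-end pipeline: simulate/load -> filter -> timing -> patterns ->
signatures, with a machine-readable run report.

Every number in the report is recomputable from the serialized stage
outputs, and a rerun with the same config produces byte-identical stage
files (no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pyfaidx
import yaml

from . import __version__
from .filtering import FilterParams, filter_trio, germline_vs_mosaic_split, \
    rejection_summary
from .io import (read_blacklist, read_regions_bed, read_signature_matrix,
                 read_vcf_trio)
from .patterns import (decompose_to_substitutions, events_table, group_events,
                       intermutation_distances, titv_table)
from .signatures import backwards_selection, build_profile, profile_table, \
    rank_signatures
from .simulate import SimulationConfig, simulate_reference, simulate_trio
from .timing import (PUBLISHED_BINS, TimingModel, assign_origin_bins,
                     estimate_boundaries, timing_table)

log = logging.getLogger("dnmosaic")

RECONCILIATION_NOTE = (
    "pattern tables report both event counts and member-base counts; "
    "member-base totals need not equal the per-bin SNV counts (multi-base "
    "events contribute several bases, biallelic events contribute two alt "
    "alleles at one site)")


class ConfigurationError(ValueError):
    pass


class ComparisonError(ValueError):
    pass


@dataclass
class RunReport:
    parameters: dict
    input_digests: dict[str, str]
    stage_counts: dict
    warnings: list[str]
    version: str = __version__
    seed: int | None = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "RunReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str, outdir: str) -> RunReport:
    """Execute the full analysis described by ``config``.

    ``config`` is a dict (or path to a YAML file) with either a
    ``simulate`` block (:class:`SimulationConfig` fields) or explicit
    ``vcf``/``samples`` inputs, plus optional ``reference``, ``blacklist``,
    ``regions`` (label -> BED path), ``signature_catalog``, ``filter``
    (FilterParams overrides), ``bins`` ("published" or "estimate"), ``seed``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_list = [RECONCILIATION_NOTE]
    seed = config.get("seed", 0)
    digests: dict[str, str] = {}

    # ---- stage: inputs (simulate or load) --------------------------------
    catalog = None
    if config.get("signature_catalog"):
        catalog = read_signature_matrix(config["signature_catalog"])
        digests["signature_catalog"] = _digest(config["signature_catalog"])
    if "simulate" in config:
        sim_dir = outdir / "simulate"
        sim_dir.mkdir(exist_ok=True)
        sim_cfg = SimulationConfig(**{**config["simulate"], "seed": seed})
        reference_path = simulate_reference(sim_cfg,
                                            sim_dir / "reference.fa")
        sim = simulate_trio(sim_cfg, reference_path, sim_dir,
                            signatures=catalog)
        vcf_path = sim.vcf
        sample_roles = {r: r for r in ("proband", "mother", "father")}
        blacklist_path = sim.blacklist_path
        region_paths = {lab: str(p) for lab, p in sim.region_beds.items()}
        log.info("simulated %d variant records", len(sim.truth))
    elif "vcf" in config:
        vcf_path = config["vcf"]
        reference_path = config.get("reference")
        sample_roles = config.get("samples") or {}
        blacklist_path = config.get("blacklist")
        region_paths = config.get("regions", {})
    else:
        raise ConfigurationError(
            "config needs either a 'simulate' block or a 'vcf' path")
    digests["vcf"] = _digest(vcf_path)
    if reference_path:
        digests["reference"] = _digest(reference_path)

    # ---- stage: filter ---------------------------------------------------
    filt_dir = outdir / "filter"
    filt_dir.mkdir(exist_ok=True)
    variants = read_vcf_trio(str(vcf_path), sample_roles)
    params = FilterParams(**config.get("filter", {}))
    regions = [read_regions_bed(str(path), label)
               for label, path in sorted(region_paths.items())]
    blacklist = (read_blacklist(str(blacklist_path))
                 if blacklist_path else None)
    survivors, audit = filter_trio(variants, params, regions, blacklist)
    audit.to_csv(filt_dir / "audit.tsv", sep="\t", index=False)
    rejections = rejection_summary(audit)
    rejections.to_csv(filt_dir / "rejections.tsv", sep="\t", index=False)
    review = pd.DataFrame(
        [{"chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
          "variant_class": c.variant_class, "vaf": round(c.vaf, 4)}
         for c in survivors])
    review.to_csv(filt_dir / "candidates.tsv", sep="\t", index=False)
    log.info("filter: %d/%d variant records survive", len(survivors),
             len(variants))

    # ---- stage: timing ---------------------------------------------------
    timing_dir = outdir / "timing"
    timing_dir.mkdir(exist_ok=True)
    if config.get("bins", "published") == "estimate":
        depth = config.get("depth") or _mean_proband_depth(variants) or 50
        model = estimate_boundaries(TimingModel(depth=int(depth), seed=seed))
        bins = model.bins()
    else:
        model = TimingModel(depth=int(config.get("depth", 50)), seed=seed)
        bins = PUBLISHED_BINS
    assign_origin_bins(survivors, bins)
    table = timing_table(survivors, bins)
    table.to_csv(timing_dir / "timing_table.tsv", sep="\t", index=False)
    germline, mosaic, above = germline_vs_mosaic_split(survivors)

    # ---- stage: patterns -------------------------------------------------
    pat_dir = outdir / "patterns"
    pat_dir.mkdir(exist_ok=True)
    substitutions = decompose_to_substitutions(survivors)
    events = group_events(substitutions)
    events_table(events).to_csv(pat_dir / "events.tsv", sep="\t", index=False)
    titv = titv_table(events)
    titv.to_csv(pat_dir / "titv.tsv", sep="\t", index=False)
    rain_rows = [
        {"chrom": chrom, "pos": pos, "distance": dist}
        for chrom, pairs in intermutation_distances(substitutions).items()
        for pos, dist in pairs]
    pd.DataFrame(rain_rows, columns=["chrom", "pos", "distance"]).to_csv(
        pat_dir / "rainfall.tsv", sep="\t", index=False)

    # ---- stage: signatures ----------------------------------------------
    refit_summary = None
    if reference_path is not None:
        sig_dir = outdir / "signatures"
        sig_dir.mkdir(exist_ok=True)
        fasta = pyfaidx.Fasta(str(reference_path))
        somatic_sbs = [m for e in events
                       if e.origin_bin == "somatic" and e.category == "SBS"
                       for m in e.members]
        profile = build_profile(somatic_sbs, fasta, extended_flank=2)
        profile_table(profile).to_csv(sig_dir / "profile96.tsv", sep="\t",
                                      index=False)
        pd.DataFrame(sorted(profile.extended_counts.items()),
                     columns=["context", "count"]).to_csv(
            sig_dir / "extended_context.tsv", sep="\t", index=False)
        if catalog is not None and profile.n > 0:
            ranking = rank_signatures(profile, catalog)
            pd.DataFrame(ranking, columns=["signature", "cosine"]).round(6) \
                .to_csv(sig_dir / "ranking.tsv", sep="\t", index=False)
            refit = backwards_selection(profile, catalog,
                                        config.get("max_delta", 0.004))
            refit_summary = {
                "selected": refit.selected,
                "contributions": [round(float(c), 4)
                                  for c in refit.contributions],
                "trajectory": [[k, round(c, 6)]
                               for k, c in refit.similarity_trajectory],
                "final_cosine": round(refit.final_cosine, 6),
            }
            with open(sig_dir / "refit.json", "w") as fh:
                json.dump(refit_summary, fh, indent=2)
                fh.write("\n")

    counts = {
        "records_in": len(variants),
        "survivors": len(survivors),
        "germline": len(germline),
        "mosaic": len(mosaic),
        "above_germline": len(above),
        "timing_bins": {row["bin"]: int(row["total"])
                        for _, row in table.iterrows()},
        "events": {cat: sum(1 for e in events if e.category == cat)
                   for cat in ("SBS", "DBS", "CBS", "BBS")},
        "rejections": {row["filter"]: int(row["rejected"])
                       for _, row in rejections.iterrows()},
        "refit": refit_summary,
    }
    report = RunReport(
        parameters={"filter": config.get("filter", {}),
                    "bins": config.get("bins", "published"),
                    "boundaries": [round(b, 6) for b in model.boundaries]},
        input_digests=digests, stage_counts=counts,
        warnings=warnings_list, seed=seed)
    report.to_json(outdir / "report.json")
    return report


def _mean_proband_depth(variants) -> float | None:
    depths = [v.samples["proband"].depth for v in variants
              if v.samples["proband"].depth]
    return sum(depths) / len(depths) if depths else None


def compare_runs(report_a: RunReport, report_b: RunReport) -> pd.DataFrame:
    """Side-by-side per-bin and per-category counts with fold differences."""
    bins_a = report_a.stage_counts["timing_bins"]
    bins_b = report_b.stage_counts["timing_bins"]
    if set(bins_a) != set(bins_b):
        raise ComparisonError("runs use different timing-bin definitions")
    if report_a.parameters.get("bins") != report_b.parameters.get("bins"):
        raise ComparisonError("runs use different bin presets")
    rows = []
    for section, a, b in (("timing", bins_a, bins_b),
                          ("events", report_a.stage_counts["events"],
                           report_b.stage_counts["events"])):
        for key in a:
            ca, cb = a[key], b.get(key, 0)
            fold = (ca / cb) if cb else float("inf") if ca else 1.0
            rows.append({"section": section, "key": key, "run_a": ca,
                         "run_b": cb, "difference": ca - cb,
                         "fold": round(fold, 3)})
    return pd.DataFrame(rows, columns=["section", "key", "run_a", "run_b",
                                       "difference", "fold"])
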