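"""Readers and writers for the formats the pipeline touches.

Variants live in 1-based coordinates (VCF convention); BED intervals are
parsed as 0-based half-open and kept that way internally, converted once at
the membership query. Multi-allelic records are preserved as a single
variant with multiple alts, because biallelic substitutions (two alts at one
position) are a category of interest downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .contexts import CONTEXTS_96

TRIO_ROLES = ("proband", "mother", "father")

_ALLOWED = set("ACGTN")


class VcfConfigError(ValueError):
    """A requested sample role is absent from the VCF."""


class VcfParseError(ValueError):
    """A VCF record could not be mapped onto the trio model."""


class SignatureFormatError(ValueError):
    """A signature catalog file violates the 96-context contract."""


@dataclass
class SampleCall:
    """Per-sample evidence at one site."""

    depth: int | None
    alt_depths: tuple[int, ...] | None  # one entry per alt allele
    genotype: tuple[int | None, ...] | None


@dataclass
class TrioVariant:
    """One multi-sample variant record for a proband/mother/father trio."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    samples: dict[str, SampleCall]  # keyed by role
    site_metrics: dict[str, float] = field(default_factory=dict)
    qual: float | None = None
    usable: bool = True
    unusable_reason: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, *self.alts):
            if not allele or not set(allele) <= _ALLOWED:
                raise ValueError(f"non-sequence allele {allele!r} at "
                                 f"{self.chrom}:{self.pos}")
        if not self.alts or len(set(self.alts)) != len(self.alts):
            raise ValueError(f"alts must be non-empty and unique at "
                             f"{self.chrom}:{self.pos}")
        for role, call in self.samples.items():
            if call.depth is not None and call.alt_depths is not None:
                total_alt = sum(call.alt_depths)
                if not 0 <= total_alt <= call.depth:
                    raise ValueError(
                        f"alt depths {call.alt_depths} exceed depth "
                        f"{call.depth} for {role} at {self.chrom}:{self.pos}")

    def key(self, alt_index: int = 0) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alts[alt_index])


@dataclass
class RegionSet:
    """Excluded genomic intervals of one class (segdup/centromere/repeat).

    Intervals are 0-based half-open per chromosome, merged at load.
    """

    label: str
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, label: str,
                       intervals: list[tuple[str, int, int]]) -> "RegionSet":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"interval start >= end: {chrom}:{start}-{end}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in trees.values():
            tree.merge_overlaps(strict=False)
        return cls(label=label, trees=trees)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based variant position."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


@dataclass(frozen=True)
class PopulationBlacklist:
    """Exact-match set of (chrom, pos, ref, alt) keys seen in a population
    database; membership means the variant is too common to be de novo."""

    keys: frozenset[tuple[str, int, str, str]]

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


@dataclass
class SignatureSet:
    """A catalog of mutational signatures over the 96 trinucleotide classes.

    ``matrix`` is a (96, K) DataFrame indexed by canonical context order;
    each column is a probability distribution (sums to 1).
    """

    names: list[str]
    matrix: pd.DataFrame
    context_order: tuple[str, ...] = CONTEXTS_96

    def __post_init__(self) -> None:
        colsums = self.matrix.sum(axis=0)
        if not ((colsums - 1.0).abs() < 1e-6).all():
            raise SignatureFormatError("signature columns must sum to 1")

    def column(self, name: str):
        return self.matrix[name].to_numpy()


def read_vcf_trio(path: str, sample_roles: dict[str, str]) -> list[TrioVariant]:
    """Read a trio VCF into :class:`TrioVariant` records.

    ``sample_roles`` maps each of proband/mother/father to the VCF sample
    name. Records with missing allelic depth in any trio sample are emitted
    flagged ``usable=False``; symbolic (structural) alt alleles are skipped.
    """
    missing = [r for r in TRIO_ROLES if r not in sample_roles]
    if missing:
        raise VcfConfigError(f"sample_roles missing roles: {missing}")
    with pysam.VariantFile(path) as vcf:
        vcf_samples = list(vcf.header.samples)
        for role in TRIO_ROLES:
            if sample_roles[role] not in vcf_samples:
                raise VcfConfigError(
                    f"sample {sample_roles[role]!r} for role {role!r} "
                    f"not in VCF samples {vcf_samples}")
        out: list[TrioVariant] = []
        for line_no, rec in enumerate(vcf, start=1):
            alts = rec.alts or ()
            if any(a is None or not set(a.upper()) <= _ALLOWED for a in alts):
                warnings.warn(f"skipping symbolic/invalid alt at "
                              f"{rec.chrom}:{rec.pos}")
                continue
            if not alts:
                continue
            try:
                variant = _record_to_variant(rec, alts, sample_roles)
            except (KeyError, TypeError, ValueError) as exc:
                raise VcfParseError(
                    f"malformed record #{line_no} at {rec.chrom}:{rec.pos}: "
                    f"{exc}") from exc
            out.append(variant)
    return out


_INFO_KEYS = ("MQ", "ReadPosRankSum", "FS", "QD")


def _record_to_variant(rec, alts, sample_roles) -> TrioVariant:
    samples: dict[str, SampleCall] = {}
    unusable: str | None = None
    for role in TRIO_ROLES:
        s = rec.samples[sample_roles[role]]
        ad = s.get("AD")
        gt = s["GT"] if "GT" in s else None
        if gt is not None and all(a is None for a in gt):
            gt = None
        if ad is None or any(a is None for a in ad):
            samples[role] = SampleCall(depth=s.get("DP"), alt_depths=None,
                                       genotype=gt)
            unusable = f"missing AD for {role}"
            continue
        ad = tuple(int(a) for a in ad)
        dp = s.get("DP")
        depth = int(dp) if dp is not None else sum(ad)
        alt_depths = ad[1:1 + len(alts)]
        # AD can exceed DP on pathological records; clamp depth up so the
        # invariant (sum alt <= depth) stays meaningful.
        depth = max(depth, sum(alt_depths))
        samples[role] = SampleCall(depth=depth, alt_depths=alt_depths,
                                   genotype=gt)
    metrics = {}
    for key in _INFO_KEYS:
        if key in rec.info:
            val = rec.info[key]
            if isinstance(val, tuple):
                val = val[0]
            if val is not None:
                metrics[key] = float(val)
    return TrioVariant(
        chrom=rec.chrom, pos=rec.pos, ref=rec.ref.upper(),
        alts=tuple(a.upper() for a in alts), samples=samples,
        site_metrics=metrics,
        qual=float(rec.qual) if rec.qual is not None else None,
        usable=unusable is None, unusable_reason=unusable)


def write_vcf_trio(variants: list[TrioVariant], path: str,
                   sample_names: dict[str, str] | None = None,
                   contig_lengths: dict[str, int] | None = None) -> None:
    """Write trio variants as an uncompressed VCF 4.2 text file.

    Output is deterministic (no timestamps); floats are written with 4
    decimals. Readable back via :func:`read_vcf_trio`.
    """
    names = sample_names or {r: r for r in TRIO_ROLES}
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for chrom, length in contig_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    else:
        for chrom in dict.fromkeys(v.chrom for v in variants):
            lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (PHRED)">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(names[r] for r in TRIO_ROLES),
    ]
    for v in variants:
        info = ";".join(f"{k}={v.site_metrics[k]:.4f}"
                        for k in _INFO_KEYS if k in v.site_metrics) or "."
        qual = f"{v.qual:.4f}" if v.qual is not None else "."
        cols = [v.chrom, str(v.pos), ".", v.ref, ",".join(v.alts), qual,
                ".", info, "GT:AD:DP"]
        for role in TRIO_ROLES:
            call = v.samples[role]
            gt = ("/".join("." if a is None else str(a) for a in call.genotype)
                  if call.genotype is not None else "./.")
            if call.alt_depths is None:
                ad = "."
                dp = str(call.depth) if call.depth is not None else "."
            else:
                ref_depth = call.depth - sum(call.alt_depths)
                ad = ",".join(str(d) for d in (ref_depth, *call.alt_depths))
                dp = str(call.depth)
            cols.append(f"{gt}:{ad}:{dp}")
        lines.append("\t".join(cols))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_regions_bed(path: str, label: str) -> RegionSet:
    """Read a BED3 file of excluded regions; overlapping intervals merge."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{line_no}: start >= end")
            intervals.append((chrom, start, end))
    return RegionSet.from_intervals(label, intervals)


def write_regions_bed(regions: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(regions.trees):
            for iv in sorted(regions.trees[chrom]):
                fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\n")


def read_blacklist(path: str) -> PopulationBlacklist:
    """Read a TSV of (chrom, pos, ref, alt) population-database keys."""
    keys = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            keys.add((chrom, int(pos), ref, alt))
    return PopulationBlacklist(keys=frozenset(keys))


def write_blacklist(keys, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, pos, ref, alt in sorted(keys):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def read_signature_matrix(path: str) -> SignatureSet:
    """Read a COSMIC-style signature TSV (context column in A[C>A]A
    notation, one column per signature).

    Rows are reordered to canonical context order and columns renormalized
    to sum to 1.
    """
    df = pd.read_csv(path, sep="\t")
    context_col = df.columns[0]
    df = df.set_index(context_col)
    missing = [c for c in CONTEXTS_96 if c not in df.index]
    if missing:
        raise SignatureFormatError(
            f"catalog missing {len(missing)} contexts: {missing[:5]}...")
    extra = [c for c in df.index if c not in CONTEXTS_96]
    if extra:
        raise SignatureFormatError(f"unknown context labels: {extra[:5]}")
    df = df.loc[list(CONTEXTS_96)]
    if (df.to_numpy() < 0).any():
        raise SignatureFormatError("negative entry in signature catalog")
    colsums = df.sum(axis=0)
    if (colsums <= 0).any():
        raise SignatureFormatError("signature column sums to zero")
    df = df / colsums
    return SignatureSet(names=list(df.columns), matrix=df)


def write_signature_matrix(sigs: SignatureSet, path: str) -> None:
    sigs.matrix.rename_axis("Type").round(8).to_csv(path, sep="\t")
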