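"""Self-contained synthetic trio generator with known truth.

Emulates the statistical structure the downstream analysis assumes: a
proband carrying inherited heterozygous variants, germline de novo variants
(expected VAF 0.5), postzygotic mosaic variants from the first and second
mitotic divisions (expected VAFs 0.25 and 0.125), sub-threshold noise at
the third-division VAF (0.0625), planted doublet/clustered/biallelic
substitution events, and decoy variants designed to be caught by specific
filters (population-blacklist hits, excluded-region hits, single-alt-read
sites, hard-filter failures).

Read counts follow the read-sampling model of the analysis: per-sample
depth is negative-binomial around the configured mean (truncated at 1;
optionally fixed), and proband alternate reads are Binomial(depth, VAF
parameter). Parents carry zero alternate reads for de novo classes (a
config switch injects single-read parental contamination). Somatic
substitution contexts are drawn from a configurable signature mixture, and
positions are chosen so the planted reference base matches the reference
FASTA.

All randomness flows from one seed; re-runs are byte-identical.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx
import yaml

from .contexts import BASES, COMPLEMENT, PYRIMIDINE_TRINUCS, parse_context, revcomp
from .io import (RegionSet, SampleCall, SignatureSet, TrioVariant,
                 write_blacklist, write_regions_bed, write_vcf_trio)

#: expected VAF parameter per origin class
CLASS_VAF = {
    "inherited": 0.5,
    "germline": 0.5,
    "first_mitosis": 0.25,
    "second_mitosis": 0.125,
    "noise": 0.0625,
}

EVENT_VAF = 0.25  # planted multi-member events ride the first-mitosis lobe
BBS_MEMBER_VAF = 0.125  # each biallelic member in its own cell lineage

DECOY_VAF = 0.25
MIN_EVENT_GAP = 101  # bp kept free around planted variants/events

REGION_LABELS = ("segdup", "centromere", "repeat")


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic trio; defaults are the study conditions."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 250_000, "chr2": 250_000})
    mean_depth: int = 50
    depth_dispersion: float | None = 80.0  # None -> fixed depth
    class_counts: dict[str, int] = field(default_factory=lambda: {
        "inherited": 100, "germline": 45,
        "first_mitosis": 400, "second_mitosis": 400, "noise": 60})
    event_rates: dict[str, int] = field(
        default_factory=lambda: {"DBS": 9, "CBS": 13, "BBS": 3})
    decoy_counts: dict[str, int] = field(default_factory=lambda: {
        "blacklist": 10, "region": 10, "low_alt": 10, "hard_filter": 10})
    signature_mixture: dict[str, float] | None = None
    contaminated_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            if length < 1000:
                raise ValueError(f"chromosome {name} shorter than 1 kb")
        for mapping in (self.class_counts, self.event_rates,
                        self.decoy_counts):
            for key, count in mapping.items():
                if count < 0:
                    raise ValueError(f"negative count for {key}")
        if self.signature_mixture is not None:
            total = sum(self.signature_mixture.values())
            if total <= 0 or any(w < 0 for w in
                                 self.signature_mixture.values()):
                raise ValueError("signature_mixture weights must be "
                                 "non-negative with positive sum")
            self.signature_mixture = {k: w / total for k, w
                                      in self.signature_mixture.items()}

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SimulatedTrio:
    """File paths and truth for one simulated dataset."""

    vcf: Path
    truth: pd.DataFrame
    truth_path: Path
    blacklist_path: Path
    region_beds: dict[str, Path]
    reference_path: Path
    config: SimulationConfig


def sample_vafs(n: int, p: float, depth: int,
                rng: np.random.Generator) -> np.ndarray:
    """VAFs of n variants under binomial read sampling at fixed depth."""
    return rng.binomial(depth, p, size=n) / depth


def simulate_reference(config: SimulationConfig, fasta_path: str) -> Path:
    """Write a seeded random reference FASTA (plus .fai index).

    Every chromosome is regenerated until all 32 pyrimidine-centred
    trinucleotides occur at least once.
    """
    rng = np.random.default_rng([config.seed, 11])
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        for chrom, length in config.chrom_lengths.items():
            for attempt in range(50):
                seq = "".join(rng.choice(list(BASES), size=length))
                present = {seq[i:i + 3] for i in range(length - 2)}
                if all(t in present or revcomp(t) in present
                       for t in PYRIMIDINE_TRINUCS):
                    break
            else:
                raise GenerationError(
                    f"could not cover all trinucleotide contexts on {chrom}")
            fh.write(f">{chrom}\n")
            for i in range(0, length, 80):
                fh.write(seq[i:i + 80] + "\n")
    pyfaidx.Faidx(str(fasta_path))  # build .fai
    return fasta_path


class _PositionPool:
    """Reserves variant positions with a guard gap, per chromosome."""

    def __init__(self, chrom_lengths: dict[str, int]):
        self.reserved: dict[str, list[int]] = {c: [] for c in chrom_lengths}
        self.lengths = chrom_lengths

    def free(self, chrom: str, start: int, end: int,
             gap: int = MIN_EVENT_GAP) -> bool:
        lst = self.reserved[chrom]
        i = bisect.bisect_left(lst, start - gap)
        return not (i < len(lst) and lst[i] <= end + gap)

    def reserve(self, chrom: str, positions: list[int]) -> None:
        for pos in positions:
            bisect.insort(self.reserved[chrom], pos)


def _context_position_index(sequences: dict[str, str]
                            ) -> dict[str, dict[str, np.ndarray]]:
    """Per chromosome: trinucleotide string -> 0-based center positions."""
    code_of = {b: i for i, b in enumerate(BASES)}
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, seq in sequences.items():
        enc = np.fromiter((code_of[b] for b in seq), dtype=np.int16,
                          count=len(seq))
        codes = 16 * enc[:-2] + 4 * enc[1:-1] + enc[2:]
        index: dict[str, np.ndarray] = {}
        for c in range(64):
            tri = BASES[c // 16] + BASES[(c // 4) % 4] + BASES[c % 4]
            index[tri] = np.nonzero(codes == c)[0] + 1  # 0-based centers
        out[chrom] = index
    return out


def _mixture_context_probs(signatures: SignatureSet | None,
                           mixture: dict[str, float] | None) -> np.ndarray:
    if signatures is None or mixture is None:
        return np.full(96, 1 / 96)
    weights = np.array([mixture.get(name, 0.0) for name in signatures.names])
    probs = signatures.matrix.to_numpy() @ weights
    return probs / probs.sum()


@dataclass
class _Planted:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    origin: str
    category: str
    p_vafs: tuple[float, ...]
    context: str = ""
    signature: str = ""
    event_id: int = -1  # members of one event share read support


def simulate_trio(config: SimulationConfig, reference_path: str,
                  outdir: str,
                  signatures: SignatureSet | None = None) -> SimulatedTrio:
    """Generate the trio VCF, truth table, blacklist and exclusion BEDs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 23])
    fasta = pyfaidx.Fasta(str(reference_path))
    sequences = {name: str(fasta[name][:]).upper()
                 for name in config.chrom_lengths}
    ctx_index = _context_position_index(sequences)
    pool = _PositionPool(config.chrom_lengths)
    chroms = list(config.chrom_lengths)
    probs96 = _mixture_context_probs(signatures, config.signature_mixture)
    sig_names, sig_probs = _per_signature_context_probs(
        signatures, config.signature_mixture)

    planted: list[_Planted] = []
    next_event = 0

    def random_site(max_tries: int = 500) -> tuple[str, int]:
        for _ in range(max_tries):
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(3, config.chrom_lengths[chrom] - 1))
            if pool.free(chrom, pos, pos):
                pool.reserve(chrom, [pos])
                return chrom, pos
        raise GenerationError("no free positions left; use a longer genome")

    def draw_context_site(max_tries: int = 500
                          ) -> tuple[str, int, str, str, str, str]:
        """Pick a mixture-drawn context and a matching reference position.

        Returns (chrom, pos, ref, alt, context_label, signature_name).
        """
        for _ in range(max_tries):
            if sig_names:
                sig_i = rng.choice(len(sig_names),
                                   p=[config.signature_mixture[n]
                                      for n in sig_names])
                sig_name = sig_names[sig_i]
                ctx_i = rng.choice(96, p=sig_probs[sig_i])
            else:
                sig_name = ""
                ctx_i = rng.choice(96, p=probs96)
            from .contexts import CONTEXTS_96
            label = CONTEXTS_96[ctx_i]
            five, ref_pyr, alt_pyr, three = parse_context(label)
            tri = five + ref_pyr + three
            chrom = chroms[rng.integers(len(chroms))]
            fwd = ctx_index[chrom][tri]
            rev = ctx_index[chrom][revcomp(tri)]
            n_fwd, n_rev = len(fwd), len(rev)
            if n_fwd + n_rev == 0:
                continue
            k = int(rng.integers(n_fwd + n_rev))
            if k < n_fwd:
                center0, ref, alt = int(fwd[k]), ref_pyr, alt_pyr
            else:
                center0 = int(rev[k - n_fwd])
                ref, alt = COMPLEMENT[ref_pyr], COMPLEMENT[alt_pyr]
            pos = center0 + 1
            if pos < 3 or pos > config.chrom_lengths[chrom] - 2:
                continue
            if not pool.free(chrom, pos, pos):
                continue
            pool.reserve(chrom, [pos])
            return chrom, pos, ref, alt, label, sig_name
        raise GenerationError(
            "could not place requested context; use a longer genome")

    def random_alt(ref: str) -> str:
        choices = [b for b in BASES if b != ref]
        return choices[rng.integers(3)]

    # ---- multi-member events --------------------------------------------
    for _ in range(config.event_rates.get("DBS", 0)):
        chrom, pos = _reserve_span(pool, rng, chroms, config, span=1)
        refs = sequences[chrom][pos - 1:pos + 1]
        planted += [
            _Planted(chrom, pos + i, refs[i], (random_alt(refs[i]),),
                     "first_mitosis", "DBS", (EVENT_VAF,),
                     event_id=next_event)
            for i in range(2)]
        next_event += 1
    for _ in range(config.event_rates.get("CBS", 0)):
        k = int(rng.integers(2, 4))  # 2 or 3 members
        if k == 2:
            gaps = [int(rng.integers(2, CLUSTER_GAP_MAX))]
        else:
            gaps = [int(rng.integers(1, 25)) for _ in range(2)]
            if gaps == [1] * 2 or sum(gaps) >= CLUSTER_GAP_MAX:
                gaps = [2, 3]
        span = sum(gaps)
        chrom, pos = _reserve_span(pool, rng, chroms, config, span=span)
        offsets = np.cumsum([0] + gaps)
        for off in offsets:
            ref = sequences[chrom][pos - 1 + off]
            planted.append(
                _Planted(chrom, pos + int(off), ref, (random_alt(ref),),
                         "first_mitosis", "CBS", (EVENT_VAF,),
                         event_id=next_event))
        next_event += 1
    for _ in range(config.event_rates.get("BBS", 0)):
        chrom, pos = random_site()
        ref = sequences[chrom][pos - 1]
        others = [b for b in BASES if b != ref]
        a1, a2 = rng.choice(others, size=2, replace=False)
        planted.append(
            _Planted(chrom, pos, ref, (str(a1), str(a2)), "second_mitosis",
                     "BBS", (BBS_MEMBER_VAF, BBS_MEMBER_VAF),
                     event_id=next_event))
        next_event += 1

    # ---- plain single-base classes --------------------------------------
    for origin in ("first_mitosis", "second_mitosis", "noise"):
        for _ in range(config.class_counts.get(origin, 0)):
            chrom, pos, ref, alt, label, sig = draw_context_site()
            planted.append(_Planted(chrom, pos, ref, (alt,), origin, "SBS",
                                    (CLASS_VAF[origin],), label, sig))
    for origin in ("germline", "inherited"):
        for _ in range(config.class_counts.get(origin, 0)):
            chrom, pos = random_site()
            ref = sequences[chrom][pos - 1]
            planted.append(_Planted(chrom, pos, ref, (random_alt(ref),),
                                    origin, "SBS", (CLASS_VAF[origin],)))

    # ---- decoys ----------------------------------------------------------
    blacklist_keys: set[tuple[str, int, str, str]] = set()
    region_intervals: dict[str, list[tuple[str, int, int]]] = {
        lab: [] for lab in REGION_LABELS}
    hard_filter_failures = (("FS", 70.0), ("QD", 1.0), ("MQ", 25.0),
                            ("ReadPosRankSum", -9.0))
    for i in range(config.decoy_counts.get("blacklist", 0)):
        chrom, pos = random_site()
        ref = sequences[chrom][pos - 1]
        alt = random_alt(ref)
        planted.append(_Planted(chrom, pos, ref, (alt,), "decoy:blacklist",
                                "SBS", (DECOY_VAF,)))
        blacklist_keys.add((chrom, pos, ref, alt))
    for i in range(config.decoy_counts.get("region", 0)):
        chrom, pos = random_site()
        ref = sequences[chrom][pos - 1]
        label = REGION_LABELS[i % len(REGION_LABELS)]
        planted.append(_Planted(chrom, pos, ref, (random_alt(ref),),
                                f"decoy:region:{label}", "SBS", (DECOY_VAF,)))
        region_intervals[label].append((chrom, pos - 11, pos + 10))
    for i in range(config.decoy_counts.get("low_alt", 0)):
        chrom, pos = random_site()
        ref = sequences[chrom][pos - 1]
        planted.append(_Planted(chrom, pos, ref, (random_alt(ref),),
                                "decoy:low_alt", "SBS", (DECOY_VAF,)))
    for i in range(config.decoy_counts.get("hard_filter", 0)):
        chrom, pos = random_site()
        ref = sequences[chrom][pos - 1]
        metric, _ = hard_filter_failures[i % len(hard_filter_failures)]
        planted.append(_Planted(chrom, pos, ref, (random_alt(ref),),
                                f"decoy:hard_filter:{metric}", "SBS",
                                (DECOY_VAF,)))
    # extra blacklist keys that match no emitted variant
    for _ in range(5):
        chrom, pos = random_site()
        ref = sequences[chrom][pos - 1]
        blacklist_keys.add((chrom, pos, ref, random_alt(ref)))
    # extra empty exclusion regions away from any variant
    for i, label in enumerate(REGION_LABELS):
        chrom, pos = random_site()
        region_intervals[label].append((chrom, pos - 1, pos + 200))

    # ---- read sampling and record assembly -------------------------------
    chrom_rank = {c: i for i, c in enumerate(chroms)}
    planted.sort(key=lambda p: (chrom_rank[p.chrom], p.pos, p.alts))
    variants, truth_rows = _sample_reads(planted, config, rng,
                                         hard_filter_failures, sequences)

    vcf_path = outdir / "trio.vcf"
    write_vcf_trio(variants, str(vcf_path),
                   contig_lengths=config.chrom_lengths)
    truth = pd.DataFrame(truth_rows, columns=[
        "chrom", "pos", "ref", "alt", "origin", "category", "context",
        "signature", "p_vaf", "event_id"])
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    blacklist_path = outdir / "blacklist.tsv"
    write_blacklist(blacklist_keys, str(blacklist_path))
    region_beds = {}
    for label in REGION_LABELS:
        rs = (RegionSet.from_intervals(label, region_intervals[label])
              if region_intervals[label] else RegionSet(label=label))
        path = outdir / f"{label}.bed"
        write_regions_bed(rs, str(path))
        region_beds[label] = path
    return SimulatedTrio(vcf=vcf_path, truth=truth, truth_path=truth_path,
                         blacklist_path=blacklist_path,
                         region_beds=region_beds,
                         reference_path=Path(reference_path), config=config)


CLUSTER_GAP_MAX = 50


def _per_signature_context_probs(signatures: SignatureSet | None,
                                 mixture: dict[str, float] | None):
    if signatures is None or mixture is None:
        return [], []
    names = [n for n in signatures.names if mixture.get(n, 0.0) > 0]
    probs = []
    for n in names:
        col = signatures.column(n)
        probs.append(col / col.sum())
    return names, probs


def _reserve_span(pool: _PositionPool, rng, chroms, config,
                  span: int, max_tries: int = 500) -> tuple[str, int]:
    for _ in range(max_tries):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(3, config.chrom_lengths[chrom] - 1 - span))
        if pool.free(chrom, pos, pos + span):
            pool.reserve(chrom, [pos, pos + span])
            return chrom, pos
    raise GenerationError("no free span left; use a longer genome")


def _draw_depth(config: SimulationConfig, rng) -> int:
    if config.depth_dispersion is None:
        return config.mean_depth
    r = config.depth_dispersion
    m = config.mean_depth
    return max(1, int(rng.negative_binomial(r, r / (r + m))))


def _passing_metrics(rng) -> dict[str, float]:
    return {
        "MQ": round(float(np.clip(rng.normal(60, 1.5), 40, 70)), 2),
        "ReadPosRankSum": round(float(rng.normal(0, 0.8)), 3),
        "FS": round(abs(float(rng.normal(0, 2))), 3),
        "QD": round(float(np.clip(rng.normal(15, 3), 3, None)), 2),
    }


def _sample_reads(planted: list[_Planted], config: SimulationConfig, rng,
                  hard_filter_failures, sequences):
    variants: list[TrioVariant] = []
    truth_rows: list[dict] = []
    event_support: dict[int, tuple[int, int]] = {}  # event_id -> (depth, alt)
    fail_values = dict(hard_filter_failures)
    for p in planted:
        depths = {role: _draw_depth(config, rng)
                  for role in ("proband", "mother", "father")}
        metrics = _passing_metrics(rng)
        if p.origin.startswith("decoy:hard_filter:"):
            metric = p.origin.rsplit(":", 1)[1]
            metrics[metric] = fail_values[metric]

        if p.category == "BBS":
            dp = depths["proband"]
            alt1 = int(rng.binomial(dp, p.p_vafs[0]))
            alt2 = int(rng.binomial(dp - alt1, p.p_vafs[1] / (1 - p.p_vafs[0])))
            alt_depths = (alt1, alt2)
            gt = (1, 2)
        elif p.event_id >= 0:
            if p.event_id not in event_support:
                dp = depths["proband"]
                event_support[p.event_id] = (dp, int(rng.binomial(
                    dp, p.p_vafs[0])))
            dp, alt = event_support[p.event_id]
            depths["proband"] = dp
            alt_depths = (alt,)
            gt = (0, 1)
        else:
            dp = depths["proband"]
            if p.origin == "decoy:low_alt":
                alt_depths = (1,)
            else:
                alt_depths = (int(rng.binomial(dp, p.p_vafs[0])),)
            gt = (0, 1)

        samples = {"proband": SampleCall(depth=depths["proband"],
                                         alt_depths=alt_depths,
                                         genotype=gt)}
        if p.origin == "inherited":
            carrier = ("mother", "father")[int(rng.integers(2))]
            for role in ("mother", "father"):
                if role == carrier:
                    alt = int(rng.binomial(depths[role], 0.5))
                    samples[role] = SampleCall(depths[role],
                                               (alt,) * len(p.alts)
                                               if len(p.alts) == 1
                                               else (alt, 0),
                                               (0, 1))
                else:
                    samples[role] = SampleCall(depths[role],
                                               (0,) * len(p.alts), (0, 0))
        else:
            contaminated = (config.contaminated_fraction > 0
                            and rng.uniform() < config.contaminated_fraction)
            victim = ("mother", "father")[int(rng.integers(2))]
            for role in ("mother", "father"):
                reads = 1 if (contaminated and role == victim) else 0
                ad = tuple(reads if i == 0 else 0
                           for i in range(len(p.alts)))
                samples[role] = SampleCall(depths[role], ad, (0, 0))
        variants.append(TrioVariant(
            chrom=p.chrom, pos=p.pos, ref=p.ref, alts=p.alts,
            samples=samples, site_metrics=metrics,
            qual=round(float(rng.uniform(100, 1000)), 2)))
        for alt, p_vaf in zip(p.alts, p.p_vafs):
            context = p.context or _context_of(sequences, p.chrom, p.pos,
                                               p.ref, alt)
            truth_rows.append({
                "chrom": p.chrom, "pos": p.pos, "ref": p.ref, "alt": alt,
                "origin": p.origin, "category": p.category,
                "context": context, "signature": p.signature,
                "p_vaf": p_vaf, "event_id": p.event_id,
            })
    return variants, truth_rows


def _context_of(sequences, chrom, pos, ref, alt) -> str:
    from .contexts import collapse_substitution

    seq = sequences[chrom]
    return collapse_substitution(seq[pos - 2], ref, alt, seq[pos])
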