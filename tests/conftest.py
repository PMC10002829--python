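"""Shared fixtures: fixture signature catalogs, a default synthetic trio,
and independent brute-force oracles used by several test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dnmosaic.contexts import CONTEXTS_96
from dnmosaic.filtering import FilterParams, filter_trio
from dnmosaic.io import (SampleCall, SignatureSet, TrioVariant, read_blacklist,
                         read_regions_bed, read_vcf_trio,
                         write_signature_matrix)
from dnmosaic.patterns import CLUSTER_BP, Substitution, SubstitutionEvent
from dnmosaic.simulate import (SimulationConfig, simulate_reference,
                               simulate_trio)

TRIO = ("proband", "mother", "father")
ROLES = {r: r for r in TRIO}


# --------------------------------------------------------------------------
# fixture catalogs
# --------------------------------------------------------------------------

def disjoint_catalog() -> SignatureSet:
    """Two signatures uniform over disjoint halves of the 96 contexts, so
    NNLS contributions are identifiable exactly."""
    m = np.zeros((96, 2))
    m[:48, 0] = 1 / 48
    m[48:, 1] = 1 / 48
    return SignatureSet(names=["S1", "S2"],
                        matrix=pd.DataFrame(m, index=list(CONTEXTS_96),
                                            columns=["S1", "S2"]))


def five_signature_catalog() -> SignatureSet:
    """S1/S2 as in the disjoint fixture plus three seeded random
    signatures, for backwards-elimination tests."""
    rng = np.random.default_rng(42)
    m = np.zeros((96, 5))
    m[:48, 0] = 1 / 48
    m[48:, 1] = 1 / 48
    for k in range(2, 5):
        col = rng.uniform(0.1, 1.0, size=96)
        m[:, k] = col / col.sum()
    names = [f"S{k + 1}" for k in range(5)]
    return SignatureSet(names=names,
                        matrix=pd.DataFrame(m, index=list(CONTEXTS_96),
                                            columns=names))


@pytest.fixture(scope="session")
def fixture_catalog() -> SignatureSet:
    return disjoint_catalog()


@pytest.fixture(scope="session")
def catalog_path(tmp_path_factory, fixture_catalog):
    path = tmp_path_factory.mktemp("catalog") / "catalog.tsv"
    write_signature_matrix(fixture_catalog, str(path))
    return path


# --------------------------------------------------------------------------
# trio variant construction helpers
# --------------------------------------------------------------------------

def make_variant(chrom="chr1", pos=1000, ref="C", alts=("T",),
                 proband=(50, (12,), (0, 1)),
                 mother=(50, (0,), (0, 0)),
                 father=(50, (0,), (0, 0)),
                 metrics=None, qual=500.0, usable=True,
                 unusable_reason=None) -> TrioVariant:
    """A trio variant that passes every default filter unless overridden."""
    if metrics is None:
        metrics = {"MQ": 60.0, "ReadPosRankSum": 0.0, "FS": 1.0, "QD": 15.0}
    samples = {role: SampleCall(depth=v[0], alt_depths=v[1], genotype=v[2])
               for role, v in zip(TRIO, (proband, mother, father))}
    return TrioVariant(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts),
                       samples=samples, site_metrics=metrics, qual=qual,
                       usable=usable, unusable_reason=unusable_reason)


# --------------------------------------------------------------------------
# default synthetic dataset (shared, seeded)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """Default-config simulation at seed 1, already filtered."""
    outdir = tmp_path_factory.mktemp("sim_default")
    config = SimulationConfig(seed=1)
    reference = simulate_reference(config, outdir / "reference.fa")
    sim = simulate_trio(config, reference, outdir)
    variants = read_vcf_trio(str(sim.vcf), ROLES)
    regions = [read_regions_bed(str(p), lab)
               for lab, p in sim.region_beds.items()]
    blacklist = read_blacklist(str(sim.blacklist_path))
    survivors, audit = filter_trio(variants, FilterParams(), regions,
                                   blacklist)
    return {"sim": sim, "variants": variants, "regions": regions,
            "blacklist": blacklist, "survivors": survivors, "audit": audit}


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def brute_force_group(substitutions: list[Substitution]
                      ) -> list[tuple[str, frozenset]]:
    """Exhaustive interval-graph clustering oracle for event grouping.

    Within each (origin, chromosome): sites with >=2 distinct alts are
    biallelic events; the rest form a graph with edges between members
    closer than the cluster threshold, whose connected components are
    classified by the category rules. Returns (category, member key set)
    pairs, order-free.
    """
    out = []
    groups: dict[tuple[str, str], list[Substitution]] = {}
    for s in substitutions:
        groups.setdefault((s.origin_bin, s.chrom), []).append(s)
    for subs in groups.values():
        by_pos: dict[int, list[Substitution]] = {}
        for s in subs:
            by_pos.setdefault(s.pos, []).append(s)
        rest = []
        for pos, site in by_pos.items():
            if len({s.alt for s in site}) >= 2:
                out.append(("BBS", frozenset((s.pos, s.ref, s.alt)
                                             for s in site)))
            else:
                rest.extend(site)
        # connected components of the <50bp proximity graph
        n = len(rest)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if abs(rest[i].pos - rest[j].pos) < CLUSTER_BP:
                    parent[find(i)] = find(j)
        comps: dict[int, list[Substitution]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(rest[i])
        for members in comps.values():
            members.sort(key=lambda s: s.pos)
            if len(members) == 1:
                cat = "SBS"
            elif (len(members) == 2
                  and members[1].pos - members[0].pos == 1):
                cat = "DBS"
            else:
                cat = "CBS"
            out.append((cat, frozenset((s.pos, s.ref, s.alt)
                                       for s in members)))
    return out


def event_key_set(events: list[SubstitutionEvent]
                  ) -> set[tuple[str, frozenset]]:
    return {(e.category, frozenset((m.pos, m.ref, m.alt) for m in e.members))
            for e in events}


def recheck_filter(variant: TrioVariant, alt_index: int, regions, blacklist,
                   params: FilterParams) -> bool:
    """Straightforward independent re-evaluation of the filter cascade for
    one variant/alt pair (conjunction, no ordering, no audit)."""
    if not variant.usable:
        return False
    alt = variant.alts[alt_index]
    proband = variant.samples["proband"]
    parents = [variant.samples[r] for r in ("mother", "father")]
    if any(p.genotype is None for p in parents):
        return False
    if any(a != 0 for p in parents for a in p.genotype):
        return False
    if any(s.depth < params.min_depth_all_samples
           for s in variant.samples.values()):
        return False
    if proband.alt_depths[alt_index] < params.min_proband_alt_reads:
        return False
    if any(p.alt_depths[alt_index] > params.max_parent_alt_reads
           for p in parents):
        return False
    if proband.alt_depths[alt_index] / proband.depth > params.max_vaf:
        return False
    if blacklist is not None and (variant.chrom, variant.pos, variant.ref,
                                  alt) in blacklist:
        return False
    if any(rs.contains(variant.chrom, variant.pos) for rs in regions):
        return False
    vclass = "SNV" if len(variant.ref) == 1 and len(alt) == 1 else "indel"
    for name, op, threshold in params.hard_filters[vclass]:
        observed = variant.site_metrics.get(name)
        if observed is None:
            continue
        if op == ">" and not observed > threshold:
            return False
        if op == "<" and not observed < threshold:
            return False
    return True
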