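"""Grouping of de novo substitutions into SBS/DBS/CBS/BBS events and
transition/transversion accounting.

Categories: a biallelic base substitution (BBS) is two alternate alleles at
one position; a doublet (DBS) is exactly two substitutions at adjacent
positions with nothing else within 50 bp; a cluster (CBS) is any maximal
group of two or more substitutions whose consecutive gaps are all < 50 bp
and that is not a pure doublet; everything else is a single-base
substitution (SBS). Equal-length multi-base variant calls are decomposed
into per-base substitutions first, so a called dinucleotide variant and two
adjacent single-base calls both yield a DBS. Events never mix origin bins
(germline and somatic members are grouped separately).

Transition = purine<->purine or pyrimidine<->pyrimidine (A<->G, C<->T);
everything else is a transversion. Ti/Tv tables count every member base of
SBS/DBS/CBS events; BBS events enter the totals as events with Ti/Tv marked
not-applicable.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

CLUSTER_BP = 50  # members closer than this (strictly) chain into a cluster

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

SBS = "SBS"
DBS = "DBS"
CBS = "CBS"
BBS = "BBS"
CATEGORY_ORDER = (SBS, DBS, CBS, BBS)


@dataclass(frozen=True)
class Substitution:
    """One single-base substitution (decomposed if called as an MNV)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    origin_bin: str = "somatic"


@dataclass
class SubstitutionEvent:
    category: str
    members: list[Substitution]
    origin_bin: str

    @property
    def span(self) -> int:
        return self.members[-1].pos - self.members[0].pos

    @property
    def n_members(self) -> int:
        return len(self.members)


def is_transition(ref: str, alt: str) -> bool:
    """True for A<->G and C<->T changes."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    pair = {ref, alt}
    return pair <= PURINES or pair <= PYRIMIDINES


def decompose_to_substitutions(candidates) -> list[Substitution]:
    """Turn SNV and equal-length MNV candidates into per-base substitutions.

    Indels (length-changing alleles) are excluded from the taxonomy.
    MNV bases that equal the reference are not substitutions and are
    dropped.
    """
    subs: list[Substitution] = []
    for cand in candidates:
        ref, alt = cand.ref, cand.alt
        if len(ref) != len(alt):
            continue
        origin = getattr(cand, "origin_bin", "somatic")
        for offset, (rb, ab) in enumerate(zip(ref, alt)):
            if rb != ab:
                subs.append(Substitution(cand.chrom, cand.pos + offset,
                                         rb, ab, origin))
    return subs


def group_events(substitutions: list[Substitution]) -> list[SubstitutionEvent]:
    """Partition position-sorted substitutions into SBS/DBS/CBS/BBS events.

    Precedence: co-located alts form a BBS; remaining members chain into
    maximal <50 bp clusters, which are DBS when they are exactly an
    adjacent pair and CBS otherwise; singletons are SBS. Grouping is done
    within each origin bin and chromosome independently.
    """
    _require_sorted(substitutions)
    events: list[SubstitutionEvent] = []
    by_group: dict[tuple[str, str], list[Substitution]] = {}
    for sub in substitutions:
        by_group.setdefault((sub.origin_bin, sub.chrom), []).append(sub)
    for (origin, _chrom), subs in by_group.items():
        events.extend(_group_chromosome(subs, origin))
    events.sort(key=lambda e: (e.members[0].chrom, e.members[0].pos))
    return events


def _require_sorted(substitutions: list[Substitution]) -> None:
    seen: dict[str, int] = {}
    last_chrom = None
    for sub in substitutions:
        if sub.chrom != last_chrom:
            if sub.chrom in seen and last_chrom is not None:
                raise ValueError("input not grouped by chromosome")
            seen[sub.chrom] = sub.pos
            last_chrom = sub.chrom
        elif sub.pos < seen[sub.chrom]:
            raise ValueError("input not position-sorted")
        else:
            seen[sub.chrom] = sub.pos


def _group_chromosome(subs: list[Substitution],
                      origin: str) -> list[SubstitutionEvent]:
    events: list[SubstitutionEvent] = []
    # site precedence: >=2 distinct alts at one position -> BBS
    by_pos: dict[int, list[Substitution]] = {}
    for sub in subs:
        by_pos.setdefault(sub.pos, []).append(sub)
    remaining: list[Substitution] = []
    for pos in sorted(by_pos):
        site = by_pos[pos]
        if len({s.alt for s in site}) >= 2:
            events.append(SubstitutionEvent(BBS, site, origin))
        else:
            remaining.extend(site)
    # neighbourhood: chain consecutive gaps < CLUSTER_BP
    cluster: list[Substitution] = []
    for sub in remaining + [None]:  # sentinel flushes the last cluster
        if cluster and (sub is None
                        or sub.pos - cluster[-1].pos >= CLUSTER_BP):
            events.append(_classify_cluster(cluster, origin))
            cluster = []
        if sub is not None:
            cluster.append(sub)
    return events


def _classify_cluster(cluster: list[Substitution],
                      origin: str) -> SubstitutionEvent:
    if len(cluster) == 1:
        return SubstitutionEvent(SBS, cluster, origin)
    if len(cluster) == 2 and cluster[1].pos - cluster[0].pos == 1:
        return SubstitutionEvent(DBS, cluster, origin)
    return SubstitutionEvent(CBS, cluster, origin)


def format_ratio(transitions: int, transversions: int) -> str:
    """Ti/Tv for display: 2 decimals, round half up; 'NA' when Tv = 0."""
    if transversions == 0:
        return "NA"
    ratio = Decimal(transitions) / Decimal(transversions)
    return str(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def titv_table(events: list[SubstitutionEvent]) -> pd.DataFrame:
    """Ti/Tv breakdown per origin bin and event category.

    For SBS/DBS/CBS the total is the member-base count (= Ti + Tv); for BBS
    it is the event count with Ti/Tv not applicable. A per-origin Total row
    sums the columns; its ratio likewise excludes BBS.
    """
    origins = []
    for e in events:
        if e.origin_bin not in origins:
            origins.append(e.origin_bin)
    origins.sort()
    rows = []
    for origin in origins:
        grand_ti = grand_tv = grand_total = 0
        for category in CATEGORY_ORDER:
            cat_events = [e for e in events
                          if e.origin_bin == origin and e.category == category]
            if category == BBS:
                total = len(cat_events)
                rows.append({"origin": origin, "category": category,
                             "transitions": pd.NA, "transversions": pd.NA,
                             "total": total, "ratio": "NA"})
                grand_total += total
                continue
            ti = sum(is_transition(m.ref, m.alt)
                     for e in cat_events for m in e.members)
            total = sum(e.n_members for e in cat_events)
            tv = total - ti
            rows.append({"origin": origin, "category": category,
                         "transitions": ti, "transversions": tv,
                         "total": total, "ratio": format_ratio(ti, tv)})
            grand_ti += ti
            grand_tv += tv
            grand_total += total
        rows.append({"origin": origin, "category": "Total",
                     "transitions": grand_ti, "transversions": grand_tv,
                     "total": grand_total,
                     "ratio": format_ratio(grand_ti, grand_tv)})
    return pd.DataFrame(rows, columns=["origin", "category", "transitions",
                                       "transversions", "total", "ratio"])


def intermutation_distances(substitutions: list[Substitution]
                            ) -> dict[str, list[tuple[int, int]]]:
    """Rainfall-plot data: per chromosome, (position, distance to the
    previous substitution). The first variant on each chromosome has no
    distance and is omitted."""
    _require_sorted(substitutions)
    out: dict[str, list[tuple[int, int]]] = {}
    prev: dict[str, int] = {}
    for sub in substitutions:
        if sub.chrom in prev:
            out.setdefault(sub.chrom, []).append(
                (sub.pos, sub.pos - prev[sub.chrom]))
        else:
            out.setdefault(sub.chrom, [])
        prev[sub.chrom] = sub.pos
    return out


def events_table(events: list[SubstitutionEvent]) -> pd.DataFrame:
    """One row per event with its members serialized."""
    rows = []
    for e in events:
        rows.append({
            "chrom": e.members[0].chrom,
            "start": e.members[0].pos,
            "end": e.members[-1].pos,
            "category": e.category,
            "origin": e.origin_bin,
            "n_members": e.n_members,
            "span": e.span,
            "members": ";".join(f"{m.pos}{m.ref}>{m.alt}" for m in e.members),
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category",
                                       "origin", "n_members", "span",
                                       "members"])


def plot_rainfall(substitutions: list[Substitution], path: str) -> None:
    """Log-scale intermutation-distance scatter along the genome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dists = intermutation_distances(substitutions)
    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    ticks, labels = [], []
    for chrom in dists:
        pts = dists[chrom]
        if pts:
            xs = [offset + p for p, _ in pts]
            ys = [d for _, d in pts]
            ax.scatter(xs, ys, s=6, alpha=0.6)
        span = max((p for p, _ in pts), default=0) + 1
        ticks.append(offset + span / 2)
        labels.append(chrom)
        offset += span
    ax.set_yscale("log")
    ax.set_ylabel("bp to previous")
    ax.set_xticks(ticks, labels, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
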