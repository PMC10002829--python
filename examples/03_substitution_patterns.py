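"""Group de novo substitutions into SBS/DBS/CBS/BBS events and build the
Ti/Tv breakdown table.

Uses hand-placed substitutions to show each category: an isolated change
(SBS), an adjacent pair (DBS), a <50 bp cluster (CBS), and two alternate
alleles at one position (BBS).
"""

from dnmosaic import Substitution, group_events, intermutation_distances, \
    titv_table

subs = [
    Substitution("chr1", 1_000, "C", "T"),                  # SBS (transition)
    Substitution("chr1", 5_000, "C", "A"),                  # DBS member
    Substitution("chr1", 5_001, "G", "T"),                  # DBS member
    Substitution("chr1", 9_000, "C", "G"),                  # CBS member
    Substitution("chr1", 9_030, "T", "A"),                  # CBS member
    Substitution("chr1", 12_000, "C", "A"),                 # BBS: two alts
    Substitution("chr1", 12_000, "C", "T"),                 # at one site
    Substitution("chr2", 2_000, "G", "A"),                  # SBS (transition)
]

events = group_events(subs)
for e in events:
    members = ", ".join(f"{m.pos}{m.ref}>{m.alt}" for m in e.members)
    print(f"{e.category:<4s} span={e.span:>3d} bp  [{members}]")

print()
print(titv_table(events).to_string(index=False))
print("\nTi/Tv counts every member base of SBS/DBS/CBS events (A<->G and "
      "C<->T are transitions); biallelic events enter the total as events "
      "with the ratio marked NA.")

print("\nintermutation distances (rainfall):")
for chrom, pairs in intermutation_distances(subs).items():
    print(f"  {chrom}: {pairs}")
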