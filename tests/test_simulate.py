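"""Synthetic-trio generator: determinism, truth completeness, planted
structure, and parameter recovery against exact binomial expectations."""

import numpy as np
import pytest
from scipy import stats

from conftest import ROLES
from dnmosaic.contexts import PYRIMIDINE_TRINUCS, revcomp
from dnmosaic.filtering import FilterParams, filter_trio
from dnmosaic.io import read_blacklist, read_vcf_trio
from dnmosaic.simulate import (GenerationError, SimulationConfig,
                               simulate_reference, simulate_trio)
from dnmosaic.timing import PUBLISHED_BINS, classify_timing

SMALL = dict(chrom_lengths={"chr1": 60_000},
             event_rates={"DBS": 0, "CBS": 0, "BBS": 0},
             decoy_counts={"blacklist": 0, "region": 0, "low_alt": 0,
                           "hard_filter": 0})


class TestConfig:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            SimulationConfig(class_counts={"germline": -1})

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="1 kb"):
            SimulationConfig(chrom_lengths={"chr1": 500})

    def test_mixture_normalized(self):
        cfg = SimulationConfig(signature_mixture={"S1": 2.0, "S2": 2.0})
        assert cfg.signature_mixture == {"S1": 0.5, "S2": 0.5}


class TestReference:
    def test_seeded_rerun_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(chrom_lengths={"chr1": 5_000}, seed=1)
        a = simulate_reference(cfg, tmp_path / "a.fa")
        b = simulate_reference(cfg, tmp_path / "b.fa")
        assert a.read_bytes() == b.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        base = dict(chrom_lengths={"chr1": 5_000})
        a = simulate_reference(SimulationConfig(**base, seed=1),
                               tmp_path / "a.fa")
        b = simulate_reference(SimulationConfig(**base, seed=2),
                               tmp_path / "b.fa")
        assert a.read_bytes() != b.read_bytes()

    def test_all_32_contexts_present_even_on_1kb(self, tmp_path):
        cfg = SimulationConfig(chrom_lengths={"chr1": 1_000}, seed=3)
        path = simulate_reference(cfg, tmp_path / "tiny.fa")
        seq = "".join(line.strip() for line in path.read_text().splitlines()
                      if not line.startswith(">"))
        present = {seq[i:i + 3] for i in range(len(seq) - 2)}
        collapsed = {t if t[1] in "CT" else revcomp(t) for t in present}
        assert set(PYRIMIDINE_TRINUCS) <= collapsed


class TestTrio:
    def test_seeded_rerun_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=5, **SMALL,
                               class_counts={"germline": 30,
                                             "first_mitosis": 40})
        ref = simulate_reference(cfg, tmp_path / "ref.fa")
        a = simulate_trio(cfg, ref, tmp_path / "a")
        b = simulate_trio(cfg, ref, tmp_path / "b")
        assert a.vcf.read_bytes() == b.vcf.read_bytes()
        assert a.truth_path.read_bytes() == b.truth_path.read_bytes()

    def test_germline_only_vafs_concentrate_near_half(self, tmp_path):
        cfg = SimulationConfig(seed=2, **SMALL,
                               class_counts={"germline": 50})
        ref = simulate_reference(cfg, tmp_path / "ref.fa")
        sim = simulate_trio(cfg, ref, tmp_path / "out")
        variants = read_vcf_trio(str(sim.vcf), ROLES)
        vafs = [v.samples["proband"].alt_depths[0] / v.samples["proband"].depth
                for v in variants]
        assert 0.45 <= np.mean(vafs) <= 0.55

    def test_requested_dbs_events_are_adjacent_pairs(self, tmp_path):
        cfg = SimulationConfig(seed=4, chrom_lengths={"chr1": 60_000},
                               class_counts={"germline": 5},
                               event_rates={"DBS": 3, "CBS": 0, "BBS": 0},
                               decoy_counts={})
        ref = simulate_reference(cfg, tmp_path / "ref.fa")
        sim = simulate_trio(cfg, ref, tmp_path / "out")
        dbs = sim.truth[sim.truth.category == "DBS"]
        assert dbs.event_id.nunique() == 3
        for _, grp in dbs.groupby("event_id"):
            positions = sorted(grp.pos)
            assert len(positions) == 2
            assert positions[1] - positions[0] == 1

    def test_blacklist_decoys_appear_in_blacklist_file(self, tmp_path):
        cfg = SimulationConfig(seed=6, chrom_lengths={"chr1": 60_000},
                               class_counts={"germline": 5},
                               event_rates={},
                               decoy_counts={"blacklist": 10})
        ref = simulate_reference(cfg, tmp_path / "ref.fa")
        sim = simulate_trio(cfg, ref, tmp_path / "out")
        bl = read_blacklist(str(sim.blacklist_path))
        decoys = sim.truth[sim.truth.origin == "decoy:blacklist"]
        assert len(decoys) == 10
        for row in decoys.itertuples():
            assert (row.chrom, row.pos, row.ref, row.alt) in bl

    def test_truth_table_is_complete_and_exact(self, default_sim):
        """Every VCF record/alt has exactly one truth row and vice versa;
        de novo truth classes have zero parental alt reads."""
        truth = default_sim["sim"].truth
        vcf_keys = {(v.chrom, v.pos, v.ref, alt)
                    for v in default_sim["variants"] for alt in v.alts}
        truth_keys = set(map(tuple,
                             truth[["chrom", "pos", "ref", "alt"]]
                             .to_numpy()))
        assert vcf_keys == truth_keys
        assert len(truth) == len(truth_keys)
        by_key = {(v.chrom, v.pos, v.ref, a): v
                  for v in default_sim["variants"] for a in v.alts}
        for row in truth.itertuples():
            v = by_key[(row.chrom, row.pos, row.ref, row.alt)]
            parental_alt = sum(sum(v.samples[r].alt_depths)
                               for r in ("mother", "father"))
            if row.origin != "inherited":
                assert parental_alt == 0

    def test_noise_class_uses_third_division_vaf(self, default_sim):
        truth = default_sim["sim"].truth
        noise = truth[truth.origin == "noise"]
        assert (noise.p_vaf == 0.0625).all()

    def test_overfull_genome_raises_generation_error(self, tmp_path):
        cfg = SimulationConfig(seed=1, chrom_lengths={"chr1": 1_000},
                               class_counts={"germline": 500},
                               event_rates={}, decoy_counts={})
        ref = simulate_reference(cfg, tmp_path / "ref.fa")
        with pytest.raises(GenerationError, match="longer genome"):
            simulate_trio(cfg, ref, tmp_path / "out")

    def test_contamination_switch_adds_parental_read(self, tmp_path):
        cfg = SimulationConfig(seed=8, **SMALL,
                               class_counts={"first_mitosis": 60},
                               contaminated_fraction=1.0)
        ref = simulate_reference(cfg, tmp_path / "ref.fa")
        sim = simulate_trio(cfg, ref, tmp_path / "out")
        variants = read_vcf_trio(str(sim.vcf), ROLES)
        contaminated = sum(
            max(v.samples["mother"].alt_depths[0],
                v.samples["father"].alt_depths[0]) == 1
            for v in variants)
        assert contaminated == len(variants)
        survivors, _ = filter_trio(variants, FilterParams())
        assert survivors == []  # default tolerance is zero parental reads
        lenient, _ = filter_trio(variants,
                                 FilterParams(max_parent_alt_reads=1))
        assert len(lenient) > 0


def expected_bin_counts(class_counts, depth=50):
    """Analytic expected per-bin counts from exact binomial tails, with the
    >=2-alt-read survival rule applied."""
    class_p = {"germline": 0.5, "first_mitosis": 0.25,
               "second_mitosis": 0.125, "noise": 0.0625}
    expected = {}
    for origin, n in class_counts.items():
        p = class_p[origin]
        for k in range(2, depth + 1):  # k<2 removed by the filter
            label = classify_timing(k / depth, PUBLISHED_BINS)
            expected[label] = expected.get(label, 0) + \
                n * stats.binom.pmf(k, depth, p)
    return expected


class TestParameterRecovery:
    def test_bin_counts_match_binomial_tail_expectation(self, tmp_path):
        """Across 5 seeds at the default class sizes (fixed depth 50), mean
        per-bin counts sit within 15% of the exact-tail expectation, and
        the two mosaic bins within 15% of their truth counts."""
        class_counts = {"germline": 45, "first_mitosis": 400,
                        "second_mitosis": 400, "noise": 60}
        observed = {}
        for seed in range(1, 6):
            cfg = SimulationConfig(seed=seed, depth_dispersion=None,
                                   class_counts=dict(class_counts),
                                   chrom_lengths={"chr1": 250_000,
                                                  "chr2": 250_000},
                                   event_rates={}, decoy_counts={})
            ref = simulate_reference(cfg, tmp_path / f"ref{seed}.fa")
            sim = simulate_trio(cfg, ref, tmp_path / f"out{seed}")
            variants = read_vcf_trio(str(sim.vcf), ROLES)
            survivors, _ = filter_trio(variants, FilterParams())
            for cand in survivors:
                label = classify_timing(cand.vaf, PUBLISHED_BINS)
                observed[label] = observed.get(label, 0) + 1 / 5
        expected = expected_bin_counts(class_counts)
        for label, exp in expected.items():
            if exp < 20:
                continue  # tiny bins are dominated by integer noise
            assert observed.get(label, 0) == pytest.approx(exp, rel=0.15)
        # the tail-implied expectation itself deviates from the planted
        # truth counts by no more than 15% for the mosaic classes
        assert expected["first-mitosis"] == pytest.approx(
            class_counts["first_mitosis"], rel=0.15)
        assert expected["second-mitosis"] == pytest.approx(
            class_counts["second_mitosis"], rel=0.15)
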