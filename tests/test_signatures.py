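"""Trinucleotide profiles, cosine ranking, NNLS refitting and backwards
elimination, including the exhaustive subset-NNLS oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import disjoint_catalog, five_signature_catalog
from dnmosaic.contexts import CONTEXTS_96
from dnmosaic.io import SignatureSet
from dnmosaic.signatures import (MutationProfile, ReferenceMismatchError,
                                 backwards_selection, build_profile,
                                 cosine_similarity, extended_context,
                                 nnls_refit, rank_signatures,
                                 trinucleotide_context)

REF = {"chr1": "TTACGTTGCAATAANAGG" + "ACGT" * 10}
# positions (1-based): 4 = C in ACG; 8 = G in TGC; 15 = N flank region


class Cand:
    def __init__(self, chrom, pos, ref, alt):
        self.chrom, self.pos, self.ref, self.alt = chrom, pos, ref, alt


class TestTrinucleotideContext:
    def test_pyrimidine_center_direct(self):
        assert trinucleotide_context("chr1", 4, "C", "T", REF) == "A[C>T]G"

    def test_purine_center_reverse_complemented(self):
        assert trinucleotide_context("chr1", 8, "G", "A", REF) == "G[C>T]A"

    def test_n_flank_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            assert trinucleotide_context("chr1", 14, "A", "G", REF) is None

    def test_reference_mismatch_names_position(self):
        with pytest.raises(ReferenceMismatchError, match="chr1:4"):
            trinucleotide_context("chr1", 4, "G", "A", REF)

    def test_extended_context_five_bases(self):
        assert extended_context("chr1", 4, "C", "T", REF) == "TA[C>T]GT"


class TestBuildProfile:
    def test_counts_conserved(self):
        cands = [Cand("chr1", 4, "C", "T"), Cand("chr1", 8, "G", "A"),
                 Cand("chr1", 20, "C", "A")]
        profile = build_profile(cands, REF)
        assert profile.n == 3
        assert profile.counts.sum() == 3

    def test_empty_input_zero_profile(self):
        profile = build_profile([], REF)
        assert profile.n == 0
        assert not profile.counts.any()

    def test_non_snv_candidates_skipped(self):
        profile = build_profile([Cand("chr1", 4, "C", "CT")], REF)
        assert profile.n == 0

    def test_pyrimidine_heavy_mixture_dominates_c_classes(self, default_sim):
        """Somatic substitutions drawn uniformly still land majority mass in
        whichever classes were planted; directional check that profile
        extraction matches the planted contexts exactly."""
        import pyfaidx

        truth = default_sim["sim"].truth
        somatic = truth[truth.origin.isin(["first_mitosis",
                                           "second_mitosis"])
                        & (truth.category == "SBS")]
        fasta = pyfaidx.Fasta(str(default_sim["sim"].reference_path))
        cands = [Cand(r.chrom, r.pos, r.ref, r.alt)
                 for r in somatic.itertuples()]
        profile = build_profile(cands, fasta)
        expected = somatic.context.value_counts()
        for label, count in expected.items():
            assert profile.counts[CONTEXTS_96.index(label)] == count


class TestCosine:
    def test_identical_vectors(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_computed_half(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])


def _profile_from_mix(catalog, weights, n):
    counts = np.zeros(96)
    for name, w in weights.items():
        counts += n * w * catalog.column(name)
    return MutationProfile(counts=counts, n=n)


class TestNnlsRefit:
    def test_pure_signature_recovered_exactly(self, fixture_catalog):
        profile = _profile_from_mix(fixture_catalog, {"S1": 1.0}, 100)
        contrib, recon = nnls_refit(profile, fixture_catalog)
        assert contrib == pytest.approx([100.0, 0.0], abs=1e-9)
        assert cosine_similarity(recon, profile.counts) == \
            pytest.approx(1.0, abs=1e-6)

    def test_exact_mixture_recovered(self, fixture_catalog):
        profile = _profile_from_mix(fixture_catalog, {"S1": 0.7, "S2": 0.3},
                                    100)
        contrib, _ = nnls_refit(profile, fixture_catalog)
        assert contrib == pytest.approx([70.0, 30.0], abs=1e-9)

    def test_orthogonal_profile_gets_zero_contributions(self):
        m = np.zeros((96, 2))
        m[:16, 0] = 1 / 16
        m[16:32, 1] = 1 / 16
        names = ["A", "B"]
        catalog = SignatureSet(names=names,
                               matrix=pd.DataFrame(m, index=list(CONTEXTS_96),
                                                   columns=names))
        counts = np.zeros(96)
        counts[80:] = 5.0
        profile = MutationProfile(counts=counts, n=int(counts.sum()))
        contrib, recon = nnls_refit(profile, catalog)
        assert contrib == pytest.approx([0.0, 0.0], abs=1e-12)
        residual = np.linalg.norm(profile.counts - recon)
        assert residual == pytest.approx(np.linalg.norm(profile.counts))


class TestRanking:
    def test_exact_signature_ranks_first_with_unit_similarity(
            self, fixture_catalog):
        profile = _profile_from_mix(fixture_catalog, {"S2": 1.0}, 50)
        ranking = rank_signatures(profile, fixture_catalog)
        assert ranking[0][0] == "S2"
        assert ranking[0][1] == pytest.approx(1.0)

    def test_ties_keep_catalog_order(self):
        m = np.tile(np.full((96, 1), 1 / 96), (1, 2))
        names = ["First", "Second"]
        catalog = SignatureSet(names=names,
                               matrix=pd.DataFrame(m, index=list(CONTEXTS_96),
                                                   columns=names))
        profile = MutationProfile(counts=np.full(96, 2.0), n=192)
        ranking = rank_signatures(profile, catalog)
        assert [name for name, _ in ranking] == ["First", "Second"]

    def test_dominant_component_ranks_above_minor(self, fixture_catalog):
        profile = _profile_from_mix(fixture_catalog, {"S1": 0.7, "S2": 0.3},
                                    100)
        ranking = rank_signatures(profile, fixture_catalog)
        assert ranking[0][0] == "S1"


def exhaustive_subset_refit(profile, catalog, max_delta):
    """Oracle: smallest subsets whose NNLS reconstruction stays within
    max_delta cosine of the full-catalog fit."""
    _, full_recon = nnls_refit(profile, catalog)
    base = cosine_similarity(profile.counts, full_recon)
    admissible = []
    for r in range(1, len(catalog.names) + 1):
        for names in itertools.combinations(catalog.names, r):
            _, recon = nnls_refit(profile, catalog, list(names))
            if base - cosine_similarity(profile.counts, recon) <= max_delta:
                admissible.append(set(names))
        if admissible:
            return admissible
    return admissible


class TestBackwardsSelection:
    def test_pure_signature_leaves_single_survivor(self):
        catalog = five_signature_catalog()
        profile = _profile_from_mix(catalog, {"S1": 1.0}, 200)
        result = backwards_selection(profile, catalog)
        assert result.selected == ["S1"]
        assert result.final_cosine == pytest.approx(1.0, abs=1e-6)

    def test_mixture_keeps_both_components_matching_subset_oracle(self):
        catalog = five_signature_catalog()
        profile = _profile_from_mix(catalog, {"S1": 0.7, "S2": 0.3}, 100)
        result = backwards_selection(profile, catalog, max_delta=0.004)
        assert {"S1", "S2"} <= set(result.selected)
        contrib = dict(zip(result.selected, result.contributions))
        assert contrib["S1"] == pytest.approx(70, abs=2)
        assert contrib["S2"] == pytest.approx(30, abs=2)
        admissible = exhaustive_subset_refit(profile, catalog, 0.004)
        assert set(result.selected) in admissible

    def test_infinite_tolerance_reduces_to_top_contributor(self,
                                                           fixture_catalog):
        profile = _profile_from_mix(fixture_catalog, {"S1": 0.7, "S2": 0.3},
                                    100)
        result = backwards_selection(profile, fixture_catalog,
                                     max_delta=float("inf"))
        assert result.selected == ["S1"]

    def test_trajectory_never_increases_when_removing(self):
        catalog = five_signature_catalog()
        rng = np.random.default_rng(3)
        counts = rng.poisson(8.0, size=96).astype(float)
        profile = MutationProfile(counts=counts, n=int(counts.sum()))
        result = backwards_selection(profile, catalog,
                                     max_delta=float("inf"))
        cosines = [c for _, c in result.similarity_trajectory]
        assert all(b <= a + 1e-9 for a, b in zip(cosines, cosines[1:]))

    def test_empty_catalog_rejected(self, fixture_catalog):
        profile = _profile_from_mix(fixture_catalog, {"S1": 1.0}, 10)
        empty = SignatureSet(names=[], matrix=fixture_catalog.matrix[[]])
        with pytest.raises(ValueError, match="empty"):
            backwards_selection(profile, empty)
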