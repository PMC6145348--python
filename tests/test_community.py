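"""OTU-MAG linking: bin abundance, dual-L1, taxonomy overlap, combined
metric, tolerance training, matching, RDP filtering, gene-content
clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakeredox.community import (
    RANKS,
    AbundanceMatrix,
    ContigRecord,
    TaxonomyPath,
    bin_abundance,
    cluster_gene_content,
    combined_distance,
    dual_l1_normalize,
    filter_taxonomy,
    match,
    taxonomy_fraction,
    train_tolerance,
)


def _contig(cid, bid, length, cov):
    return ContigRecord(contig_id=cid, bin_id=bid, length=length, coverage=cov)


class TestBinAbundance:
    def test_single_contig_identity(self):
        c = _contig("c1", "b", 1000, {"s1": 7.0})
        assert bin_abundance([c], "s1") == pytest.approx(7.0)

    def test_length_weighted_mean(self):
        contigs = [
            _contig("c1", "b", 1000, {"s1": 10.0}),
            _contig("c2", "b", 3000, {"s1": 2.0}),
        ]
        assert bin_abundance(contigs, "s1") == pytest.approx(4.0)

    def test_zero_coverage_gives_zero(self):
        contigs = [_contig("c1", "b", 500, {"s1": 0.0})]
        assert bin_abundance(contigs, "s1") == 0.0

    def test_library_read_division(self):
        c = _contig("c1", "b", 1000, {"s1": 8.0})
        assert bin_abundance([c], "s1", library_reads=4) == pytest.approx(2.0)

    def test_split_contig_invariance(self):
        whole = [_contig("c", "b", 2000, {"s1": 5.0})]
        halves = [
            _contig("c_a", "b", 1000, {"s1": 5.0}),
            _contig("c_b", "b", 1000, {"s1": 5.0}),
        ]
        assert bin_abundance(whole, "s1") == pytest.approx(
            bin_abundance(halves, "s1")
        )

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            bin_abundance([], "s1")


class TestDualL1:
    def test_hand_worked_two_by_two(self):
        m = AbundanceMatrix(
            table=pd.DataFrame([[2.0, 0.0], [2.0, 4.0]], index=["a", "b"],
                               columns=["s1", "s2"])
        )
        out = dual_l1_normalize(m)
        assert out.table.loc["a"].to_numpy() == pytest.approx([1.0, 0.0])
        assert out.table.loc["b"].to_numpy() == pytest.approx([1 / 3, 2 / 3])
        assert out.normalization_state == "dual_l1"

    def test_equal_matrix_gives_uniform_rows(self):
        m = AbundanceMatrix(table=pd.DataFrame(np.full((3, 4), 5.0)))
        out = dual_l1_normalize(m)
        assert out.table.to_numpy() == pytest.approx(np.full((3, 4), 0.25))

    def test_rows_sum_to_one_or_zero(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 10, (6, 5))
        vals[2] = 0.0
        out = dual_l1_normalize(AbundanceMatrix(table=pd.DataFrame(vals)))
        sums = out.table.sum(axis=1).to_numpy()
        assert sums[2] == 0.0
        assert np.delete(sums, 2) == pytest.approx(np.ones(5))

    def test_row_step_idempotent(self):
        rng = np.random.default_rng(4)
        out = dual_l1_normalize(
            AbundanceMatrix(table=pd.DataFrame(rng.uniform(0, 1, (4, 3))))
        )
        vals = out.table.to_numpy()
        again = vals / vals.sum(axis=1, keepdims=True)
        assert again == pytest.approx(vals)


class TestTaxonomyFraction:
    def _path(self, fid, names):
        return TaxonomyPath(
            feature_id=fid,
            ranks={r: (n, 90.0) for r, n in zip(RANKS, names)},
        )

    def test_identical_paths(self):
        p = self._path("x", ["k1", "p1", "c1", "o1", "f1", "g1"])
        assert taxonomy_fraction(p, p) == 1.0

    def test_partial_overlap_counts_levels_independently(self):
        mag = TaxonomyPath(
            "m",
            {
                "kingdom": ("Bacteria", 99.0),
                "phylum": ("Proteobacteria", 95.0),
                "class": ("Betaproteobacteria", 80.0),
            },
        )
        otu = self._path(
            "o",
            ["Bacteria", "Proteobacteria", "Gammaproteobacteria", "x", "y", "z"],
        )
        assert taxonomy_fraction(otu, mag) == pytest.approx(2 / 3)

    def test_mismatch_at_shallow_rank_does_not_block_deeper_match(self):
        mag = self._path("m", ["k1", "pX", "c1", "o1", "f1", "g1"])
        otu = self._path("o", ["k1", "pY", "c1", "o1", "f1", "g1"])
        assert taxonomy_fraction(otu, mag) == pytest.approx(5 / 6)

    def test_disjoint_paths(self):
        a = self._path("a", ["k1"] * 6)
        b = self._path("b", ["k2"] * 6)
        assert taxonomy_fraction(a, b) == 0.0

    def test_fully_unassigned_mag_rejected(self):
        mag = TaxonomyPath("m", {r: ("unassigned", 0.0) for r in RANKS})
        otu = self._path("o", ["k"] * 6)
        with pytest.raises(ValueError):
            taxonomy_fraction(otu, mag)


class TestCombinedDistance:
    def test_perfect_match_scores_minus_one(self):
        row = np.array([0.2, 0.3, 0.5])
        assert combined_distance(row, row, 1.0) == pytest.approx(-1.0)

    def test_identical_rows_no_taxonomy(self):
        row = np.array([0.5, 0.5])
        assert combined_distance(row, row, 0.0) == 0.0

    def test_orthogonal_rows_full_taxonomy(self):
        m = combined_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 1.0)
        assert m == pytest.approx(np.sqrt(2) - 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combined_distance(np.ones(2), np.ones(3), 0.0)

    @given(
        data=st.lists(st.floats(0, 1), min_size=2, max_size=8),
        f=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_lower_bound_minus_one(self, data, f):
        a = np.array(data)
        if a.sum() == 0:
            return
        a = a / a.sum()
        b = np.roll(a, 1)
        m = combined_distance(a, b, f)
        assert m >= -1.0
        if m == -1.0:
            assert f == 1.0 and np.allclose(a, b)


class TestTrainTolerance:
    def test_single_control(self):
        assert train_tolerance([-0.2]) == -0.2

    def test_max_of_controls(self):
        assert train_tolerance([-0.5, -0.2, 0.1]) == pytest.approx(0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            train_tolerance([])


class TestMatch:
    def test_noise_free_exact_recovery(self):
        # identical abundance rows and taxonomy: all pairs at m = -1
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.1, 5.0, (4, 6))
        otus = dual_l1_normalize(
            AbundanceMatrix(table=pd.DataFrame(vals, index=[f"o{i}" for i in range(4)]))
        )
        mags = dual_l1_normalize(
            AbundanceMatrix(table=pd.DataFrame(vals, index=[f"m{i}" for i in range(4)]))
        )
        taxa = {}
        for i in range(4):
            ranks = {r: (f"{r}_{i}", 99.0) for r in RANKS}
            taxa[f"o{i}"] = TaxonomyPath(f"o{i}", ranks)
            taxa[f"m{i}"] = TaxonomyPath(f"m{i}", ranks)
        cands = match(otus, otus, mags, taxa, tol_amplicon=-1.0, tol_metagenomic=-1.0)
        accepted = {(c.otu_id, c.mag_id) for c in cands if c.accepted}
        assert accepted == {(f"o{i}", f"m{i}") for i in range(4)}

    def test_conjunction_rule_blocks_single_dataset_pass(self):
        vals = np.array([[1.0, 2.0, 3.0]])
        otu_a = dual_l1_normalize(AbundanceMatrix(table=pd.DataFrame(vals, index=["o"])))
        # metagenomic dataset disagrees badly
        otu_m = dual_l1_normalize(
            AbundanceMatrix(table=pd.DataFrame(np.array([[3.0, 1.0, 0.0]]), index=["o"]))
        )
        mags = dual_l1_normalize(AbundanceMatrix(table=pd.DataFrame(vals, index=["m"])))
        ranks = {r: ("t", 99.0) for r in RANKS}
        taxa = {"o": TaxonomyPath("o", ranks), "m": TaxonomyPath("m", ranks)}
        cands = match(otu_a, otu_m, mags, taxa, tol_amplicon=-0.9, tol_metagenomic=-0.9)
        assert not any(c.accepted for c in cands)

    def test_planted_community_recovery(self, community, community_match_inputs):
        amp, met, mags, tol_a, tol_m = community_match_inputs
        cands = match(amp, met, mags, community.taxonomies, tol_a, tol_m)
        accepted = {(c.otu_id, c.mag_id) for c in cands if c.accepted}
        planted = set(community.planted_pairs)
        assert len(accepted & planted) / len(planted) >= 0.95
        false_otus = {c.otu_id for c in cands if c.accepted} - {
            o for o, _ in planted
        }
        assert len(false_otus) == 0

    def test_determinism(self, community, community_match_inputs):
        amp, met, mags, tol_a, tol_m = community_match_inputs
        a = match(amp, met, mags, community.taxonomies, tol_a, tol_m)
        b = match(amp, met, mags, community.taxonomies, tol_a, tol_m)
        assert [(c.otu_id, c.mag_id, c.accepted) for c in a] == [
            (c.otu_id, c.mag_id, c.accepted) for c in b
        ]


class TestFilterTaxonomy:
    def _p(self, **ranks):
        return TaxonomyPath("x", {r: v for r, v in ranks.items()})

    def test_low_confidence_rank_removed_others_kept(self):
        p = self._p(kingdom=("Bacteria", 99.0), genus=("Geobacter", 40.0))
        (out,) = filter_taxonomy([p])
        assert out.ranks["genus"][0] == "unassigned"
        assert out.ranks["kingdom"][0] == "Bacteria"

    def test_clean_path_unchanged(self):
        p = self._p(kingdom=("Bacteria", 99.0), phylum=("Firmicutes", 51.0))
        (out,) = filter_taxonomy([p])
        assert out.ranks == p.ranks

    def test_incertae_sedis_removed_despite_high_confidence(self):
        p = self._p(family=("Incertae Sedis XI", 99.0))
        (out,) = filter_taxonomy([p])
        assert out.ranks["family"][0] == "unassigned"


class TestClusterGeneContent:
    def test_identical_profiles_merge_at_zero(self):
        df = pd.DataFrame(
            [[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], index=["a", "b", "c"]
        )
        Z = cluster_gene_content(df)
        assert Z[0, 2] == pytest.approx(0.0)  # a,b merge first at height 0

    def test_monotone_transform_invariance(self):
        df = pd.DataFrame([[1, 2, 3, 4], [10, 20, 35, 90]], index=["a", "b"])
        Z = cluster_gene_content(df)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_reversed_profile_merges_last_at_height_two(self):
        df = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 9, 16], [4, 3, 2, 1]], index=["a", "b", "c"]
        )
        Z = cluster_gene_content(df)
        # complete linkage: final merge at 1 - (-1) = 2
        assert Z[-1, 2] == pytest.approx(2.0)

    def test_constant_profile_named_in_error(self):
        df = pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            cluster_gene_content(df)
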