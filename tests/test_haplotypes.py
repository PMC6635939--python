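import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylopop import (
    Alignment,
    DistanceMatrix,
    EstimationError,
    HaplotypeCatalog,
    PopulationMap,
    collapse_haplotypes,
    gst_nst,
    haplotype_diversity,
    nucleotide_diversity,
    pooled_diversity,
)
from phylopop.datasets import coi_haplotype_catalog
from phylopop.haplotypes import diversity_table, retained_columns
from helpers import random_alignment


class TestCollapse:
    def _pm(self, aln, pop="P"):
        return PopulationMap(
            {s: pop for s in aln.ids}, {pop: "R"}, {pop: (0.0, 0.0)}
        )

    def test_identical_sequences_one_haplotype(self):
        aln = Alignment(("a", "b"), ("ACGT", "ACGT"))
        cat = collapse_haplotypes(aln, self._pm(aln))
        assert cat.n_haplotypes == 1
        assert cat.labels == ("H1",)
        assert cat.n_total == 2

    def test_planted_classes_recovered(self):
        rng = np.random.default_rng(29)
        base = random_alignment(rng, 3, 50)
        # plant 3 classes with multiplicities 4, 2, 1
        seqs = [base.seqs[0]] * 4 + [base.seqs[1]] * 2 + [base.seqs[2]]
        ids = tuple(f"s{i}" for i in range(7))
        aln = Alignment(ids, tuple(seqs))
        cat = collapse_haplotypes(aln, self._pm(aln))
        assert cat.n_haplotypes == len(set(seqs))
        assert sorted(cat.pooled_counts.tolist(), reverse=True)[:2] == [4, 2]
        # oracle: string equality classes
        for sid, seq in zip(ids, seqs):
            mates = [s for s, q in zip(ids, seqs) if q == seq]
            haps = {cat.sample_to_haplotype[m] for m in mates}
            assert len(haps) == 1

    def test_complete_deletion_identity(self):
        # sequences differing only at an ambiguous column share a haplotype
        aln = Alignment(("a", "b"), ("ACNT", "ACGT"))
        cat = collapse_haplotypes(aln, self._pm(aln))
        assert cat.n_haplotypes == 1

    def test_zero_retained_columns_raises(self):
        aln = Alignment(("a", "b"), ("N-", "NN"))
        with pytest.raises(EstimationError):
            collapse_haplotypes(aln, self._pm(aln))

    def test_count_matrix_partition(self, two_pop_fixed):
        aln, pm = two_pop_fixed
        cat = collapse_haplotypes(aln, pm)
        assert cat.counts.sum() == aln.n
        assert cat.n_haplotypes == 2

    def test_exports(self, tmp_path, two_pop_fixed):
        aln, pm = two_pop_fixed
        cat = collapse_haplotypes(aln, pm)
        cat.write_tsv(tmp_path / "cat.tsv")
        cat.write_fasta(tmp_path / "cat.fasta")
        assert (tmp_path / "cat.tsv").read_text().startswith("population\t")


class TestHaplotypeDiversity:
    # printed survey values: h(SD) per population from its count vector
    @pytest.mark.parametrize(
        "counts, h_expected, sd_expected",
        [
            ((2, 2, 1, 1), 0.867, 0.129),
            ((8, 2, 1, 1), 0.561, 0.154),
            ((15, 8, 12), 0.666, 0.032),
        ],
    )
    def test_published_values(self, counts, h_expected, sd_expected):
        h, sd = haplotype_diversity(counts)
        assert round(h, 3) == h_expected
        assert round(sd, 3) == sd_expected

    def test_monomorphic_zero(self):
        h, sd = haplotype_diversity((4,))
        assert h == 0.0
        assert sd == 0.0

    def test_two_singletons(self):
        h, _ = haplotype_diversity((1, 1))
        assert h == pytest.approx(1.0)

    def test_n_below_two_raises(self):
        with pytest.raises(EstimationError):
            haplotype_diversity((1,))

    @given(
        counts=st.lists(st.integers(1, 8), min_size=1, max_size=6).filter(
            lambda c: sum(c) >= 2
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_pair_counting_oracle(self, counts):
        # oracle: the unbiased h equals the exact fraction of unordered
        # sample pairs carrying different types:
        #   h = n/(n-1) (1 - sum p^2) = (n^2 - sum c^2) / (n (n-1))
        labels = [i for i, c in enumerate(counts) for _ in range(c)]
        n = len(labels)
        pairs = list(itertools.combinations(range(n), 2))
        frac_diff = sum(
            1 for i, j in pairs if labels[i] != labels[j]
        ) / len(pairs)
        h, _ = haplotype_diversity(counts)
        assert h == pytest.approx(frac_diff, rel=1e-12)


class TestPooled:
    def test_single_population_identity(self):
        cat = HaplotypeCatalog.from_counts({"P": {"H1": 3, "H2": 2}})
        h_pop, _ = haplotype_diversity(cat.population_counts("P"))
        h_tot, _ = pooled_diversity(cat)
        assert h_tot == pytest.approx(h_pop)

    def test_species_level_survey(self):
        cat = coi_haplotype_catalog()
        h, _ = pooled_diversity(cat)
        assert round(h, 3) == 0.952
        assert int(cat.pooled_counts.max()) == 33  # most frequent haplotype
        assert int((cat.pooled_counts == 1).sum()) == 18  # singletons

    def test_survey_diversity_table(self):
        cat = coi_haplotype_catalog()
        table = diversity_table(cat)
        by_pop = dict(zip(table.populations, zip(table.h, table.h_sd)))
        assert round(by_pop["GXLC"][0], 3) == 0.867
        assert round(by_pop["GXLC"][1], 3) == 0.129
        assert round(by_pop["GXNN"][0], 3) == 0.561
        assert round(by_pop["HBCD"][0], 3) == 0.666
        assert by_pop["SCLX"][0] == 0.0


class TestNucleotideDiversity:
    def test_identical(self):
        aln = Alignment(("a", "b"), ("ACGT", "ACGT"))
        assert nucleotide_diversity(aln) == 0.0

    def test_micro_example(self, micro_aln):
        # 6 pairs, 10 total differences over 4 sites
        assert nucleotide_diversity(micro_aln) == pytest.approx(10 / 6 / 4)

    def test_order_invariant(self, micro_aln):
        rng = np.random.default_rng(1)
        order = rng.permutation(micro_aln.n)
        shuffled = Alignment(
            tuple(micro_aln.ids[i] for i in order),
            tuple(micro_aln.seqs[i] for i in order),
        )
        assert nucleotide_diversity(shuffled) == pytest.approx(
            nucleotide_diversity(micro_aln)
        )

    def test_single_sequence_raises(self):
        with pytest.raises(EstimationError):
            nucleotide_diversity(Alignment(("a",), ("ACGT",)))


class TestGstNst:
    def test_identical_frequency_vectors_gst_near_zero(self):
        counts = {f"P{i}": {"H1": 250, "H2": 250} for i in range(4)}
        cat = HaplotypeCatalog.from_counts(counts)
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        hdm = DistanceMatrix(cat.labels, d, "raw")
        stats = gst_nst(cat, hdm, n_perm=49, seed=0, n_boot=20)
        assert abs(stats.gst) < 0.01

    def test_equal_distances_force_nst_equal_gst(self):
        cat = HaplotypeCatalog.from_counts(
            {"P1": {"H1": 5, "H2": 3}, "P2": {"H2": 4, "H3": 6}}
        )
        d = 2.5 * (1 - np.eye(3))
        hdm = DistanceMatrix(cat.labels, d, "raw")
        stats = gst_nst(cat, hdm, n_perm=49, seed=0, n_boot=20)
        assert stats.nst == pytest.approx(stats.gst, abs=1e-12)

    def test_two_clade_geography_nst_exceeds_gst(self):
        # two regions fixed for clades of mutually similar haplotypes; with
        # 5 haplotypes per clade the permutation null is fine-grained enough
        # for p < 0.05 (few label permutations preserve clade membership)
        rng = np.random.default_rng(3)
        counts = {}
        for r, region in enumerate(("A", "B")):
            for p in range(3):
                haps = rng.integers(1, 6, size=5)
                counts[f"{region}{p}"] = {
                    f"{region}H{j}": int(c) for j, c in enumerate(haps)
                }
        cat = HaplotypeCatalog.from_counts(counts)
        labels = cat.labels
        d = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    d[i, j] = 1.0 if a[0] == b[0] else 10.0
        hdm = DistanceMatrix(labels, d, "raw")
        stats = gst_nst(cat, hdm, n_perm=999, seed=0, n_boot=20)
        assert stats.nst > stats.gst
        assert stats.p_nst_gt_gst < 0.05

    def test_ht_bounds(self):
        cat = coi_haplotype_catalog()
        d = 1 - np.eye(cat.n_haplotypes)
        hdm = DistanceMatrix(cat.labels, d, "raw")
        stats = gst_nst(cat, hdm, n_perm=19, seed=1, n_boot=10)
        assert 0 <= stats.hs <= stats.ht + 0.05 <= 1.05
        assert -0.05 <= stats.gst <= 1

    def test_seeded_reproducibility(self):
        cat = coi_haplotype_catalog()
        d = 1 - np.eye(cat.n_haplotypes)
        hdm = DistanceMatrix(cat.labels, d, "raw")
        a = gst_nst(cat, hdm, n_perm=29, seed=5, n_boot=10)
        b = gst_nst(cat, hdm, n_perm=29, seed=5, n_boot=10)
        assert a == b

    def test_null_permutation_p_roughly_uniform(self):
        # exchangeable haplotype distances: p should not concentrate at 0
        rng = np.random.default_rng(42)
        cat = HaplotypeCatalog.from_counts(
            {
                f"P{i}": {
                    f"H{j}": int(c)
                    for j, c in enumerate(rng.integers(1, 6, size=5))
                }
                for i in range(5)
            }
        )
        pvals = []
        for rep in range(20):
            d = rng.random((cat.n_haplotypes, cat.n_haplotypes))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            hdm = DistanceMatrix(cat.labels, d, "raw")
            stats = gst_nst(cat, hdm, n_perm=39, seed=rep, n_boot=5)
            pvals.append(stats.p_nst_gt_gst)
        assert 0.2 < np.mean(pvals) < 0.8

    def test_retained_columns_helper(self):
        aln = Alignment(("a", "b"), ("AC-T", "ACGT"))
        assert retained_columns(aln) == (0, 1, 3)
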