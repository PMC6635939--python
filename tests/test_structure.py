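import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from phylopop import (
    Alignment,
    EstimationError,
    InputError,
    PopulationMap,
    amova,
    mantel,
    pairwise_fst,
    samova,
)
from phylopop.distances import distance_matrix
from phylopop.structure import fct_for_grouping, gabriel_graph
from helpers import random_alignment


def exact_three_level_oracle(d2_int, pops, groups):
    """Hand-solved moment equations in exact rational arithmetic.

    d2_int: integer squared-distance matrix; pops/groups: label per sample.
    Returns (sigma_a, sigma_b, sigma_c) as Fractions.
    """
    n = len(pops)
    pop_names = sorted(set(pops))
    group_names = sorted(set(groups))
    group_of_pop = {}
    for p, g in zip(pops, groups):
        group_of_pop[p] = g
    n_p = {p: pops.count(p) for p in pop_names}
    n_g = {g: groups.count(g) for g in group_names}

    def ssd(indices):
        tot = Fraction(0)
        for i, j in itertools.combinations(indices, 2):
            tot += Fraction(int(d2_int[i][j]))
        return tot / len(indices)

    all_idx = list(range(n))
    ssd_total = ssd(all_idx)
    ssd_wp = sum(
        ssd([i for i in all_idx if pops[i] == p]) for p in pop_names
    )
    ssd_wg = sum(
        ssd([i for i in all_idx if groups[i] == g]) for g in group_names
    )
    ssd_ag = ssd_total - ssd_wg
    ssd_apwg = ssd_wg - ssd_wp
    df_wp = n - len(pop_names)
    df_apwg = len(pop_names) - len(group_names)
    df_ag = len(group_names) - 1
    sum_np2_over_ng = sum(
        Fraction(
            sum(n_p[p] ** 2 for p in pop_names if group_of_pop[p] == g), n_g[g]
        )
        for g in group_names
    )
    n1 = (n - sum_np2_over_ng) / df_apwg
    n2 = (sum_np2_over_ng - Fraction(sum(v**2 for v in n_p.values()), n)) / df_ag
    n3 = (n - Fraction(sum(v**2 for v in n_g.values()), n)) / df_ag
    sigma_c = ssd_wp / df_wp
    sigma_b = (ssd_apwg / df_apwg - sigma_c) / n1
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def _pm(sample_pops, pop_groups, coords=None):
    coords = coords or {
        p: (float(i), float(i)) for i, p in enumerate(pop_groups)
    }
    return PopulationMap(sample_pops, pop_groups, coords)


class TestAmova:
    def test_fixed_haplotypes_fst_one(self, two_pop_fixed):
        aln, pm = two_pop_fixed
        dm = distance_matrix(aln, metric="raw")
        res = amova(dm, pm, grouping={"A": "g", "B": "g"}, n_perm=99, seed=0)
        assert res.fst == pytest.approx(1.0)
        assert res.levels[0].pct == pytest.approx(100.0)
        assert res.levels[1].pct == pytest.approx(0.0)

    def test_single_population_all_within(self):
        aln = Alignment(("a", "b", "c"), ("AAAA", "AAAT", "AATT"))
        pm = _pm({s: "P" for s in aln.ids}, {"P": "R"})
        res = amova(distance_matrix(aln, "raw"), pm, n_perm=0)
        assert len(res.levels) == 1
        assert res.levels[0].pct == 100.0
        assert math.isnan(res.fst)

    def test_all_zero_matrix_errors(self):
        aln = Alignment(("a", "b", "c", "d"), ("AAAA",) * 4)
        pm = _pm(
            {"a": "P1", "b": "P1", "c": "P2", "d": "P2"},
            {"P1": "R", "P2": "R"},
        )
        with pytest.raises(EstimationError):
            amova(distance_matrix(aln, "raw"), pm, n_perm=0)

    def test_three_level_matches_exact_oracle(self):
        # 2 groups x 2 pops x 3 sequences, solved independently with
        # exact rational moment equations
        rng = np.random.default_rng(101)
        aln = random_alignment(rng, 12, 30)
        pops = [f"P{i // 3}" for i in range(12)]
        groups = ["G0" if i < 6 else "G1" for i in range(12)]
        pm = _pm(
            dict(zip(aln.ids, pops)),
            {"P0": "G0", "P1": "G0", "P2": "G1", "P3": "G1"},
        )
        dm = distance_matrix(aln, metric="raw")
        res = amova(dm, pm, n_perm=0)
        sa, sb, sc = exact_three_level_oracle(
            dm.matrix.astype(int).tolist(), pops, groups
        )
        got = {lv.name: lv.variance for lv in res.levels}
        assert got["Among groups"] == pytest.approx(float(sa), abs=1e-10)
        assert got["Among populations within groups"] == pytest.approx(
            float(sb), abs=1e-10
        )
        assert got["Within populations"] == pytest.approx(float(sc), abs=1e-10)
        total = float(sa + sb + sc)
        assert res.fct == pytest.approx(float(sa) / total, abs=1e-10)
        assert res.fsc == pytest.approx(float(sb / (sb + sc)), abs=1e-10)
        assert res.fst == pytest.approx(float((sa + sb) / total), abs=1e-10)

    def test_percentages_sum_and_df(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, 10, 25)
        pops = ["P0"] * 3 + ["P1"] * 3 + ["P2"] * 4
        pm = _pm(
            dict(zip(aln.ids, pops)),
            {"P0": "G0", "P1": "G0", "P2": "G1"},
        )
        res = amova(distance_matrix(aln, "raw"), pm, n_perm=19, seed=2)
        assert sum(lv.pct for lv in res.levels) == pytest.approx(100.0, abs=0.01)
        assert sum(lv.df for lv in res.levels) == aln.n - 1

    def test_permutation_p_range_and_reproducibility(self):
        rng = np.random.default_rng(31)
        aln = random_alignment(rng, 12, 40)
        pops = [f"P{i % 3}" for i in range(12)]
        pm = _pm(
            dict(zip(aln.ids, pops)),
            {"P0": "G", "P1": "G", "P2": "G"},
        )
        dm = distance_matrix(aln, "raw")
        res1 = amova(dm, pm, n_perm=99, seed=7)
        res2 = amova(dm, pm, n_perm=99, seed=7)
        assert res1.p_fst == res2.p_fst
        assert 1 / 100 <= res1.p_fst <= 1.0


class TestPairwiseFst:
    def test_exchangeable_populations(self):
        # both pops drawn from one haplotype pool: FST near 0, p large
        rng = np.random.default_rng(3)
        pool = random_alignment(rng, 4, 30).seqs
        ids = tuple(f"s{i}" for i in range(20))
        seqs = tuple(pool[int(rng.integers(4))] for _ in ids)
        aln = Alignment(ids, seqs)
        pops = ["P1"] * 10 + ["P2"] * 10
        pm = _pm(dict(zip(ids, pops)), {"P1": "R", "P2": "R"})
        res = pairwise_fst(distance_matrix(aln, "raw"), pm, n_perm=99, seed=0)
        assert abs(res.fst[0, 1]) < 0.15
        assert res.p[0, 1] > 0.2

    def test_fixed_differences_fst_one(self, two_pop_fixed):
        aln, pm = two_pop_fixed
        res = pairwise_fst(distance_matrix(aln, "raw"), pm, n_perm=19, seed=0)
        assert res.fst[0, 1] == pytest.approx(1.0)

    def test_matches_full_amova_on_pair(self, two_pop_fixed):
        aln, pm = two_pop_fixed
        dm = distance_matrix(aln, "raw")
        res = pairwise_fst(dm, pm, n_perm=0, seed=0)
        full = amova(dm, pm, grouping={"A": "g", "B": "g"}, n_perm=0)
        assert res.fst[0, 1] == pytest.approx(full.fst)

    def test_singleton_population_skipped(self):
        aln = Alignment(
            ("a1", "a2", "b1"), ("AAAA", "AAAT", "TTTA")
        )
        pm = _pm(
            {"a1": "A", "a2": "A", "b1": "B"}, {"A": "R", "B": "R"}
        )
        res = pairwise_fst(distance_matrix(aln, "raw"), pm, n_perm=9, seed=0)
        assert ("A", "B") in res.skipped


def _clustered_dataset(n_demes_west=3, n_demes_east=3, n_per=4, seed=11):
    """Two diverged clusters of demes with geographic coordinates."""
    rng = np.random.default_rng(seed)
    west_core = "".join(rng.choice(list("ACGT"), 40))
    east_core = list(west_core)
    for pos in rng.choice(40, size=12, replace=False):
        east_core[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[
            east_core[pos]
        ]
    east_core = "".join(east_core)
    ids, seqs, s2p, p2r, coords = [], [], {}, {}, {}
    for d in range(n_demes_west + n_demes_east):
        west = d < n_demes_west
        name = f"{'W' if west else 'E'}{d}"
        core = west_core if west else east_core
        p2r[name] = "west" if west else "east"
        coords[name] = (
            20.0 + d * 0.5,
            (100.0 if west else 115.0) + d * 0.3,
        )
        for i in range(n_per):
            sid = f"{name}_{i}"
            seq = list(core)
            pos = int(rng.integers(40))
            seq[pos] = str(rng.choice(list("ACGT")))
            ids.append(sid)
            seqs.append("".join(seq))
            s2p[sid] = name
    aln = Alignment(tuple(ids), tuple(seqs))
    return aln, PopulationMap(s2p, p2r, coords)


def exhaustive_best_fct(dm, pm, k, contiguous_only=True):
    """Enumeration oracle over all K-group partitions (optionally contiguous)."""
    pops = list(pm.populations)
    graph = gabriel_graph({p: pm.coordinates[p] for p in pops})
    import networkx as nx

    best = (-math.inf, None)
    for assignment in itertools.product(range(k), repeat=len(pops)):
        if set(assignment) != set(range(k)):
            continue
        if contiguous_only:
            ok = True
            for g in range(k):
                members = [p for p, a in zip(pops, assignment) if a == g]
                if not nx.is_connected(graph.subgraph(members)):
                    ok = False
                    break
            if not ok:
                continue
        grouping = {p: f"g{a}" for p, a in zip(pops, assignment)}
        try:
            fct = fct_for_grouping(dm, pm, grouping)
        except EstimationError:
            continue
        if fct > best[0]:
            best = (fct, grouping)
    return best


class TestSamova:
    def test_k_out_of_range(self, two_pop_fixed):
        aln, pm = two_pop_fixed
        dm = distance_matrix(aln, "raw")
        with pytest.raises(InputError):
            samova(dm, pm, k=2)  # K must be < number of populations

    def test_recovers_true_bipartition(self):
        aln, pm = _clustered_dataset()
        dm = distance_matrix(aln, "raw")
        res = samova(dm, pm, k=2, n_restarts=10, seed=0)
        parts = {frozenset(g) for g in res.best_partition}
        west = frozenset(p for p in pm.populations if p.startswith("W"))
        east = frozenset(p for p in pm.populations if p.startswith("E"))
        assert parts == {west, east}
        # FCT at the optimum equals the plain AMOVA FCT for that grouping
        grouping = {p: ("w" if p in west else "e") for p in pm.populations}
        assert res.fct == pytest.approx(
            fct_for_grouping(dm, pm, grouping), abs=1e-10
        )

    def test_matches_exhaustive_oracle(self):
        aln, pm = _clustered_dataset(n_demes_west=3, n_demes_east=3)
        dm = distance_matrix(aln, "raw")
        best_fct, _ = exhaustive_best_fct(dm, pm, k=2)
        res = samova(dm, pm, k=2, n_restarts=8, seed=1)
        assert res.fct == pytest.approx(best_fct, abs=1e-10)

    def test_three_demes_isolates_most_divergent(self):
        # K = n_pops - 1 on 3 demes: best split isolates the divergent deme
        aln, pm = _clustered_dataset(n_demes_west=2, n_demes_east=1)
        dm = distance_matrix(aln, "raw")
        res = samova(dm, pm, k=2, n_restarts=8, seed=2)
        singleton = [g for g in res.best_partition if len(g) == 1]
        assert singleton and singleton[0][0].startswith("E")

    def test_fct_nondecreasing_in_k(self):
        aln, pm = _clustered_dataset(n_demes_west=3, n_demes_east=3)
        dm = distance_matrix(aln, "raw")
        fcts = [
            samova(dm, pm, k=k, n_restarts=8, seed=3).fct for k in (2, 3, 4)
        ]
        # refinement does not guarantee exact monotonicity (the moment
        # coefficients change with K), so allow a small tolerance
        for lo, hi in zip(fcts, fcts[1:]):
            assert hi >= lo - 0.05

    def test_restart_bundle_hits_global_optimum(self):
        # >= 95% of seeded restart bundles attain the enumeration optimum
        aln, pm = _clustered_dataset(n_demes_west=3, n_demes_east=2, seed=23)
        dm = distance_matrix(aln, "raw")
        best_fct, _ = exhaustive_best_fct(dm, pm, k=2)
        hits = 0
        for seed in range(20):
            res = samova(dm, pm, k=2, n_restarts=5, seed=seed)
            if res.fct >= best_fct - 1e-10:
                hits += 1
        assert hits >= 19


class TestMantel:
    @staticmethod
    def _sym(rng, n):
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return a

    def test_identity_correlation(self):
        a = self._sym(np.random.default_rng(0), 6)
        r, p = mantel(a, a.copy(), n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_negated_correlation(self):
        rng = np.random.default_rng(1)
        a = self._sym(rng, 6)
        b = a.max() + 1 - a
        np.fill_diagonal(b, 0)
        r, _ = mantel(a, b, n_perm=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        a = np.zeros((4, 4))
        with pytest.raises(EstimationError):
            mantel(a, a, n_perm=9)

    def test_p_matches_exhaustive_enumeration(self):
        # 5x5 matrices: compare the sampled permutation p against the exact
        # exhaustive-permutation p over all 120 orderings
        rng = np.random.default_rng(9)
        a = self._sym(rng, 5)
        b = self._sym(rng, 5)
        il = np.tril_indices(5, k=-1)
        va = a[il]
        r_obs = np.corrcoef(va, b[il])[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(range(5)):
            perm = np.array(perm)
            r_p = np.corrcoef(va, b[np.ix_(perm, perm)][il])[0, 1]
            total += 1
            if r_p >= r_obs - 1e-12:
                count += 1
        exact_p = count / total
        _, p = mantel(a, b, n_perm=4999, seed=3)
        assert p == pytest.approx(exact_p, abs=0.03)
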