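"""Hierarchical molecular variance, pairwise FST, SAMOVA, and Mantel test.

AMOVA decomposes squared molecular distances (for haplotypic data the
squared Euclidean distance between two sequences equals their raw difference
count) into among-group / among-population / within-population components by
the standard moment equations, with level-appropriate permutation schemes.
SAMOVA searches for the K-group, geographically contiguous partition of
populations maximizing FCT by simulated annealing over a Gabriel
neighborhood graph.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from .distances import DistanceMatrix
from .errors import EstimationError, InputError
from .io import PopulationMap

log = logging.getLogger("phylopop.structure")


def _squared(dm: DistanceMatrix) -> np.ndarray:
    """Squared molecular distances: raw counts are already squared Euclidean."""
    m = np.asarray(dm.matrix, dtype=float)
    if np.isnan(m).any():
        raise InputError("distance matrix contains NaN (saturated pairs)")
    return m if dm.metric == "raw" else m**2


@dataclass(frozen=True)
class AmovaLevel:
    name: str
    df: int
    ss: float
    variance: float
    pct: float


@dataclass(frozen=True)
class AmovaResult:
    levels: tuple[AmovaLevel, ...]
    fst: float
    fsc: float | None
    fct: float | None
    p_fst: float | None
    p_fsc: float | None
    p_fct: float | None
    n_permutations: int
    negative_components: bool

    def to_dict(self) -> dict:
        return {
            "levels": [
                {
                    "source": lv.name,
                    "df": lv.df,
                    "SS": lv.ss,
                    "variance_component": lv.variance,
                    "pct_variation": lv.pct,
                }
                for lv in self.levels
            ],
            "FST": self.fst,
            "FSC": self.fsc,
            "FCT": self.fct,
            "p_FST": self.p_fst,
            "p_FSC": self.p_fsc,
            "p_FCT": self.p_fct,
            "n_permutations": self.n_permutations,
            "negative_components_flag": self.negative_components,
        }

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\tdf\tSS\tVC\tPV_pct\n")
            for lv in self.levels:
                fh.write(
                    f"{lv.name}\t{lv.df}\t{lv.ss:.6f}\t{lv.variance:.6f}"
                    f"\t{lv.pct:.2f}\n"
                )
            fh.write(f"# FST={self.fst:.6f}")
            if self.fct is not None:
                fh.write(f" FSC={self.fsc:.6f} FCT={self.fct:.6f}")
            fh.write("\n")


def _pop_cross_sums(d2: np.ndarray, pop_index: np.ndarray, n_pops: int) -> np.ndarray:
    """S[p, q] = double (ordered) sum of d2 over samples of pops p and q."""
    m = np.zeros((len(pop_index), n_pops))
    for p in range(n_pops):
        m[:, p] = d2[:, pop_index == p].sum(axis=1)
    s = np.zeros((n_pops, n_pops))
    for p in range(n_pops):
        s[p] = m[pop_index == p].sum(axis=0)
    return s


def _two_level_components(
    s: np.ndarray, sizes: np.ndarray
) -> tuple[float, float, tuple[float, float]]:
    """(sigma_a, sigma_c, (ss_among, ss_within)) for pops vs total."""
    n_total = float(sizes.sum())
    n_pops = len(sizes)
    ssd_total = s.sum() / (2.0 * n_total)
    ssd_wp = float(sum(s[p, p] / (2.0 * sizes[p]) for p in range(n_pops)))
    ssd_ap = ssd_total - ssd_wp
    df_wp = n_total - n_pops
    df_ap = n_pops - 1
    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    n_prime = (n_total - float((sizes**2).sum()) / n_total) / df_ap
    ms_ap = ssd_ap / df_ap
    sigma_a = (ms_ap - sigma_c) / n_prime
    return sigma_a, sigma_c, (ssd_ap, ssd_wp)


def _three_level_components(
    s: np.ndarray, sizes: np.ndarray, group_of_pop: np.ndarray
) -> tuple[float, float, float, tuple[float, float, float]]:
    """(sigma_a, sigma_b, sigma_c, (ss_ag, ss_apwg, ss_wp))."""
    n_total = float(sizes.sum())
    n_pops = len(sizes)
    groups = np.unique(group_of_pop)
    n_groups = len(groups)
    ssd_total = s.sum() / (2.0 * n_total)
    ssd_wp = float(sum(s[p, p] / (2.0 * sizes[p]) for p in range(n_pops)))
    ssd_wg = 0.0
    group_sizes = np.zeros(n_groups)
    sum_np2_over_ng = 0.0
    for gi, g in enumerate(groups):
        pops_g = np.where(group_of_pop == g)[0]
        n_g = float(sizes[pops_g].sum())
        group_sizes[gi] = n_g
        ssd_wg += s[np.ix_(pops_g, pops_g)].sum() / (2.0 * n_g)
        sum_np2_over_ng += float((sizes[pops_g] ** 2).sum()) / n_g
    ssd_ag = ssd_total - ssd_wg
    ssd_apwg = ssd_wg - ssd_wp
    df_wp = n_total - n_pops
    df_apwg = n_pops - n_groups
    df_ag = n_groups - 1
    if df_apwg <= 0 or df_ag <= 0 or df_wp <= 0:
        raise EstimationError("degenerate hierarchy for three-level AMOVA")
    sigma_c = ssd_wp / df_wp
    n_coef = (n_total - sum_np2_over_ng) / df_apwg
    n2_coef = (sum_np2_over_ng - float((sizes**2).sum()) / n_total) / df_ag
    n3_coef = (n_total - float((group_sizes**2).sum()) / n_total) / df_ag
    sigma_b = (ssd_apwg / df_apwg - sigma_c) / n_coef
    sigma_a = (ssd_ag / df_ag - sigma_c - n2_coef * sigma_b) / n3_coef
    return sigma_a, sigma_b, sigma_c, (ssd_ag, ssd_apwg, ssd_wp)


def amova(
    dm: DistanceMatrix,
    pm: PopulationMap,
    grouping: Mapping[str, str] | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> AmovaResult:
    """Two- or three-level AMOVA with permutation p-values.

    ``grouping`` maps population -> group; default uses the map's regions.
    With a single group a two-level analysis (among/within populations) is
    returned. Negative variance components are retained in sums and flagged.
    """
    d2 = _squared(dm)
    pops = list(pm.populations)
    if grouping is None:
        grouping = dict(pm.population_to_region)
    pop_labels = pm.labels_for(dm.ids, "population")
    pop_idx = np.array([pops.index(p) for p in pop_labels])
    sizes = np.bincount(pop_idx, minlength=len(pops)).astype(float)
    if (sizes == 0).any():
        keep = sizes > 0
        remap = {old: new for new, old in enumerate(np.where(keep)[0])}
        pops = [p for p, k in zip(pops, keep) if k]
        pop_idx = np.array([remap[i] for i in pop_idx])
        sizes = sizes[keep]
    if not d2.any():
        raise EstimationError("all-zero distance matrix: indices undefined")
    if len(pops) == 1:
        # degenerate case: all variation within the single population
        ssd_total = d2.sum() / (2.0 * sizes[0])
        df = int(sizes[0]) - 1
        level = AmovaLevel(
            "Within populations", df, ssd_total, ssd_total / df, 100.0
        )
        return AmovaResult(
            levels=(level,), fst=math.nan, fsc=None, fct=None,
            p_fst=None, p_fsc=None, p_fct=None,
            n_permutations=0, negative_components=False,
        )
    groups = sorted({grouping[p] for p in pops})
    group_of_pop = np.array([groups.index(grouping[p]) for p in pops])
    n_total = int(sizes.sum())
    rng = np.random.default_rng(seed)
    s = _pop_cross_sums(d2, pop_idx, len(pops))

    if len(groups) < 2 or len(groups) == len(pops):
        sigma_a, sigma_c, (ss_ap, ss_wp) = _two_level_components(s, sizes)
        total = sigma_a + sigma_c
        if total <= 0:
            raise EstimationError("total variance is zero")
        fst = sigma_a / total
        b = 0
        for _ in range(n_perm):
            perm = rng.permutation(pop_idx)
            sp = _pop_cross_sums(d2, perm, len(pops))
            sa, sc, _ = _two_level_components(sp, sizes)
            if sa + sc > 0 and sa / (sa + sc) >= fst - 1e-12:
                b += 1
        p_fst = (b + 1) / (n_perm + 1) if n_perm else None
        levels = (
            AmovaLevel("Among populations", len(pops) - 1, ss_ap, sigma_a,
                       100.0 * sigma_a / total),
            AmovaLevel("Within populations", n_total - len(pops), ss_wp,
                       sigma_c, 100.0 * sigma_c / total),
        )
        return AmovaResult(
            levels=levels, fst=fst, fsc=None, fct=None,
            p_fst=p_fst, p_fsc=None, p_fct=None,
            n_permutations=n_perm,
            negative_components=bool(sigma_a < 0 or sigma_c < 0),
        )

    sigma_a, sigma_b, sigma_c, sss = _three_level_components(
        s, sizes, group_of_pop
    )
    total = sigma_a + sigma_b + sigma_c
    if total <= 0:
        raise EstimationError("total variance is zero")
    fst = (sigma_a + sigma_b) / total
    fsc = sigma_b / (sigma_b + sigma_c) if sigma_b + sigma_c != 0 else math.nan
    fct = sigma_a / total

    def stats_for(perm_pop_idx: np.ndarray, perm_groups: np.ndarray):
        sp = _pop_cross_sums(d2, perm_pop_idx, len(pops))
        return _three_level_components(sp, sizes, perm_groups)

    b_fst = b_fsc = b_fct = 0
    group_of_sample = group_of_pop[pop_idx]
    for _ in range(n_perm):
        # FST: permute individuals among all populations
        perm = rng.permutation(pop_idx)
        sa, sb, sc, _ = stats_for(perm, group_of_pop)
        tot = sa + sb + sc
        if tot != 0 and (sa + sb) / tot >= fst - 1e-12:
            b_fst += 1
        # FSC: permute individuals among populations within groups
        perm2 = pop_idx.copy()
        for gi in range(len(groups)):
            mask = group_of_sample == gi
            perm2[mask] = rng.permutation(pop_idx[mask])
        sa, sb, sc, _ = stats_for(perm2, group_of_pop)
        if sb + sc != 0 and sb / (sb + sc) >= fsc - 1e-12:
            b_fsc += 1
        # FCT: permute whole populations among groups
        permg = rng.permutation(group_of_pop)
        try:
            sa, sb, sc, _ = _three_level_components(s, sizes, permg)
        except EstimationError:
            continue
        tot = sa + sb + sc
        if tot != 0 and sa / tot >= fct - 1e-12:
            b_fct += 1
    p_fst = (b_fst + 1) / (n_perm + 1) if n_perm else None
    p_fsc = (b_fsc + 1) / (n_perm + 1) if n_perm else None
    p_fct = (b_fct + 1) / (n_perm + 1) if n_perm else None
    ss_ag, ss_apwg, ss_wp = sss
    levels = (
        AmovaLevel("Among groups", len(groups) - 1, ss_ag, sigma_a,
                   100.0 * sigma_a / total),
        AmovaLevel("Among populations within groups",
                   len(pops) - len(groups), ss_apwg, sigma_b,
                   100.0 * sigma_b / total),
        AmovaLevel("Within populations", n_total - len(pops), ss_wp, sigma_c,
                   100.0 * sigma_c / total),
    )
    return AmovaResult(
        levels=levels, fst=fst, fsc=fsc, fct=fct,
        p_fst=p_fst, p_fsc=p_fsc, p_fct=p_fct,
        n_permutations=n_perm,
        negative_components=bool(min(sigma_a, sigma_b, sigma_c) < 0),
    )


@dataclass(frozen=True)
class PairwiseFstResult:
    populations: tuple[str, ...]
    fst: np.ndarray
    p: np.ndarray
    skipped: tuple[tuple[str, str], ...]

    def to_dict(self) -> dict:
        return {
            "populations": list(self.populations),
            "fst": self.fst.tolist(),
            "p": self.p.tolist(),
            "skipped_pairs": [list(t) for t in self.skipped],
        }


def pairwise_fst(
    dm: DistanceMatrix,
    pm: PopulationMap,
    n_perm: int = 999,
    seed: int | None = None,
) -> PairwiseFstResult:
    """Two-level AMOVA FST for every population pair with permutation p."""
    pops = list(pm.populations)
    fst = np.full((len(pops), len(pops)), np.nan)
    pval = np.full((len(pops), len(pops)), np.nan)
    np.fill_diagonal(fst, 0.0)
    skipped: list[tuple[str, str]] = []
    rng = np.random.default_rng(seed)
    sample_pops = pm.labels_for(dm.ids, "population")
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ids = [
                s for s, p in zip(dm.ids, sample_pops) if p in (pops[i], pops[j])
            ]
            counts = [sum(1 for s in ids if pm.population_of(s) == pops[i]),
                      sum(1 for s in ids if pm.population_of(s) == pops[j])]
            if min(counts) < 2:
                skipped.append((pops[i], pops[j]))
                log.warning("skipping pair %s-%s: singleton population",
                            pops[i], pops[j])
                continue
            sub = dm.submatrix(ids)
            sub_pm = PopulationMap(
                {s: pm.population_of(s) for s in ids},
                {pops[i]: "all", pops[j]: "all"},
                {
                    pops[i]: pm.coordinates.get(pops[i], (0.0, 0.0)),
                    pops[j]: pm.coordinates.get(pops[j], (0.0, 0.0)),
                },
            )
            try:
                res = amova(
                    sub, sub_pm, n_perm=n_perm,
                    seed=int(rng.integers(2**31)),
                )
            except EstimationError:
                fst[i, j] = fst[j, i] = 0.0
                pval[i, j] = pval[j, i] = 1.0
                continue
            fst[i, j] = fst[j, i] = res.fst
            pval[i, j] = pval[j, i] = res.p_fst
    return PairwiseFstResult(tuple(pops), fst, pval, tuple(skipped))


# ---------------------------------------------------------------------------
# SAMOVA
# ---------------------------------------------------------------------------


def _haversine(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance (km) between two decimal-degree points."""
    r = 6371.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def gabriel_graph(coords: Mapping[str, tuple[float, float]]) -> nx.Graph:
    """Gabriel neighborhood graph on great-circle distances.

    Edge (u, v) is kept unless some w lies strictly inside the circle with
    diameter uv, i.e. d(u,w)^2 + d(w,v)^2 < d(u,v)^2.
    """
    names = list(coords)
    g = nx.Graph()
    g.add_nodes_from(names)
    d = {
        (a, b): _haversine(*coords[a], *coords[b])
        for a in names
        for b in names
    }
    for i, u in enumerate(names):
        for v in names[i + 1 :]:
            duv2 = d[(u, v)] ** 2
            if any(
                d[(u, w)] ** 2 + d[(w, v)] ** 2 < duv2 - 1e-9
                for w in names
                if w not in (u, v)
            ):
                continue
            g.add_edge(u, v)
    return g


@dataclass(frozen=True)
class AnnealParams:
    """Geometric-cooling settings for the SAMOVA search."""

    n_steps: int = 500
    t_initial: float = 0.05
    t_final: float = 1e-4

    @property
    def alpha(self) -> float:
        return (self.t_final / self.t_initial) ** (1.0 / max(self.n_steps - 1, 1))


@dataclass(frozen=True)
class SamovaResult:
    k: int
    best_partition: tuple[tuple[str, ...], ...]
    fct: float
    fct_trajectory: tuple[float, ...]  # best FCT per restart
    n_restarts: int
    anneal: AnnealParams

    def to_dict(self) -> dict:
        return {
            "K": self.k,
            "best_partition": [list(g) for g in self.best_partition],
            "FCT": self.fct,
            "fct_per_restart": list(self.fct_trajectory),
            "n_restarts": self.n_restarts,
            "anneal": {
                "n_steps": self.anneal.n_steps,
                "t_initial": self.anneal.t_initial,
                "t_final": self.anneal.t_final,
            },
        }


def fct_for_grouping(
    dm: DistanceMatrix, pm: PopulationMap, grouping: Mapping[str, str]
) -> float:
    """FCT of a fixed population partition (no permutations)."""
    res = amova(dm, pm, grouping=grouping, n_perm=0)
    if res.fct is None:
        raise EstimationError("grouping does not define >= 2 groups")
    return res.fct


class _FctEvaluator:
    """Cached population cross-sums so proposals are cheap to score."""

    def __init__(self, dm: DistanceMatrix, pm: PopulationMap):
        d2 = _squared(dm)
        self.pops = list(pm.populations)
        pop_idx = np.array(
            [self.pops.index(p) for p in pm.labels_for(dm.ids, "population")]
        )
        self.sizes = np.bincount(pop_idx, minlength=len(self.pops)).astype(float)
        self.s = _pop_cross_sums(d2, pop_idx, len(self.pops))

    def fct(self, assignment: np.ndarray) -> float:
        sa, sb, sc, _ = _three_level_components(self.s, self.sizes, assignment)
        tot = sa + sb + sc
        if tot == 0:
            return -math.inf
        return sa / tot


def samova(
    dm: DistanceMatrix,
    pm: PopulationMap,
    k: int,
    n_restarts: int = 100,
    anneal: AnnealParams | None = None,
    seed: int | None = None,
    contiguity: bool = True,
) -> SamovaResult:
    """Search for the K-group partition of populations maximizing FCT.

    Simulated annealing with geometric cooling; proposals move one population
    to the group of a Gabriel-graph neighbor, keeping every group non-empty
    and (with ``contiguity``) connected. Best-of-restarts is returned.
    """
    pops = list(pm.populations)
    if not 2 <= k < len(pops):
        raise InputError(f"K must satisfy 2 <= K < {len(pops)}, got {k}")
    anneal = anneal or AnnealParams()
    ev = _FctEvaluator(dm, pm)
    graph = (
        gabriel_graph({p: pm.coordinates[p] for p in pops})
        if contiguity
        else nx.complete_graph(pops)
    )
    rng = np.random.default_rng(seed)
    pop_pos = {p: i for i, p in enumerate(pops)}

    def connected(members: list[str]) -> bool:
        if not contiguity:
            return True
        sub = graph.subgraph(members)
        return len(members) > 0 and nx.is_connected(sub)

    def random_partition() -> np.ndarray:
        while True:
            seeds = rng.choice(len(pops), size=k, replace=False)
            assign = np.full(len(pops), -1)
            frontier = {int(s): [pops[s]] for s in seeds}
            for gi, s in enumerate(seeds):
                assign[s] = gi
            unassigned = set(range(len(pops))) - set(int(s) for s in seeds)
            progress = True
            while unassigned and progress:
                progress = False
                order = rng.permutation(sorted(unassigned))
                for pi in order:
                    nbr_groups = {
                        assign[pop_pos[q]]
                        for q in graph.neighbors(pops[pi])
                        if assign[pop_pos[q]] >= 0
                    }
                    if nbr_groups:
                        assign[pi] = int(
                            rng.choice(sorted(int(g) for g in nbr_groups))
                        )
                        unassigned.discard(pi)
                        progress = True
            if not unassigned:
                return assign

    best_assign = None
    best_fct = -math.inf
    trajectory: list[float] = []
    for _ in range(n_restarts):
        assign = random_partition()
        cur = ev.fct(assign)
        local_best, local_assign = cur, assign.copy()
        temp = anneal.t_initial
        for _ in range(anneal.n_steps):
            pi = int(rng.integers(len(pops)))
            gi = assign[pi]
            members = [p for p, a in zip(pops, assign) if a == gi]
            if len(members) <= 1:
                temp *= anneal.alpha
                continue
            nbr_groups = sorted(
                {
                    int(assign[pop_pos[q]])
                    for q in graph.neighbors(pops[pi])
                    if assign[pop_pos[q]] != gi
                }
            )
            if not nbr_groups:
                temp *= anneal.alpha
                continue
            target = int(nbr_groups[int(rng.integers(len(nbr_groups)))])
            remaining = [p for p in members if p != pops[pi]]
            if not connected(remaining):
                temp *= anneal.alpha
                continue
            trial = assign.copy()
            trial[pi] = target
            try:
                val = ev.fct(trial)
            except EstimationError:
                temp *= anneal.alpha
                continue
            if val >= cur or rng.random() < math.exp((val - cur) / max(temp, 1e-12)):
                assign, cur = trial, val
                if cur > local_best:
                    local_best, local_assign = cur, assign.copy()
            temp *= anneal.alpha
        trajectory.append(local_best)
        if local_best > best_fct:
            best_fct, best_assign = local_best, local_assign
    partition = tuple(
        tuple(p for p, a in zip(pops, best_assign) if a == gi)
        for gi in sorted(set(int(a) for a in best_assign))
    )
    return SamovaResult(
        k=k,
        best_partition=partition,
        fct=float(best_fct),
        fct_trajectory=tuple(trajectory),
        n_restarts=n_restarts,
        anneal=anneal,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def mantel(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two symmetric matrices.

    r is the Pearson correlation over lower triangles; p is one-tailed
    (greater) from permutations of row/column order of the second matrix.
    """
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InputError("matrices must be square and of equal shape")
    n = a.shape[0]
    il = np.tril_indices(n, k=-1)
    va = a[il]
    if va.std() == 0 or b[il].std() == 0:
        raise EstimationError("zero variance in a distance triangle")
    r_obs = float(np.corrcoef(va, b[il])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = float(np.corrcoef(va, b[np.ix_(perm, perm)][il])[0, 1])
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p
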