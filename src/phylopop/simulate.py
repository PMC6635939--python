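"""Structured-coalescent simulator for end-to-end tests.

Generates alignments plus population maps with the statistical structure the
analysis pipeline assumes: an island model with two deme groups, restricted
between-group gene flow, an instantaneous expansion at a controllable scaled
time, and finite-sites K2P-style mutation (so reverse/parallel changes can
occur, which matters for haplotype collapsing and median networks).

Time units are mutational (a pair separated for time t accumulates
Poisson(t) differences): lineages mutate at rate 1/2 per unit, a deme of
scaled size theta imposes pairwise coalescence hazard 1/theta, and migration
rates are per lineage per unit time. At scaled time ``tau`` (going back) all
demes merge into one ancestral pool of size ``theta0`` - the instantaneous
expansion out of a single refugium.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError
from .io import Alignment, PopulationMap

log = logging.getLogger("phylopop.simulate")

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": "CT", "G": "CT", "C": "AG", "T": "AG",
}


@dataclass(frozen=True)
class DemeSpec:
    name: str
    n_samples: int
    group: str
    lat: float = 0.0
    lon: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run (seed mandatory)."""

    demes: tuple[DemeSpec, ...]
    seed: int
    theta1: float = 2.0  # present (post-expansion) scaled deme size
    theta0: float = 0.2  # ancestral (pre-expansion) scaled size
    tau: float | None = 4.0  # scaled expansion time; None = constant size
    m_within: float = 1.0  # per-lineage migration rate within a group
    m_between: float = 0.05  # per-lineage migration rate between groups
    seq_length: int = 586
    kappa: float = 10.0  # transition/transversion rate ratio
    merge_at_tau: bool = True

    def __post_init__(self) -> None:
        if not self.demes:
            raise InputError("config needs >= 1 deme")
        if any(d.n_samples < 1 for d in self.demes):
            raise InputError("every deme needs >= 1 sample")
        if self.theta1 <= 0 or (self.tau is not None and self.theta0 <= 0):
            raise InputError("theta values must be positive")
        if self.tau is not None and self.tau < 0:
            raise InputError("tau must be >= 0")
        if self.seq_length < 1:
            raise InputError("sequence length must be >= 1")
        if min(self.m_within, self.m_between) < 0:
            raise InputError("migration rates must be >= 0")
        groups = {d.group for d in self.demes}
        if (
            len(groups) > 1
            and self.m_between == 0
            and not (self.merge_at_tau and self.tau is not None)
        ):
            raise InputError(
                "isolated groups never coalesce: need m_between > 0 or "
                "merge_at_tau with a finite tau"
            )

    @property
    def n_total(self) -> int:
        return sum(d.n_samples for d in self.demes)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for d in self.demes:
            seen.setdefault(d.group)
        return tuple(seen)


@dataclass(frozen=True)
class SimulatedDataset:
    alignment: Alignment
    population_map: PopulationMap
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.alignment.write_fasta(outdir / "alignment.fasta")
        with open(outdir / "population_map.csv", "w") as fh:
            fh.write("sample,population,region,lat,lon\n")
            pmap = self.population_map
            for s in pmap.samples:
                pop = pmap.population_of(s)
                lat, lon = pmap.coordinates[pop]
                fh.write(
                    f"{s},{pop},{pmap.population_to_region[pop]},{lat},{lon}\n"
                )
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n"
        )


def _simulate_genealogy(config: SimulationConfig, rng: np.random.Generator):
    """Backward-in-time structured coalescent; returns (parents, lengths)."""
    demes = config.demes
    n_demes = len(demes)
    group_idx = {g: i for i, g in enumerate(config.groups)}
    deme_group = np.array([group_idx[d.group] for d in demes])
    n = config.n_total
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    node_time = np.zeros(n_nodes)
    lineage_deme: dict[int, int] = {}
    node = 0
    for di, d in enumerate(demes):
        for _ in range(d.n_samples):
            lineage_deme[node] = di
            node += 1
    next_node = n
    t = 0.0
    merged = False
    tau = config.tau
    same_group = [
        [q for q in range(n_demes) if q != p and deme_group[q] == deme_group[p]]
        for p in range(n_demes)
    ]
    other_group = [
        [q for q in range(n_demes) if deme_group[q] != deme_group[p]]
        for p in range(n_demes)
    ]
    while len(lineage_deme) > 1:
        active = list(lineage_deme)
        if merged:
            k = len(active)
            rate = k * (k - 1) / 2.0 / config.theta0
            t += rng.exponential(1.0 / rate)
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
        else:
            per_deme: dict[int, list[int]] = {}
            for lin, dm_i in lineage_deme.items():
                per_deme.setdefault(dm_i, []).append(lin)
            theta = config.theta1
            coal_rates = {
                dm_i: len(lins) * (len(lins) - 1) / 2.0 / theta
                for dm_i, lins in per_deme.items()
            }
            mig_rate_per_lin = config.m_within + config.m_between
            total_coal = sum(coal_rates.values())
            total_mig = mig_rate_per_lin * len(lineage_deme)
            total = total_coal + total_mig
            if total <= 0:
                raise InputError("zero total event rate; check parameters")
            wait = rng.exponential(1.0 / total)
            if tau is not None and t < tau <= t + wait and config.merge_at_tau:
                t = tau
                merged = True
                continue
            t += wait
            if rng.random() < total_mig / total:
                lin = active[int(rng.integers(len(active)))]
                src = lineage_deme[lin]
                choices: list[int] = []
                if (
                    config.m_between > 0
                    and other_group[src]
                    and rng.random()
                    < config.m_between / max(mig_rate_per_lin, 1e-300)
                ):
                    choices = other_group[src]
                elif same_group[src]:
                    choices = same_group[src]
                if choices:
                    lineage_deme[lin] = int(
                        choices[int(rng.integers(len(choices)))]
                    )
                continue
            # coalescence: pick a deme weighted by its rate
            demes_with, weights = zip(*coal_rates.items())
            weights = np.array(weights)
            if weights.sum() <= 0:
                continue
            dm_i = demes_with[
                int(rng.choice(len(demes_with), p=weights / weights.sum()))
            ]
            lins = per_deme[dm_i]
            i, j = rng.choice(len(lins), size=2, replace=False)
            a, b = lins[i], lins[j]
        new = next_node
        next_node += 1
        parent[a] = parent[b] = new
        node_time[new] = t
        dm_i = lineage_deme[a]
        del lineage_deme[a], lineage_deme[b]
        lineage_deme[new] = dm_i
        if next_node > n_nodes:  # pragma: no cover - safety net
            raise RuntimeError("coalescent bookkeeping overflow")
    lengths = np.zeros(n_nodes)
    for i in range(n_nodes):
        if parent[i] >= 0:
            lengths[i] = node_time[parent[i]] - node_time[i]
    return parent, lengths, node_time[-1]


def _mutate(
    parent: np.ndarray,
    lengths: np.ndarray,
    n_leaves: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[str], int]:
    """Forward K2P mutation from a random root sequence; finite sites."""
    n_nodes = len(parent)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for i in range(n_nodes):
        if parent[i] >= 0:
            children[parent[i]].append(i)
    k = config.seq_length
    root = rng.integers(0, 4, size=k)
    seqs = [None] * n_nodes
    p_ts = config.kappa / (config.kappa + 2.0)
    n_mut = 0
    stack = [(n_nodes - 1, root)]
    while stack:
        node, seq = stack.pop()
        n_events = rng.poisson(0.5 * lengths[node])
        if n_events:
            seq = seq.copy()
            sites = rng.integers(0, k, size=n_events)
            for site in sites:
                base = _BASES[seq[site]]
                if rng.random() < p_ts:
                    new = _TRANSITION[base]
                else:
                    new = _TRANSVERSIONS[base][int(rng.integers(2))]
                seq[site] = _BASES.index(new)
            n_mut += n_events
        seqs[node] = seq
        for ch in children[node]:
            stack.append((ch, seq))
    leaves = ["".join(_BASES[b] for b in seqs[i]) for i in range(n_leaves)]
    return leaves, n_mut


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run one simulation; deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    parent, lengths, depth = _simulate_genealogy(config, rng)
    leaves, n_mut = _mutate(parent, lengths, config.n_total, config, rng)
    ids: list[str] = []
    sample_to_pop: dict[str, str] = {}
    pop_to_region: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    for d in config.demes:
        pop_to_region[d.name] = d.group
        coords[d.name] = (d.lat, d.lon)
        for i in range(d.n_samples):
            sid = f"{d.name}_{i + 1:02d}"
            ids.append(sid)
            sample_to_pop[sid] = d.name
    aln = Alignment(ids=tuple(ids), seqs=tuple(leaves))
    pmap = PopulationMap(sample_to_pop, pop_to_region, coords)
    truth = {
        "tau": config.tau,
        "theta0": config.theta0,
        "theta1": config.theta1,
        "m_within": config.m_within,
        "m_between": config.m_between,
        "seq_length": config.seq_length,
        "kappa": config.kappa,
        "seed": config.seed,
        "tmrca": float(depth),
        "n_mutations": int(n_mut),
        "partition": {d.name: d.group for d in config.demes},
    }
    return SimulatedDataset(alignment=aln, population_map=pmap, truth=truth)


def make_two_refugia_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """23-deme preset emulating the surveyed two-refugium geography.

    Deme names, sample sizes, coordinates and the two-group split follow the
    bundled survey (236 samples total); between-group gene flow is low and
    an instantaneous expansion sits deep enough that within-group coalescence
    typically predates it.
    """
    from .datasets import coi_survey, region_of

    demes = tuple(
        DemeSpec(
            name=r.abbr,
            n_samples=r.n,
            group=region_of(r.abbr),
            lat=r.lat,
            lon=r.lon,
        )
        for r in coi_survey()
    )
    params = dict(
        demes=demes,
        seed=seed,
        theta1=2.0,
        theta0=0.2,
        tau=8.0,
        m_within=2.0,
        m_between=0.02,
        seq_length=586,
        kappa=10.0,
        merge_at_tau=True,
    )
    params.update(overrides)
    return SimulationConfig(**params)
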