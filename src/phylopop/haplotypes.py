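"""Haplotype collapsing, diversity statistics, and differentiation.

Collapsing uses complete deletion: columns containing any ambiguity code or
gap in any sequence are discarded before comparing sequences, so haplotype
identity is a true equivalence relation. Diversity follows the unbiased
gene-diversity estimator h = n(1 - sum p_i^2)/(n - 1) with its sampling
variance; differentiation (HS, HT, GST, NST) follows the permutation-test
framework of haplotype-frequency vs distance-weighted diversities.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .distances import DistanceMatrix, raw_differences
from .errors import EstimationError, InputError
from .io import Alignment, PopulationMap, UNAMBIGUOUS

log = logging.getLogger("phylopop.haplotypes")


def retained_columns(aln: Alignment) -> tuple[int, ...]:
    """0-based indices of columns with an unambiguous base in every sequence."""
    cols = []
    for col in range(aln.length):
        if all(seq[col] in UNAMBIGUOUS for seq in aln.seqs):
            cols.append(col)
    return tuple(cols)


@dataclass(frozen=True)
class HaplotypeCatalog:
    """Distinct haplotypes with a population x haplotype count matrix.

    ``labels`` are H1..HNh in first-observed order; ``counts[p, h]`` is the
    number of samples of population ``populations[p]`` carrying haplotype
    ``labels[h]``. ``sequences`` holds a full-length representative per
    haplotype (empty when built from printed counts only).
    """

    labels: tuple[str, ...]
    populations: tuple[str, ...]
    counts: np.ndarray
    sequences: tuple[str, ...] = ()
    keys: tuple[str, ...] = ()  # complete-deletion-reduced haplotype strings
    sample_to_haplotype: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.populations), len(self.labels)):
            raise InputError("count matrix shape mismatch")
        if (self.counts < 0).any():
            raise InputError("negative haplotype counts")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_haplotypes(self) -> int:
        return len(self.labels)

    @property
    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def population_counts(self, population: str) -> np.ndarray:
        return self.counts[self.populations.index(population)]

    @classmethod
    def from_counts(
        cls, counts_by_pop: Mapping[str, Mapping[str, int]]
    ) -> "HaplotypeCatalog":
        """Build a catalog from printed per-population haplotype counts."""
        pops = tuple(counts_by_pop)
        labels: dict[str, None] = {}
        for pop_counts in counts_by_pop.values():
            for label in pop_counts:
                labels.setdefault(label)
        label_list = tuple(labels)
        mat = np.zeros((len(pops), len(label_list)), dtype=int)
        for i, pop in enumerate(pops):
            for label, c in counts_by_pop[pop].items():
                mat[i, label_list.index(label)] = c
        return cls(labels=label_list, populations=pops, counts=mat)

    def haplotype_distance_matrix(self) -> DistanceMatrix:
        """Raw per-site differences between haplotype sequences."""
        if not self.sequences:
            raise InputError("catalog has no sequences (built from counts)")
        n = self.n_haplotypes
        m = np.zeros((n, n), dtype=float)
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = raw_differences(
                    self.keys[i] if self.keys else self.sequences[i],
                    self.keys[j] if self.keys else self.sequences[j],
                )
        return DistanceMatrix(self.labels, m, "raw")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("population\t" + "\t".join(self.labels) + "\n")
            for pop, row in zip(self.populations, self.counts):
                fh.write(pop + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    def write_fasta(self, path: str | Path) -> None:
        if not self.sequences:
            raise InputError("catalog has no sequences (built from counts)")
        with open(path, "w") as fh:
            for label, seq, total in zip(
                self.labels, self.sequences, self.pooled_counts
            ):
                fh.write(f">{label} count={int(total)}\n{seq}\n")

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "populations": list(self.populations),
            "counts": self.counts.tolist(),
            "n_total": self.n_total,
            "n_haplotypes": self.n_haplotypes,
        }


def collapse_haplotypes(aln: Alignment, pm: PopulationMap) -> HaplotypeCatalog:
    """Collapse identical sequences (complete deletion) into haplotypes."""
    pm.validate_against(aln)
    cols = retained_columns(aln)
    if not cols:
        raise EstimationError("no unambiguous columns retained for collapsing")
    keys = ["".join(seq[c] for c in cols) for seq in aln.seqs]
    label_of_key: dict[str, str] = {}
    representative: dict[str, str] = {}
    sample_to_hap: dict[str, str] = {}
    for sid, seq, key in zip(aln.ids, aln.seqs, keys):
        if key not in label_of_key:
            label = f"H{len(label_of_key) + 1}"
            label_of_key[key] = label
            representative[label] = seq
        sample_to_hap[sid] = label_of_key[key]
    labels = tuple(label_of_key.values())
    pops = pm.populations
    mat = np.zeros((len(pops), len(labels)), dtype=int)
    label_idx = {lab: i for i, lab in enumerate(labels)}
    pop_idx = {pop: i for i, pop in enumerate(pops)}
    for sid in aln.ids:
        mat[pop_idx[pm.population_of(sid)], label_idx[sample_to_hap[sid]]] += 1
    key_of_label = {v: k for k, v in label_of_key.items()}
    log.info("collapsed %d sequences into %d haplotypes", aln.n, len(labels))
    return HaplotypeCatalog(
        labels=labels,
        populations=pops,
        counts=mat,
        sequences=tuple(representative[lab] for lab in labels),
        keys=tuple(key_of_label[lab] for lab in labels),
        sample_to_haplotype=sample_to_hap,
    )


def haplotype_diversity(counts: Sequence[int]) -> tuple[float, float]:
    """Unbiased gene diversity h and its standard deviation.

    h = n(1 - sum p_i^2)/(n - 1);
    V(h) = (2/(n(n-1))) * {2(n-2)[sum p^3 - (sum p^2)^2]
                           + sum p^2 - (sum p^2)^2}.
    """
    arr = np.asarray([c for c in counts if c > 0], dtype=float)
    n = arr.sum()
    if n < 2:
        raise EstimationError("gene diversity needs n >= 2 samples")
    p = arr / n
    sp2 = float((p**2).sum())
    sp3 = float((p**3).sum())
    h = n * (1.0 - sp2) / (n - 1.0)
    v = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (sp3 - sp2**2) + sp2 - sp2**2
    )
    return float(h), math.sqrt(max(v, 0.0))


def pooled_diversity(cat: HaplotypeCatalog) -> tuple[float, float]:
    """Species-level gene diversity from pooled haplotype counts."""
    return haplotype_diversity(cat.pooled_counts)


def nucleotide_diversity(aln: Alignment) -> float:
    """Mean pairwise proportion of differing sites (pairwise deletion)."""
    if aln.n < 2:
        raise EstimationError("nucleotide diversity needs >= 2 sequences")
    from .distances import _pair_counts, encode_alignment

    codes = encode_alignment(aln)
    total = 0.0
    n_pairs = 0
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            ts, tv, n_sites = _pair_counts(codes[i], codes[j])
            if n_sites == 0:
                raise EstimationError(
                    f"no comparable sites between {aln.ids[i]!r} and "
                    f"{aln.ids[j]!r}"
                )
            total += (ts + tv) / n_sites
            n_pairs += 1
    return total / n_pairs


@dataclass(frozen=True)
class DiversityStats:
    """Per-population and total diversity (Table-1-style rows)."""

    populations: tuple[str, ...]
    n: tuple[int, ...]
    n_haplotypes: tuple[int, ...]
    h: tuple[float, ...]
    h_sd: tuple[float, ...]
    pi: tuple[float | None, ...]
    total_n: int
    total_h: float
    total_h_sd: float
    total_pi: float | None

    def to_dict(self) -> dict:
        return {
            "populations": [
                {
                    "population": pop,
                    "n": n,
                    "n_haplotypes": nh,
                    "h": h,
                    "h_sd": sd,
                    "pi": pi,
                }
                for pop, n, nh, h, sd, pi in zip(
                    self.populations,
                    self.n,
                    self.n_haplotypes,
                    self.h,
                    self.h_sd,
                    self.pi,
                )
            ],
            "total": {
                "n": self.total_n,
                "h": self.total_h,
                "h_sd": self.total_h_sd,
                "pi": self.total_pi,
            },
        }


def diversity_table(
    cat: HaplotypeCatalog,
    aln: Alignment | None = None,
    pm: PopulationMap | None = None,
) -> DiversityStats:
    """Per-population h(SD) and pi plus pooled totals.

    pi requires sequences; when the catalog was built from printed counts
    only, pass ``aln``/``pm`` as None and pi fields are None.
    """
    hs, sds, pis, ns, nhs = [], [], [], [], []
    for pop in cat.populations:
        counts = cat.population_counts(pop)
        n = int(counts.sum())
        ns.append(n)
        nhs.append(int((counts > 0).sum()))
        if n >= 2:
            h, sd = haplotype_diversity(counts)
        else:
            h, sd = 0.0, 0.0
        hs.append(h)
        sds.append(sd)
        if aln is not None and pm is not None and n >= 2:
            pis.append(nucleotide_diversity(aln.subset(pm.samples_in(pop))))
        else:
            pis.append(None)
    th, tsd = pooled_diversity(cat)
    tpi = nucleotide_diversity(aln) if aln is not None else None
    return DiversityStats(
        populations=cat.populations,
        n=tuple(ns),
        n_haplotypes=tuple(nhs),
        h=tuple(hs),
        h_sd=tuple(sds),
        pi=tuple(pis),
        total_n=cat.n_total,
        total_h=th,
        total_h_sd=tsd,
        total_pi=tpi,
    )


@dataclass(frozen=True)
class DifferentiationStats:
    """HS/HT/GST/NST with bootstrap SEs and the NST > GST permutation test."""

    hs: float
    ht: float
    gst: float
    nst: float
    se_hs: float
    se_ht: float
    se_gst: float
    se_nst: float
    p_nst_gt_gst: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "HS": self.hs,
            "HT": self.ht,
            "GST": self.gst,
            "NST": self.nst,
            "SE": {
                "HS": self.se_hs,
                "HT": self.se_ht,
                "GST": self.se_gst,
                "NST": self.se_nst,
            },
            "p_NST_greater_GST": self.p_nst_gt_gst,
            "n_permutations": self.n_permutations,
        }


def _vs_vt(freqs: np.ndarray, sizes: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Within (vS) and total (vT) distance-weighted diversities.

    ``freqs``: (s, H) per-population haplotype frequencies; ``sizes``: (s,)
    sample sizes; ``d``: (H, H) haplotype distance matrix. With d = 1 - I this
    reduces to the gene-diversity estimators HS / HT. vT uses the unweighted
    mean frequency vector plus the harmonic-mean small-sample correction.
    """
    s = len(sizes)
    v_i = (sizes / (sizes - 1.0)) * np.einsum("ik,kl,il->i", freqs, d, freqs)
    v_s = float(v_i.mean())
    xbar = freqs.mean(axis=0)
    n_harm = s / float((1.0 / sizes).sum())
    v_t = float(xbar @ d @ xbar) + v_s / (n_harm * s)
    return v_s, v_t


def _gst_nst_point(
    counts: np.ndarray, d_unit: np.ndarray, d_hap: np.ndarray
) -> tuple[float, float, float, float]:
    sizes = counts.sum(axis=1).astype(float)
    freqs = counts / sizes[:, None]
    hs, ht = _vs_vt(freqs, sizes, d_unit)
    if ht <= 0:
        raise EstimationError("HT = 0: differentiation undefined")
    vs, vt = _vs_vt(freqs, sizes, d_hap)
    if vt <= 0:
        raise EstimationError("vT = 0: NST undefined")
    return hs, ht, (ht - hs) / ht, (vt - vs) / vt


def gst_nst(
    cat: HaplotypeCatalog,
    hap_dm: DistanceMatrix | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    n_boot: int = 200,
) -> DifferentiationStats:
    """HS, HT, GST, NST with a permutation test of NST > GST.

    The permutation scheme reassigns haplotype identities to distance-matrix
    rows (GST is invariant; NST is recomputed). Standard errors come from
    bootstrap resampling of populations. Populations with n < 2 are dropped.
    """
    if hap_dm is None:
        hap_dm = cat.haplotype_distance_matrix()
    if tuple(hap_dm.ids) != tuple(cat.labels):
        raise InputError("haplotype distance matrix ids must match catalog")
    keep = cat.counts.sum(axis=1) >= 2
    if keep.sum() < 2:
        raise EstimationError("need >= 2 populations with >= 2 samples")
    if not keep.all():
        log.warning("dropping %d populations with n < 2", int((~keep).sum()))
    counts = cat.counts[keep].astype(float)
    n_h = cat.n_haplotypes
    d_unit = 1.0 - np.eye(n_h)
    d_hap = np.asarray(hap_dm.matrix, dtype=float)
    hs, ht, gst, nst = _gst_nst_point(counts, d_unit, d_hap)

    rng = np.random.default_rng(seed)
    obs = nst - gst
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_h)
        d_p = d_hap[np.ix_(perm, perm)]
        _, _, _, nst_p = _gst_nst_point(counts, d_unit, d_p)
        if nst_p - gst >= obs - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)

    boot = np.empty((n_boot, 4))
    s = counts.shape[0]
    for r in range(n_boot):
        idx = rng.integers(0, s, size=s)
        try:
            boot[r] = _gst_nst_point(counts[idx], d_unit, d_hap)
        except EstimationError:
            boot[r] = np.nan
    with np.errstate(invalid="ignore"):
        ses = np.nanstd(boot, axis=0, ddof=1)
    return DifferentiationStats(
        hs=hs,
        ht=ht,
        gst=gst,
        nst=nst,
        se_hs=float(ses[0]),
        se_ht=float(ses[1]),
        se_gst=float(ses[2]),
        se_nst=float(ses[3]),
        p_nst_gt_gst=p,
        n_permutations=n_perm,
    )
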