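"""Pairwise distance kernels and distance matrices.

Two metrics are provided: the Kimura two-parameter (K2P) distance in
substitutions per site and raw difference counts. Comparisons use pairwise
deletion: only columns where both sequences carry an unambiguous base
(A/C/G/T) enter a pair's comparison.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EstimationError, InputError
from .io import Alignment, PopulationMap

log = logging.getLogger("phylopop.distances")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = np.array([True, False, True, False])  # A, C, G, T


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Encode as an (n, k) uint8 array; A,C,G,T -> 0..3, anything else 255."""
    table = np.full(256, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        table[ord(base)] = code
    rows = [
        table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        for seq in aln.seqs
    ]
    return np.vstack(rows)


@dataclass(frozen=True)
class K2PDistance:
    """K2P distance with its transition (P) and transversion (Q) fractions."""

    d: float
    p: float
    q: float
    n_sites: int
    saturated: bool


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(transitions, transversions, comparable sites) for two encoded rows."""
    valid = (a < 4) & (b < 4)
    n_sites = int(valid.sum())
    diff = valid & (a != b)
    ts = int((diff & (_PURINE[a & 3] == _PURINE[b & 3])).sum())
    tv = int(diff.sum()) - ts
    return ts, tv, n_sites


def _k2p_from_counts(ts: int, tv: int, n_sites: int) -> K2PDistance:
    if n_sites == 0:
        raise EstimationError("no comparable (unambiguous) sites in pair")
    p = ts / n_sites
    q = tv / n_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PDistance(math.nan, p, q, n_sites, saturated=True)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PDistance(max(d, 0.0), p, q, n_sites, saturated=False)


def k2p_distance(seq_a: str, seq_b: str) -> K2PDistance:
    """K2P distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q) for one pair.

    Saturated pairs (log argument <= 0) are flagged rather than raised.
    """
    if len(seq_a) != len(seq_b):
        raise InputError("sequences must have equal length")
    aln = Alignment(ids=("a", "b"), seqs=(seq_a.upper(), seq_b.upper()))
    codes = encode_alignment(aln)
    return _k2p_from_counts(*_pair_counts(codes[0], codes[1]))


def raw_differences(seq_a: str, seq_b: str) -> int:
    """Number of differing unambiguous columns (pairwise deletion)."""
    if len(seq_a) != len(seq_b):
        raise InputError("sequences must have equal length")
    aln = Alignment(ids=("a", "b"), seqs=(seq_a.upper(), seq_b.upper()))
    codes = encode_alignment(aln)
    ts, tv, _ = _pair_counts(codes[0], codes[1])
    return ts + tv


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered sample ids.

    ``metric`` is "k2p" (substitutions/site) or "raw" (difference counts).
    Saturated K2P pairs hold NaN and are listed in ``saturated_pairs``.
    """

    ids: tuple[str, ...]
    matrix: np.ndarray
    metric: str
    saturated_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise InputError("matrix shape does not match ids")
        if not np.allclose(np.diag(m), 0.0):
            raise InputError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(m) < -1e-12:
                raise InputError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, sample_id: str) -> int:
        return self.ids.index(sample_id)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.index_of(s) for s in ids]
        sub = self.matrix[np.ix_(idx, idx)]
        sat = tuple(
            (a, b) for a, b in self.saturated_pairs if a in ids and b in ids
        )
        return DistanceMatrix(tuple(ids), sub, self.metric, sat)

    def write_square_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for sid, row in zip(self.ids, self.matrix):
                fh.write(sid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for sid, row in zip(self.ids, self.matrix):
                fh.write(
                    f"{sid[:10]:<10s} "
                    + " ".join(f"{v:.8f}" for v in row)
                    + "\n"
                )


def distance_matrix(aln: Alignment, metric: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix under ``metric`` ("k2p" | "raw")."""
    if metric not in ("k2p", "raw"):
        raise InputError(f"unknown metric: {metric!r}")
    codes = encode_alignment(aln)
    n = aln.n
    out = np.zeros((n, n), dtype=float)
    saturated: list[tuple[str, str]] = []
    valid = codes < 4
    purine = _PURINE[codes & 3] & valid
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        n_sites = both.sum(axis=1)
        diff = both & (codes[i] != codes[i + 1 :])
        ts = (diff & (purine[i] == purine[i + 1 :])).sum(axis=1)
        total = diff.sum(axis=1)
        if metric == "raw":
            out[i, i + 1 :] = total
            continue
        for off, (t_s, tot, ns) in enumerate(zip(ts, total, n_sites)):
            j = i + 1 + off
            if ns == 0:
                raise EstimationError(
                    f"no comparable sites between {aln.ids[i]!r} "
                    f"and {aln.ids[j]!r}"
                )
            k2p = _k2p_from_counts(int(t_s), int(tot - t_s), int(ns))
            out[i, j] = k2p.d
            if k2p.saturated:
                saturated.append((aln.ids[i], aln.ids[j]))
    out = out + out.T
    if saturated:
        log.warning("%d saturated K2P pairs flagged as NaN", len(saturated))
    return DistanceMatrix(aln.ids, out, metric, tuple(saturated))


@dataclass(frozen=True)
class WithinBetweenSummary:
    """Within- vs between-group distance summary for gap-style plots."""

    mean_within: float
    mean_between: float
    ratio: float
    within: tuple[float, ...]
    between: tuple[float, ...]
    n_excluded: int  # saturated / NaN pairs dropped from the summary

    def to_dict(self) -> dict:
        return {
            "mean_within": self.mean_within,
            "mean_between": self.mean_between,
            "ratio_between_over_within": self.ratio,
            "n_within_pairs": len(self.within),
            "n_between_pairs": len(self.between),
            "n_excluded_pairs": self.n_excluded,
        }


def within_between_summary(
    dm: DistanceMatrix, pm: PopulationMap, level: str = "population"
) -> WithinBetweenSummary:
    """Mean within-group and between-group distances over unordered pairs."""
    labels = pm.labels_for(dm.ids, level=level)
    if len(set(labels)) < 2:
        raise EstimationError("need >= 2 groups for a within/between summary")
    within: list[float] = []
    between: list[float] = []
    n_excluded = 0
    m = dm.matrix
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            v = m[i, j]
            if math.isnan(v):
                n_excluded += 1
                continue
            (within if labels[i] == labels[j] else between).append(float(v))
    if not within:
        raise EstimationError("no within-group pairs")
    mean_w = float(np.mean(within))
    mean_b = float(np.mean(between)) if between else math.nan
    ratio = mean_b / mean_w if mean_w > 0 else math.inf
    if n_excluded:
        log.warning("excluded %d NaN pairs from summary", n_excluded)
    return WithinBetweenSummary(
        mean_w, mean_b, ratio, tuple(within), tuple(between), n_excluded
    )
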