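"""Neutrality tests and sudden-expansion mismatch inference.

Tajima's D and Fu's Fs are computed from their defining formulas; their
significance comes from neutral coalescent simulation conditioned on the
sample size (theta-hat = S/a1 for D, theta-hat = mean pairwise differences
for Fs). The mismatch distribution is fitted to the stepwise-expansion
expectation by SSD minimization (coarse grid + Nelder-Mead), with parametric
bootstrap p-values for SSD and Harpending's raggedness, and the scaled
expansion time tau is converted to years via t = tau / (2 u), u = mu * k * g.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from ._coalescent import (
    drop_mutations,
    mismatch_histogram_sim,
    sim_genealogy,
    summarize,
)
from .distances import DistanceMatrix, distance_matrix, encode_alignment, _pair_counts
from .errors import EstimationError, InputError
from .haplotypes import retained_columns
from .io import Alignment, site_summary

log = logging.getLogger("phylopop.demography")


# ---------------------------------------------------------------------------
# Neutrality tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeutralityStats:
    """Tajima's D and/or Fu's Fs with simulation p-values."""

    n: int
    s: int
    theta_pi: float
    d: float | None = None
    d_p: float | None = None
    fs: float | None = None
    fs_p: float | None = None
    n_sim: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "S": self.s,
            "theta_pi": self.theta_pi,
            "tajimas_D": self.d,
            "tajimas_D_p": self.d_p,
            "fus_Fs": self.fs,
            "fus_Fs_p": self.fs_p,
            "n_simulations": self.n_sim,
        }


def tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _d_from_summaries(n: int, s: int, pi: float) -> float:
    c = tajima_constants(n)
    denom = math.sqrt(c["e1"] * s + c["e2"] * s * (s - 1))
    if denom == 0:
        raise EstimationError("Tajima's D denominator is zero")
    return (pi - s / c["a1"]) / denom


def _mean_pairwise_raw(aln: Alignment) -> float:
    codes = encode_alignment(aln)
    total = 0
    n_pairs = 0
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            ts, tv, ns = _pair_counts(codes[i], codes[j])
            total += ts + tv
            n_pairs += 1
    return total / n_pairs


def tajimas_d(
    aln: Alignment, n_sim: int = 10000, seed: int | None = None
) -> NeutralityStats:
    """Tajima's D with a two-tailed coalescent-simulation p-value."""
    if aln.n < 4:
        raise EstimationError("Tajima's D needs n >= 4 sequences")
    s = site_summary(aln).segregating
    if s < 1:
        raise EstimationError("Tajima's D undefined for S = 0")
    pi = _mean_pairwise_raw(aln)
    d_obs = _d_from_summaries(aln.n, s, pi)
    theta = s / tajima_constants(aln.n)["a1"]
    rng = np.random.default_rng(seed)
    b = 0
    m = 0
    for _ in range(n_sim):
        tree = sim_genealogy(aln.n, rng, theta1=theta)
        summ = summarize(tree, drop_mutations(tree, rng))
        if summ.s < 1:
            continue
        m += 1
        if abs(_d_from_summaries(aln.n, summ.s, summ.mean_pairwise)) >= abs(d_obs):
            b += 1
    p = (b + 1) / (m + 1) if m else math.nan
    return NeutralityStats(
        n=aln.n, s=s, theta_pi=pi, d=d_obs, d_p=p, n_sim=n_sim
    )


def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = [1]  # n = 0
    for m in range(n):
        new = [0] * (len(row) + 1)
        for k, v in enumerate(row):
            new[k] += m * v
            new[k + 1] += v
        row = new
    return np.array(
        [math.log(v) if v > 0 else -math.inf for v in row], dtype=float
    )


def ewens_k_tail(n: int, k_obs: int, theta: float) -> float:
    """P(K >= k_obs) for a sample of n under the Ewens sampling formula."""
    if theta <= 0:
        raise EstimationError("Ewens tail needs theta > 0")
    logs = _log_stirling_row(n)
    k = np.arange(n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    logp = logs + k * math.log(theta) - log_rising
    logp[0] = -math.inf  # K = 0 impossible
    w = np.exp(logp - logp.max())
    w /= w.sum()
    return float(w[k_obs:].sum())


def _fs_from(n: int, k_obs: int, theta: float) -> float:
    sp = ewens_k_tail(n, k_obs, theta)
    if sp <= 0.0:
        return math.inf
    if sp >= 1.0:
        return -math.inf
    return math.log(sp / (1.0 - sp))


def count_alleles(aln: Alignment) -> int:
    """Distinct sequences after complete deletion of ambiguous columns."""
    cols = retained_columns(aln)
    if not cols:
        raise EstimationError("no unambiguous columns retained")
    return len({"".join(seq[c] for c in cols) for seq in aln.seqs})


def fus_fs(
    aln: Alignment, n_sim: int = 10000, seed: int | None = None
) -> NeutralityStats:
    """Fu's Fs = ln(S'/(1-S')), S' = P(K >= k_obs | theta = theta_pi).

    The p-value is the coalescent-simulation fraction with Fs <= observed
    (Fs is negative under expansion, so small values are extreme).
    """
    if aln.n < 3:
        raise EstimationError("Fu's Fs needs n >= 3 sequences")
    s = site_summary(aln).segregating
    if s < 1:
        raise EstimationError("Fu's Fs undefined for S = 0")
    theta = _mean_pairwise_raw(aln)
    k_obs = count_alleles(aln)
    fs_obs = _fs_from(aln.n, k_obs, theta)
    rng = np.random.default_rng(seed)
    b = 0
    m = 0
    for _ in range(n_sim):
        tree = sim_genealogy(aln.n, rng, theta1=theta)
        summ = summarize(tree, drop_mutations(tree, rng))
        if summ.mean_pairwise <= 0:
            continue
        m += 1
        fs_sim = _fs_from(aln.n, summ.n_alleles, summ.mean_pairwise)
        if fs_sim <= fs_obs:
            b += 1
    p = (b + 1) / (m + 1) if m else math.nan
    return NeutralityStats(
        n=aln.n, s=s, theta_pi=theta, fs=fs_obs, fs_p=p, n_sim=n_sim
    )


def neutrality_tests(
    aln: Alignment, n_sim: int = 10000, seed: int | None = None
) -> NeutralityStats:
    """Both statistics on one alignment (shared observed summaries)."""
    d_part = tajimas_d(aln, n_sim=n_sim, seed=seed)
    fs_part = fus_fs(aln, n_sim=n_sim, seed=None if seed is None else seed + 1)
    return NeutralityStats(
        n=d_part.n,
        s=d_part.s,
        theta_pi=d_part.theta_pi,
        d=d_part.d,
        d_p=d_part.d_p,
        fs=fs_part.fs,
        fs_p=fs_part.fs_p,
        n_sim=n_sim,
    )


# ---------------------------------------------------------------------------
# Mismatch distribution
# ---------------------------------------------------------------------------


def mismatch_observed(data: Alignment | DistanceMatrix) -> np.ndarray:
    """Histogram of raw pairwise difference counts over unordered pairs."""
    if isinstance(data, Alignment):
        dm = distance_matrix(data, metric="raw")
    else:
        dm = data
        if dm.metric != "raw":
            raise InputError("mismatch histogram needs a raw-difference matrix")
    iu = np.triu_indices(dm.n, k=1)
    vals = dm.matrix[iu].astype(int)
    return np.bincount(vals)


def _equilibrium_pmf(theta: float, j_max: int) -> np.ndarray:
    """Geometric mismatch distribution at mutation-drift equilibrium."""
    j = np.arange(j_max + 1)
    if theta <= 0:
        out = np.zeros(j_max + 1)
        out[0] = 1.0
        return out
    # log-space to avoid overflow for large theta / j
    return np.exp(j * math.log(theta) - (j + 1) * math.log(theta + 1.0))


def sudden_expansion_pmf(
    tau: float, theta0: float, theta1: float, j_max: int
) -> np.ndarray:
    """Expected mismatch frequencies under a stepwise expansion.

    Pairs coalescing since the expansion (size theta1) contribute the
    equilibrium term damped by a regularized incomplete gamma; earlier pairs
    carry Poisson(tau) new mutations on top of the theta0 equilibrium.
    Sums to 1 over j = 0..infinity.
    """
    if theta1 <= 0 or tau < 0 or theta0 < 0:
        raise InputError("need theta1 > 0, tau >= 0, theta0 >= 0")
    j = np.arange(j_max + 1)
    a = (theta1 + 1.0) / theta1
    recent = _equilibrium_pmf(theta1, j_max) * special.gammainc(j + 1, a * tau)
    pois = stats.poisson.pmf(j, tau)
    ancient = math.exp(-tau / theta1) * np.convolve(
        pois, _equilibrium_pmf(theta0, j_max)
    )[: j_max + 1]
    return recent + ancient


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness r with an appended zero class."""
    x = np.append(np.asarray(freqs, dtype=float), 0.0)
    return float(np.sum(np.diff(x) ** 2))


@dataclass(frozen=True)
class MismatchFit:
    """Observed mismatch histogram with fitted sudden-expansion parameters."""

    histogram: tuple[int, ...]
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    p_ssd: float | None
    p_raggedness: float | None
    n_boot: int
    boot_tau: tuple[float, ...] = ()
    converged: bool = True

    def tau_ci(self, level: float = 0.95) -> tuple[float, float]:
        if not self.boot_tau:
            raise EstimationError("no bootstrap replicates stored")
        lo = (1.0 - level) / 2.0 * 100.0
        arr = np.asarray(self.boot_tau)
        return (
            float(np.percentile(arr, lo)),
            float(np.percentile(arr, 100.0 - lo)),
        )

    def to_dict(self) -> dict:
        return {
            "histogram": list(self.histogram),
            "tau": self.tau,
            "theta0": self.theta0,
            "theta1": self.theta1,
            "SSD": self.ssd,
            "raggedness": self.raggedness,
            "p_SSD": self.p_ssd,
            "p_raggedness": self.p_raggedness,
            "n_bootstrap": self.n_boot,
            "converged": self.converged,
        }


def _fit_core(freqs: np.ndarray) -> tuple[float, float, float, float, bool]:
    """Grid + Nelder-Mead SSD minimization; returns (tau, th0, th1, ssd, ok)."""
    j_max = len(freqs) - 1
    j = np.arange(j_max + 1)
    mean_d = float((j * freqs).sum())

    def ssd_of(params: np.ndarray) -> float:
        tau, th0, dth = np.abs(params)
        th1 = th0 + dth
        if th1 <= 1e-9:
            return 1e9
        model = sudden_expansion_pmf(tau, th0, th1, j_max)
        return float(np.sum((freqs - model) ** 2))

    best = None
    taus = np.unique(np.clip(mean_d * np.array([0.25, 0.5, 0.75, 1.0, 1.25]),
                             1e-3, None))
    for tau in taus:
        for th0 in (0.01, 0.5, 2.0):
            for th1 in (1.0, 10.0, 100.0, 1000.0):
                if th1 <= th0:
                    continue
                x = np.array([tau, th0, th1 - th0])
                v = ssd_of(x)
                if best is None or v < best[1]:
                    best = (x, v)
    res = optimize.minimize(
        ssd_of, best[0], method="Nelder-Mead",
        options={"maxiter": 400, "xatol": 1e-5, "fatol": 1e-11},
    )
    x = np.abs(res.x)
    if res.fun <= best[1]:
        tau, th0, dth = x
        ssd = float(res.fun)
    else:  # keep grid optimum if the simplex wandered off
        tau, th0, dth = np.abs(best[0])
        ssd = float(best[1])
    return float(tau), float(th0), float(th0 + dth), ssd, bool(res.success)


def fit_sudden_expansion(
    hist: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    n_sequences: int | None = None,
) -> MismatchFit:
    """Fit (tau, theta0, theta1) to an observed mismatch histogram.

    p(SSD) and p(raggedness) are parametric-bootstrap fractions of replicates
    (coalescent data re-simulated under the fitted model and refitted) with a
    statistic >= the observed one. ``n_sequences`` defaults to the value
    implied by the number of pairs in the histogram.
    """
    hist = np.asarray(hist)
    npairs = int(hist.sum())
    if npairs < 1:
        raise InputError("empty mismatch histogram")
    freqs = hist / npairs
    tau, th0, th1, ssd, converged = _fit_core(freqs)
    r_obs = raggedness(freqs)
    if not converged:
        log.warning("mismatch optimizer did not fully converge")

    if n_sequences is None:
        n_sequences = int(round((1 + math.sqrt(1 + 8 * npairs)) / 2))
    boot_tau: list[float] = []
    b_ssd = 0
    b_rag = 0
    m = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        h = mismatch_histogram_sim(n_sequences, tau, th0, th1, rng)
        f = h / h.sum()
        try:
            t_b, _, _, ssd_b, _ = _fit_core(f)
        except Exception:  # pragma: no cover - degenerate replicate
            continue
        m += 1
        boot_tau.append(t_b)
        if ssd_b >= ssd:
            b_ssd += 1
        if raggedness(f) >= r_obs:
            b_rag += 1
    p_ssd = (b_ssd + 1) / (m + 1) if m else None
    p_rag = (b_rag + 1) / (m + 1) if m else None
    return MismatchFit(
        histogram=tuple(int(v) for v in hist),
        tau=tau,
        theta0=th0,
        theta1=th1,
        ssd=ssd,
        raggedness=r_obs,
        p_ssd=p_ssd,
        p_raggedness=p_rag,
        n_boot=n_boot,
        boot_tau=tuple(boot_tau),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Expansion-time conversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpansionTime:
    """t = tau / (2 u) with u = mu * k * g."""

    tau: float
    mu: float
    k: int
    g: float
    u: float
    t_generations: float
    t_years: float
    t_mya: float

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "mu_per_site_per_year": self.mu,
            "k_sites": self.k,
            "generation_time_years": self.g,
            "u_per_sequence_per_generation": self.u,
            "t_generations": self.t_generations,
            "t_years": self.t_years,
            "t_mya": self.t_mya,
        }


def expansion_time(tau: float, mu: float, k: int, g: float) -> ExpansionTime:
    """Convert a fitted tau to absolute time since expansion."""
    if tau < 0:
        raise InputError("tau must be >= 0")
    if mu <= 0 or k <= 0 or g <= 0:
        raise InputError("mu, k and g must all be positive")
    u = mu * k * g
    t_gen = tau / (2.0 * u)
    t_years = t_gen * g
    return ExpansionTime(
        tau=tau,
        mu=mu,
        k=k,
        g=g,
        u=u,
        t_generations=t_gen,
        t_years=t_years,
        t_mya=t_years / 1e6,
    )
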