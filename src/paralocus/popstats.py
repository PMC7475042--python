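"""Population-level statistics for allele-count distributions.

Observed per-individual allele counts (or exome allele frequencies) are
compared against the distribution expected if the NOTCH2NLA/NOTCH2NLB Exon1
variants segregate like two independent biallelic loci (an AABB x AABB cross:
0..4 variant alleles with probabilities 1:4:6:4:1 / 16). Group comparisons use
the Kruskal-Wallis rank test with Dunn's post hoc z tests, distribution
comparisons the two-sample Kolmogorov-Smirnov test, and all p values are
Holm-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

POLYGENIC_PROBS = (1 / 16, 4 / 16, 6 / 16, 4 / 16, 1 / 16)


@dataclass(frozen=True)
class ExpectedDistributionSpec:
    """A categorical support jittered with Gaussian noise, at sample size n."""

    support: tuple[float, ...]
    probabilities: tuple[float, ...]
    n: int
    jitter_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(self.support) != len(p):
            raise ValueError("support and probabilities differ in length")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


def simons_expected_spec(n: int = 2790, jitter_sd: float = 0.34, seed: int = 0) -> ExpectedDistributionSpec:
    """The allele-count scale expectation: 0..4 alleles at 1:4:6:4:1."""
    return ExpectedDistributionSpec((0, 1, 2, 3, 4), POLYGENIC_PROBS, n, jitter_sd, seed)


def expected_polygenic_sample(spec: ExpectedDistributionSpec) -> np.ndarray:
    """Draw a category for each individual, then add Gaussian jitter.

    Equivalent to the Gaussian-mixture formulation (normal draws around
    category means) and exactly reproducible under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    cats = rng.choice(np.asarray(spec.support, dtype=float), size=spec.n,
                      p=np.asarray(spec.probabilities, dtype=float))
    return cats + rng.normal(0.0, spec.jitter_sd, size=spec.n)


def expected_ukb_sample(
    n: int = 50_000,
    support: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4),
    jitter_sd: float = 0.034,
    loss_rate_nlc: float = 0.0,
    loss_rate_nlr: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Expected exome-cohort variant *frequencies* under the same cross.

    The support is the allele-count support divided by the modal ten-allele
    total. Losses of NOTCH2NLC or NOTCH2NLR (at the given population rates)
    shrink an individual's allele total from 10 to 10 - (number of lost
    alleles), which rescales that individual's frequency before jitter is
    added: support value k/10 becomes k/(10 - L). Rates are estimated from a
    genotyped cohort, not assumed.
    """
    for r in (loss_rate_nlc, loss_rate_nlr):
        if not 0.0 <= r <= 1.0:
            raise ValueError("loss rates must lie in [0, 1]")
    support = np.asarray(support, dtype=float)
    rng = np.random.default_rng(seed)
    k = rng.choice(np.arange(len(support)), size=n, p=np.asarray(POLYGENIC_PROBS))
    losses = (rng.random(n) < loss_rate_nlc).astype(int) + (
        rng.random(n) < loss_rate_nlr
    ).astype(int)
    base_total = 10.0
    values = support[k] * base_total / (base_total - losses)
    return values + rng.normal(0.0, jitter_sd, size=n)


def expected_ukb_mean(
    loss_rate_nlc: float, loss_rate_nlr: float,
    support: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4),
) -> float:
    """Closed-form mean of :func:`expected_ukb_sample` (used as an oracle)."""
    support = np.asarray(support, dtype=float)
    mean_support = float(np.dot(support, POLYGENIC_PROBS))
    pc, pr = loss_rate_nlc, loss_rate_nlr
    p_l = {0: (1 - pc) * (1 - pr), 1: pc * (1 - pr) + pr * (1 - pc), 2: pc * pr}
    scale = sum(p * 10.0 / (10.0 - l) for l, p in p_l.items())
    return mean_support * scale


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    pairwise: tuple[tuple[str, str, float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value out of [0, 1]")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction (chi-square p, k-1 df).

    All-tied data (every value identical) is degenerate — the tie correction
    divides by zero — and is defined here as H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0)
    stat, p = sps.kruskal(*arrays)
    return TestResult(float(stat), float(p))


def dunn_test(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjustment: str = "holm",
) -> TestResult:
    """Dunn's post hoc rank comparison for all group pairs.

    z_ij = (mean rank_i - mean rank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p values,
    Holm-adjusted by default. The overall statistic reported is the
    Kruskal-Wallis H on the same groups.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    if adjustment not in {"holm", "none"}:
        raise ValueError("adjustment must be 'holm' or 'none'")

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    mean_ranks = []
    offset = 0
    for size in sizes:
        mean_ranks.append(float(ranks[offset:offset + size].mean()))
        offset += size

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = []
    raw_ps = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
            p = float(2.0 * sps.norm.sf(abs(z)))
            pairs.append((labels[i], labels[j], float(z)))
            raw_ps.append(p)
    adj = holm_adjust(raw_ps) if adjustment == "holm" else list(raw_ps)
    pairwise = tuple(
        (a, b, z, raw, ap) for (a, b, z), raw, ap in zip(pairs, raw_ps, adj)
    )
    overall = kruskal_wallis(groups)
    return TestResult(overall.statistic, overall.p_value, pairwise)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm's step-down adjustment: (m - i) * p_(i) with a running maximum,
    capped at 1; order-preserving and never below the raw p."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()
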