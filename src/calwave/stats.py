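"""Sample summaries and assumption-light two-sample comparisons.

Used to contrast conditions (e.g. intact vs excised meristems): per-sample
mean ± relative standard error, and distribution equality assessed with a
two-sided Kolmogorov-Smirnov test plus a permutation test on the mean
difference.  The permutation test enumerates all label assignments exactly
when feasible and falls back to seeded Monte-Carlo with the add-one
correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import ks_2samp

EXACT_ENUMERATION_LIMIT = 100_000


@dataclass
class SampleSummary:
    n: int
    mean: float
    sd: float | None
    se: float | None
    rel_se: float | None

    def to_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean, "sd": self.sd,
                "se": self.se, "rel_se": self.rel_se}


@dataclass
class MethodResult:
    name: str
    statistic: float
    p_value: float


@dataclass
class ComparisonResult:
    methods: list[MethodResult]
    smallest_p: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {
            "methods": [
                {"name": m.name, "statistic": m.statistic, "p_value": m.p_value}
                for m in self.methods
            ],
            "smallest_p": self.smallest_p,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def summarize_sample(values) -> SampleSummary:
    """Mean, SD (n-1 denominator), SE and relative SE (SE/mean)."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(x.mean())
    if x.size < 2:
        return SampleSummary(1, mean, None, None, None)
    sd = float(x.std(ddof=1))
    se = sd / np.sqrt(x.size)
    rel = se / mean if mean != 0 else None
    return SampleSummary(int(x.size), mean, sd, float(se), rel)


def _permutation_p(
    a: np.ndarray, b: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Two-sided permutation test on the difference of means.

    Exhaustive over all C(n_a+n_b, n_a) assignments when that count is
    small; otherwise Monte-Carlo with p = (1 + #extreme) / (1 + N).
    Returns (observed |difference|, p).
    """
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    obs = abs(a.mean() - b.mean())
    total = pooled.sum()
    eps = 1e-12 * (abs(obs) + pooled.std() + 1)

    if comb(n, na) <= EXACT_ENUMERATION_LIMIT:
        count = 0
        n_total = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            diff = abs(sa / na - (total - sa) / (n - na))
            count += diff >= obs - eps
            n_total += 1
        return obs, count / n_total
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = abs(perm[:na].mean() - perm[na:].mean())
        count += diff >= obs - eps
    return obs, (1 + count) / (1 + n_permutations)


def compare_distributions(
    sample_a,
    sample_b,
    methods: tuple[str, ...] = ("ks", "permutation"),
    n_permutations: int = 9999,
    seed: int = 0,
) -> ComparisonResult:
    """Two-sample distribution comparison; reports each p and the smallest."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two values")
    if not methods:
        raise ValueError("at least one comparison method is required")
    rng = np.random.default_rng(seed)
    results: list[MethodResult] = []
    for m in methods:
        if m == "ks":
            r = ks_2samp(a, b, alternative="two-sided")
            results.append(MethodResult("ks", float(r.statistic), float(r.pvalue)))
        elif m == "permutation":
            stat, p = _permutation_p(a, b, n_permutations, rng)
            results.append(MethodResult("permutation_mean", float(stat), float(p)))
        else:
            raise ValueError(f"unknown method {m!r}")
    smallest = min(r.p_value for r in results)
    return ComparisonResult(results, smallest, int(a.size), int(b.size))


def duration_ratio(durations_a, durations_b) -> SampleSummary:
    """Per-recording ratio of paired event durations, then summarized.

    Used to express how much longer spontaneous oscillation events last than
    mechanically triggered waves recorded in the same sample.
    """
    a = np.asarray(list(durations_a), dtype=float)
    b = np.asarray(list(durations_b), dtype=float)
    if a.size != b.size:
        raise ValueError("ratio requires paired per-recording values")
    if np.any(b == 0):
        raise ValueError("denominator durations must be nonzero")
    return summarize_sample(a / b)
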