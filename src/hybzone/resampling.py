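"""Randomization tests for hybrid-proportion differences, Holm correction,
and the Evanno delta-K rule for choosing the number of clusters.

The proportion test compares the fraction of flagged hybrids between two
focal regions.  Individuals are randomized between the pair without
replacement, which makes the null count of hybrids assigned to group 1
hypergeometric; the null distribution is sampled directly from that law,
which is distributionally identical to explicitly permuting the pooled
indicator vector and far faster.  Reported p-values use the add-one
convention (b + 1) / (n + 1), so they are never exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RandomizationResult:
    """Outcome of one pairwise hybrid-proportion randomization test."""

    pair: tuple[str, str]
    observed_stat: float
    n_reps: int
    p_value: float
    sidedness: str
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class LnPTable:
    """Replicate log-probabilities of the data across a contiguous K grid."""

    k_values: np.ndarray
    lnp: np.ndarray  # shape (n_K, n_reps)

    def __post_init__(self):
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.lnp = np.asarray(self.lnp, dtype=float)
        if self.lnp.shape[0] != self.k_values.size:
            raise ValueError("one row of replicates per K required")
        if self.lnp.shape[1] < 2:
            raise ValueError("at least 2 replicates per K (SD undefined)")
        if not np.all(np.diff(self.k_values) == 1):
            raise ValueError("K grid must be contiguous")
        if self.k_values.size < 3:
            raise ValueError("delta-K needs at least 3 consecutive K values")


def randomize_proportion_test(
    flags1,
    flags2,
    n_reps: int = 100_000,
    sidedness: str = "two_sided",
    seed=None,
    pair: tuple[str, str] = ("group1", "group2"),
) -> RandomizationResult:
    """Randomization test for a difference in hybrid proportions.

    observed = mean(flags1) - mean(flags2).  Null replicates reassign the
    pooled hybrid flags to the two groups without replacement;
    p = (1 + #{null meeting the criterion}) / (n_reps + 1) where the
    criterion is |null| >= |observed| (two_sided) or null >= observed
    (one_sided_greater).
    """
    f1 = np.asarray(flags1, dtype=bool)
    f2 = np.asarray(flags2, dtype=bool)
    if f1.size == 0 or f2.size == 0:
        raise ValueError("both groups must be nonempty")
    if sidedness not in ("two_sided", "one_sided_greater"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    n1, n2 = f1.size, f2.size
    k_total = int(f1.sum() + f2.sum())
    observed = f1.mean() - f2.mean()
    rng = np.random.default_rng(seed)
    x1 = rng.hypergeometric(k_total, n1 + n2 - k_total, n1, size=n_reps)
    null = x1 / n1 - (k_total - x1) / n2
    if sidedness == "two_sided":
        hits = np.abs(null) >= abs(observed) - 1e-12
    else:
        hits = null >= observed - 1e-12
    p = (1 + int(hits.sum())) / (n_reps + 1)
    return RandomizationResult(pair, float(observed), n_reps, p, sidedness, seed)


def pairwise_proportion_tests(
    flags_by_region: dict[str, np.ndarray],
    n_reps: int = 100_000,
    sidedness: str = "two_sided",
    seed=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise randomization tests with Holm-corrected significance."""
    regions = list(flags_by_region)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(regions) * (len(regions) - 1) // 2)
    rows, k = [], 0
    for i, r1 in enumerate(regions):
        for r2 in regions[i + 1:]:
            res = randomize_proportion_test(
                flags_by_region[r1],
                flags_by_region[r2],
                n_reps=n_reps,
                sidedness=sidedness,
                seed=child_seeds[k],
                pair=(r1, r2),
            )
            rows.append(
                {
                    "region1": r1,
                    "prop1": float(np.mean(flags_by_region[r1])),
                    "n1": len(flags_by_region[r1]),
                    "region2": r2,
                    "prop2": float(np.mean(flags_by_region[r2])),
                    "n2": len(flags_by_region[r2]),
                    "observed_diff": res.observed_stat,
                    "p_value": res.p_value,
                }
            )
            k += 1
    df = pd.DataFrame(rows)
    if not df.empty:
        df["significant"] = holm_sequential_bonferroni(
            df["p_value"].to_numpy(), alpha=alpha
        )
    return df


def holm_sequential_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Sequential Bonferroni (Holm) significance flags, in input order.

    The i-th smallest p-value is significant iff p_(i) <= alpha / (m - i + 1)
    and every smaller p-value was significant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags


def parse_reported_p(text) -> tuple[float, bool]:
    """Parse a table-style p entry; ``"<.00001"`` becomes (1e-6, censored)."""
    s = str(text).strip().rstrip("*")
    if s.startswith("<"):
        return 1e-6, True
    return float(s), False


def evanno_delta_k(table: LnPTable) -> pd.DataFrame:
    """Evanno second-difference statistic per interior K.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K), with
    the sample (n-1) SD over replicates.  A zero replicate SD yields an
    infinite delta-K with a warning.
    """
    means = table.lnp.mean(axis=1)
    sds = table.lnp.std(axis=1, ddof=1)
    ks = table.k_values[1:-1]
    second = np.abs(means[2:] - 2 * means[1:-1] + means[:-2])
    sd_int = sds[1:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        dk = np.where(sd_int > 0, second / np.where(sd_int > 0, sd_int, 1.0), np.inf)
    dk = np.where((sd_int == 0) & (second == 0), 0.0, dk)
    if np.any((sd_int == 0) & (second > 0)):
        warnings.warn("zero replicate SD: delta-K flagged infinite at some K")
    return pd.DataFrame(
        {"K": ks, "delta_k": dk, "mean_lnp": means[1:-1], "sd_lnp": sd_int}
    )


def best_k(table: LnPTable) -> int:
    """K maximizing delta-K (ties broken toward the smaller K)."""
    dk = evanno_delta_k(table)
    return int(dk.loc[dk["delta_k"].idxmax(), "K"])
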