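"""Maternal-parent asymmetry tests for F1 hybrids.

In an anuran contact zone the maternal species of an F1 hybrid is read off
the maternally inherited mitochondrion; here that assignment is consumed as
a per-individual label ("A", "B", or "unknown").  If females of the two
species hybridize at equal rates, the maternal species among F1s is
Binomial(n, 1/2); the exact two-sided binomial test against that null
detects asymmetric hybridization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

logger = logging.getLogger(__name__)

#: Minimum F1 count for a region's test to be highlighted in reports.
REPORT_MIN_F1 = 15


@dataclass
class MaternalTally:
    """Maternal-species counts among F1s in one region, with the test p."""

    region: str
    n_f1: int
    k_a: int
    k_b: int
    p_value: float

    def __post_init__(self):
        if self.k_a + self.k_b != self.n_f1:
            raise ValueError("k_a + k_b must equal n_f1")


def exact_binomial_asymmetry(k_a: int, k_b: int) -> float:
    """Two-sided exact binomial p-value at null proportion 1/2.

    Tail doubling: p = min(1, 2 * min(P(X <= min), P(X >= max))) with
    X ~ Binomial(k_a + k_b, 1/2).  At p0 = 1/2 this coincides with the
    minimum-likelihood summation convention by symmetry.
    """
    if k_a < 0 or k_b < 0:
        raise ValueError("counts must be non-negative")
    n = k_a + k_b
    if n == 0:
        raise ValueError("at least one labelled F1 required")
    lo, hi = min(k_a, k_b), max(k_a, k_b)
    p = 2.0 * min(binom.cdf(lo, n, 0.5), binom.sf(hi - 1, n, 0.5))
    return float(min(1.0, p))


def tally_maternal(
    results_df: pd.DataFrame,
    maternal: pd.Series | None = None,
    include_total: bool = True,
) -> pd.DataFrame:
    """Tally maternal species among F1-flagged individuals, per region.

    Parameters
    ----------
    results_df : DataFrame
        Per-individual hybrid-index results with columns ``individual``,
        ``region`` and ``is_f1`` (e.g. from
        ``HybridIndexEstimator.results_frame``), and optionally a
        ``maternal`` column.
    maternal : Series, optional
        Maternal labels indexed by individual id; overrides the column.

    Returns
    -------
    DataFrame with columns region, n_f1, k_a, k_b, p_value, reportable
    (the n_f1 > 15 reporting filter — all regions are computed regardless),
    plus a pooled ``total`` row.  Individuals with unknown labels are
    excluded with a logged count.
    """
    df = results_df.copy()
    if maternal is not None:
        df["maternal"] = df["individual"].map(maternal).fillna("unknown")
    if "maternal" not in df.columns:
        raise ValueError("maternal labels missing")
    f1 = df[df["is_f1"].astype(bool)]
    n_unknown = int((f1["maternal"] == "unknown").sum())
    if n_unknown:
        logger.info("excluding %d F1s with unknown maternal label", n_unknown)
    f1 = f1[f1["maternal"] != "unknown"]
    if f1.empty:
        logger.warning("no labelled F1 hybrids: empty maternal tally")
    rows = []
    groups = list(f1.dropna(subset=["region"]).groupby("region"))
    if include_total:
        groups.append(("total", f1))
    for region, grp in groups:
        k_a = int((grp["maternal"] == "A").sum())
        k_b = int((grp["maternal"] == "B").sum())
        n = k_a + k_b
        p = exact_binomial_asymmetry(k_a, k_b) if n >= 1 else np.nan
        rows.append(
            {
                "region": region,
                "n_f1": n,
                "k_a": k_a,
                "k_b": k_b,
                "p_value": p,
                "reportable": n > REPORT_MIN_F1,
            }
        )
    return pd.DataFrame(
        rows, columns=["region", "n_f1", "k_a", "k_b", "p_value", "reportable"]
    )
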