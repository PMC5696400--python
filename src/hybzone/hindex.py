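"""Maximum-likelihood hybrid index estimation and hybrid classification.

The hybrid index h of a putative hybrid is the proportion of its genome
derived from parental species A (h = 1: pure A, h = 0: pure B).  Given
reference allele-frequency distributions p_A and p_B estimated from pooled
allopatric samples of each species, each observed allele copy a at locus l
contributes a mixture likelihood

    P(a | h) = h * p_A(l, a) + (1 - h) * p_B(l, a)

and the per-individual log-likelihood is the sum over all non-missing allele
copies.  h is estimated by a grid scan plus bounded refinement, with a 95%
profile-likelihood confidence interval (log-likelihood drop of 1.92, the
chi-square(1) 95% half-deviance), clamped to [0, 1].

Two classification rules are provided:

* boundary rule: individuals with h in [0.25, 0.75] (the hybrid-index range
  bracketing laboratory-bred F1s) are flagged putative F1 hybrids;
* CI rule: individuals whose 95% CI excludes both 0 and 1 are flagged
  hybrids of undetermined class.

:class:`HybridIndexEstimator` follows the scikit-learn estimator protocol
(``fit`` on reference genotypes with species labels, ``predict`` hybrid
indices); module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from sklearn.base import BaseEstimator

from .genotypes import MISSING, GenotypeDataset, LocusDef, ReferencePair

logger = logging.getLogger(__name__)

#: chi-square(1) 95% quantile / 2 — profile-likelihood CI drop.
CI_DROP_95 = 1.92


@dataclass
class AlleleFrequencyTable:
    """Per-locus reference allele frequencies for the two parental species.

    For each locus: the allele universe (sorted ids), frequency vectors
    p_A and p_B over that universe (each summing to 1), and the number of
    allele copies sampled in each reference.  Frequencies carry add-alpha
    smoothing so no allele in the universe has probability 0 in either
    species.
    """

    locus_names: list[str]
    alleles: list[np.ndarray]
    p_a: list[np.ndarray]
    p_b: list[np.ndarray]
    n_a: np.ndarray  # allele-copy counts per locus, species A
    n_b: np.ndarray
    alpha: float = 0.5

    def __post_init__(self):
        for name, pa, pb in zip(self.locus_names, self.p_a, self.p_b):
            for label, p in (("A", pa), ("B", pb)):
                if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"locus {name!r}: species {label} frequencies invalid"
                    )

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def flipped(self) -> "AlleleFrequencyTable":
        """Swap the roles of the two reference species."""
        return AlleleFrequencyTable(
            self.locus_names,
            self.alleles,
            [p.copy() for p in self.p_b],
            [p.copy() for p in self.p_a],
            self.n_b.copy(),
            self.n_a.copy(),
            self.alpha,
        )


@dataclass
class HybridIndexResult:
    """Per-individual hybrid-index estimate with CI and classification flags."""

    individual: str
    h_hat: float
    loglik_max: float
    ci_low: float
    ci_high: float
    n_loci_used: int
    is_f1: bool = False
    is_hybrid_ci: bool = False

    def __post_init__(self):
        if not (self.ci_low - 1e-9 <= self.h_hat <= self.ci_high + 1e-9):
            raise ValueError("CI must bracket the point estimate")
        if self.n_loci_used < 1:
            raise ValueError("at least one typed locus required")


@dataclass
class AdmixtureSummary:
    """Regional admixture proportions under the two classification rules.

    ``prop_advanced`` (undetermined minus F1) approximates the fraction of
    advanced-generation hybrids; it is clipped at 0 with a warning when the
    two rules disagree on more individuals than they agree.
    """

    region: str
    n: int
    prop_f1: float
    prop_undetermined: float
    prop_advanced: float


# ---------------------------------------------------------------------------
# frequency estimation
# ---------------------------------------------------------------------------

def _counts(calls: np.ndarray, universe: np.ndarray) -> tuple[np.ndarray, int]:
    a = calls.ravel()
    a = a[a != MISSING]
    idx = np.searchsorted(universe, a)
    counts = np.bincount(idx, minlength=universe.size).astype(float)
    return counts, a.size


def estimate_frequencies(
    references: ReferencePair,
    alpha: float = 0.5,
    allele_universe: list[np.ndarray] | None = None,
) -> AlleleFrequencyTable:
    """Estimate smoothed reference allele frequencies from pooled samples.

    p = (count + alpha) / (copies + alpha * K) over the union allele set of
    both references (optionally extended by ``allele_universe``, e.g. alleles
    seen in the individuals to be scored), so no observed allele has
    probability 0 in either species.  alpha = 0 reproduces raw proportions.
    Loci untyped in a reference are dropped with a warning.
    """
    ds = references.dataset
    names, alleles, p_a, p_b, n_a, n_b = [], [], [], [], [], []
    for j, locus in enumerate(ds.loci):
        uni = np.unique(
            np.concatenate(
                [
                    ds.calls[references.idx_a, j, :].ravel(),
                    ds.calls[references.idx_b, j, :].ravel(),
                    np.asarray(
                        allele_universe[j] if allele_universe is not None else [],
                        dtype=int,
                    ).ravel(),
                ]
            )
        )
        uni = uni[uni != MISSING]
        ca, na = _counts(ds.calls[references.idx_a, j, :], uni)
        cb, nb = _counts(ds.calls[references.idx_b, j, :], uni)
        if na == 0 or nb == 0 or uni.size == 0:
            logger.warning(
                "locus %s untyped in a reference pool: dropped", locus.name
            )
            continue
        K = uni.size
        pa = (ca + alpha) / (na + alpha * K)
        pb = (cb + alpha) / (nb + alpha * K)
        names.append(locus.name)
        alleles.append(uni)
        p_a.append(pa)
        p_b.append(pb)
        n_a.append(na)
        n_b.append(nb)
    if not names:
        raise ValueError("no locus typed in both references")
    return AlleleFrequencyTable(
        names, alleles, p_a, p_b, np.array(n_a), np.array(n_b), alpha
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _genotype_mixture_terms(
    genotype: np.ndarray, freqs: AlleleFrequencyTable, locus_indices=None
) -> tuple[np.ndarray, np.ndarray]:
    """(p_A, p_B) per non-missing allele copy of one genotype (L, 2)."""
    pa_list, pb_list = [], []
    rng_ = range(freqs.n_loci) if locus_indices is None else locus_indices
    for j in rng_:
        uni, pa, pb = freqs.alleles[j], freqs.p_a[j], freqs.p_b[j]
        for a in genotype[j]:
            if a == MISSING:
                continue
            k = np.searchsorted(uni, a)
            if k >= uni.size or uni[k] != a:
                # allele unseen in the fitted universe: smoothing pseudo-count
                if freqs.alpha <= 0:
                    raise AssertionError(
                        f"allele {a} at locus {freqs.locus_names[j]} has zero "
                        f"probability in both references (alpha=0)"
                    )
                K = uni.size + 1
                pa_list.append(freqs.alpha / (freqs.n_a[j] + freqs.alpha * K))
                pb_list.append(freqs.alpha / (freqs.n_b[j] + freqs.alpha * K))
            else:
                pa_list.append(pa[k])
                pb_list.append(pb[k])
    return np.asarray(pa_list), np.asarray(pb_list)


def loglik_h(genotype: np.ndarray, freqs: AlleleFrequencyTable, h) -> np.ndarray:
    """Log-likelihood of hybrid index h for one genotype (L, 2) array.

    Vectorized over h; returns a scalar for scalar h.
    """
    h_arr = np.atleast_1d(np.asarray(h, dtype=float))
    if np.any((h_arr < 0) | (h_arr > 1)):
        raise ValueError("h must lie in [0, 1]")
    pa, pb = _genotype_mixture_terms(genotype, freqs)
    mix = np.outer(h_arr, pa) + np.outer(1.0 - h_arr, pb)
    if np.any(mix <= 0):
        raise AssertionError(
            "zero mixture probability for an observed allele; use alpha > 0"
        )
    out = np.log(mix).sum(axis=1)
    return out[0] if np.isscalar(h) or np.ndim(h) == 0 else out


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class HybridIndexEstimator(BaseEstimator):
    """Scikit-learn style maximum-likelihood hybrid index estimator.

    Parameters
    ----------
    alpha : float, default 0.5
        Add-alpha (Jeffreys-like) smoothing pseudo-count for reference
        allele frequencies.  alpha = 0 uses raw proportions (and raises if
        a scored individual carries an allele absent from both references).
    f1_bounds : pair of float, default (0.25, 0.75)
        Inclusive hybrid-index interval for the F1 boundary rule.
    ci_drop : float, default 1.92
        Profile log-likelihood drop defining the confidence interval.
    grid_step : float, default 1e-3
        Initial grid resolution for locating the MLE.
    tol : float, default 1e-6
        Refinement tolerance for the MLE and CI endpoints.
    ci_tol : float, default 1e-9
        Slack used by the CI classification rule when testing whether an
        interval reaches 0 or 1.

    Attributes
    ----------
    freqs_ : AlleleFrequencyTable
        Smoothed reference allele frequencies fitted from the references.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        f1_bounds: tuple[float, float] = (0.25, 0.75),
        ci_drop: float = CI_DROP_95,
        grid_step: float = 1e-3,
        tol: float = 1e-6,
        ci_tol: float = 1e-9,
    ):
        self.alpha = alpha
        self.f1_bounds = f1_bounds
        self.ci_drop = ci_drop
        self.grid_step = grid_step
        self.tol = tol
        self.ci_tol = ci_tol

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None, allele_universe=None):
        """Fit reference allele frequencies.

        ``X`` may be a :class:`ReferencePair`, or an (n, L, 2) call array
        with ``y`` an array of species labels ("A"/"B") — the scikit-learn
        calling convention.
        """
        lo, hi = self.f1_bounds
        if not (0 <= lo < hi <= 1):
            raise ValueError("f1_bounds must satisfy 0 <= low < high <= 1")
        if isinstance(X, ReferencePair):
            pair = X
        else:
            X = np.asarray(X)
            y = np.asarray(y)
            if X.ndim != 3 or X.shape[2] != 2:
                raise ValueError("X must be an (n, L, 2) diploid call array")
            ds = GenotypeDataset(
                individual_ids=[f"ref{i}" for i in range(X.shape[0])],
                localities=["ref"] * X.shape[0],
                loci=[LocusDef(f"L{j + 1}") for j in range(X.shape[1])],
                calls=X,
            )
            pair = ReferencePair(
                ds, np.flatnonzero(y == "A"), np.flatnonzero(y == "B")
            )
        self.freqs_ = estimate_frequencies(
            pair, alpha=self.alpha, allele_universe=allele_universe
        )
        return self

    # -- per-individual machinery ---------------------------------------
    def _estimate_one(self, individual: str, genotype: np.ndarray) -> HybridIndexResult:
        pa, pb = _genotype_mixture_terms(genotype, self.freqs_)
        if pa.size == 0:
            raise ValueError(f"individual {individual!r}: all loci missing")
        n_loci_used = int(
            np.sum(np.any(genotype[: len(self.freqs_.locus_names)] != MISSING, axis=1))
        )

        # floor keeps boundary evaluations finite when unsmoothed diagnostic
        # frequencies make P(allele | h) exactly 0 at h = 0 or 1
        tiny = 1e-300

        def negll(h):
            return -np.sum(np.log(np.maximum(h * pa + (1.0 - h) * pb, tiny)))

        grid = np.arange(0.0, 1.0 + self.grid_step / 2, self.grid_step)
        ll_grid = np.log(
            np.maximum(np.outer(grid, pa) + np.outer(1 - grid, pb), tiny)
        ).sum(axis=1)
        k = int(np.argmax(ll_grid))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        if hi > lo:
            res = minimize_scalar(
                negll, bounds=(lo, hi), method="bounded",
                options={"xatol": self.tol / 10},
            )
            h_hat, ll_max = float(res.x), -float(res.fun)
            # the bounded optimizer never quite reaches the boundary
            for edge in (0.0, 1.0):
                if -negll(edge) >= ll_max:
                    h_hat, ll_max = edge, -negll(edge)
        else:
            h_hat, ll_max = float(grid[k]), float(ll_grid[k])
        thr = ll_max - self.ci_drop

        def profile(h):
            return -negll(h) - thr

        ci_low = 0.0 if profile(0.0) >= 0 else brentq(
            profile, 0.0, h_hat, xtol=self.tol
        )
        ci_high = 1.0 if profile(1.0) >= 0 else brentq(
            profile, h_hat, 1.0, xtol=self.tol
        )
        res = HybridIndexResult(
            individual=individual,
            h_hat=min(max(h_hat, 0.0), 1.0),
            loglik_max=ll_max,
            ci_low=min(ci_low, h_hat),
            ci_high=max(ci_high, h_hat),
            n_loci_used=max(n_loci_used, 1),
        )
        res.is_f1 = classify_f1(res, self.f1_bounds)
        res.is_hybrid_ci = classify_ci(res, self.ci_tol)
        return res

    def estimate(self, X, individual_ids=None) -> list[HybridIndexResult]:
        """Full per-individual results (point estimate, CI, flags).

        ``X`` may be a GenotypeDataset or an (n, L, 2) call array.
        """
        if not hasattr(self, "freqs_"):
            raise RuntimeError("estimator is not fitted")
        if isinstance(X, GenotypeDataset):
            name_to_idx = {n: j for j, n in enumerate(X.locus_names)}
            order = [name_to_idx[n] for n in self.freqs_.locus_names]
            calls = X.calls[:, order, :]
            ids = X.individual_ids
        else:
            calls = np.asarray(X)
            ids = individual_ids or [f"ind{i}" for i in range(calls.shape[0])]
        return [self._estimate_one(i, g) for i, g in zip(ids, calls)]

    def predict(self, X) -> np.ndarray:
        """Point estimates h_hat only."""
        return np.array([r.h_hat for r in self.estimate(X)])

    def results_frame(self, X, dataset: GenotypeDataset | None = None) -> pd.DataFrame:
        """Tidy results table (one row per individual)."""
        results = self.estimate(X)
        df = pd.DataFrame(
            {
                "individual": [r.individual for r in results],
                "h_hat": [r.h_hat for r in results],
                "ci_low": [r.ci_low for r in results],
                "ci_high": [r.ci_high for r in results],
                "loglik_max": [r.loglik_max for r in results],
                "n_loci_used": [r.n_loci_used for r in results],
                "is_f1": [r.is_f1 for r in results],
                "is_hybrid_ci": [r.is_hybrid_ci for r in results],
            }
        )
        src = dataset if dataset is not None else (
            X if isinstance(X, GenotypeDataset) else None
        )
        if src is not None:
            df.insert(1, "locality", list(src.localities))
            if src.meta is not None:
                region = src.meta.set_index("locality")["region"]
                df.insert(2, "region", df["locality"].map(region))
        return df


# ---------------------------------------------------------------------------
# classification and summaries
# ---------------------------------------------------------------------------

def classify_f1(result: HybridIndexResult, bounds=(0.25, 0.75)) -> bool:
    """Boundary rule: h within the lab-F1-calibrated interval (inclusive)."""
    lo, hi = bounds
    if not (0 <= lo < hi <= 1):
        raise ValueError("bounds must satisfy 0 <= low < high <= 1")
    return bool(lo <= result.h_hat <= hi)


def classify_ci(result: HybridIndexResult, tol: float = 1e-9) -> bool:
    """CI rule: hybrid of undetermined class iff the 95% CI excludes 0 and 1."""
    return bool(result.ci_low > 0.0 + tol and result.ci_high < 1.0 - tol)


def summarize_region(results, region: str) -> AdmixtureSummary:
    """Admixture proportions for one region from per-individual results."""
    results = list(results)
    if not results:
        raise ValueError(f"region {region!r}: no individuals")
    n = len(results)
    prop_f1 = sum(r.is_f1 for r in results) / n
    prop_und = sum(r.is_hybrid_ci for r in results) / n
    adv = prop_und - prop_f1
    if adv < 0:
        warnings.warn(
            f"region {region!r}: more F1-flagged than CI-flagged individuals; "
            f"advanced-hybrid proportion clipped to 0"
        )
        adv = 0.0
    return AdmixtureSummary(region, n, prop_f1, prop_und, adv)


def summarize_regions(results_df: pd.DataFrame) -> pd.DataFrame:
    """Per-region admixture summary from a results_frame with a region column."""
    rows = []
    for region, grp in results_df.dropna(subset=["region"]).groupby("region"):
        n = len(grp)
        p_f1 = grp["is_f1"].mean()
        p_ci = grp["is_hybrid_ci"].mean()
        rows.append(
            {
                "region": region,
                "n": n,
                "prop_f1": p_f1,
                "prop_undetermined": p_ci,
                "prop_advanced": max(p_ci - p_f1, 0.0),
            }
        )
    return pd.DataFrame(rows)


def estimate_hybrid_index(
    genotype: np.ndarray,
    freqs: AlleleFrequencyTable,
    individual: str = "ind",
    **params,
) -> HybridIndexResult:
    """One-shot functional wrapper around :class:`HybridIndexEstimator`."""
    est = HybridIndexEstimator(**params)
    est.freqs_ = freqs
    return est._estimate_one(individual, np.asarray(genotype))
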