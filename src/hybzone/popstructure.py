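"""Population-structure statistics for the contact zone.

Covers within-locality diversity (observed/expected heterozygosity and the
Nei G_is heterozygosity-deficit statistic with a permutation test), pairwise
Weir-Cockerham Fst and Slatkin Rst distance matrices, principal coordinates
analysis, great-circle/planar geographic distances, the Mantel test of
isolation by distance (IBD), and a randomization test asking whether
residual genetic differentiation (after removing the distance trend) is
elevated for locality pairs involving sympatric (reinforced) populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


@dataclass
class DistanceMatrix:
    """Symmetric pairwise locality matrix (genetic, geographic, or signal)."""

    labels: list[str]
    values: np.ndarray
    kind: str = "euclidean"  # {fst, rst, geographic_km, euclidean}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix entries must be finite")
        if self.kind in ("fst", "rst") and np.any(
            self.values[~np.eye(n, dtype=bool)] < 0
        ):
            logger.info("%s matrix contains negative estimates (kept)", self.kind)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) entries, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "euclidean"):
        return cls(list(df.index), df.to_numpy(dtype=float), kind)

    def to_phylip(self, path) -> None:
        """Write a PHYLIP-style square distance matrix (label + full row)."""
        lines = [f"{self.n}"]
        for label, row in zip(self.labels, self.values):
            name = f"{label[:10]:<10}"
            lines.append(name + " " + " ".join(f"{v:.6f}" for v in row))
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)


@dataclass
class PcoaResult:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame  # localities x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # per retained axis, of the positive total


@dataclass
class IbdResult:
    """Isolation-by-distance fit plus the sympatry-residual randomization."""

    slope: float
    intercept: float
    mantel_r: float
    r_squared: float
    p_mantel: float
    residuals: DistanceMatrix
    sympatry_stat: float
    p_randomization: float
    n_reps: int
    seed: object = None


# ---------------------------------------------------------------------------
# diversity / HWE
# ---------------------------------------------------------------------------

def _het_stats(calls: np.ndarray) -> tuple[float, float, int]:
    """(H_obs, unbiased H_exp, n typed individuals) for one locality/locus."""
    typed = np.all(calls != MISSING, axis=1)
    g = calls[typed]
    n = g.shape[0]
    if n == 0:
        return np.nan, np.nan, 0
    h_obs = float(np.mean(g[:, 0] != g[:, 1]))
    _, counts = np.unique(g.ravel(), return_counts=True)
    p = counts / (2 * n)
    h_exp = (2 * n / (2 * n - 1)) * (1 - np.sum(p**2)) if n > 1 else np.nan
    return h_obs, float(h_exp), n


def diversity(
    dataset: GenotypeDataset,
    min_n: int = 20,
    n_perms: int = 999,
    seed=None,
) -> pd.DataFrame:
    """Per-locality, per-locus heterozygosity and G_is with permutation p.

    Only localities with at least ``min_n`` typed individuals are analysed.
    G_is = 1 - H_obs / H_exp (Nei); its permutation p-value shuffles allele
    copies among individuals within the locality (which leaves H_exp fixed)
    and is one-sided for heterozygote deficit (permuted G_is >= observed),
    with mid-p handling of ties and the add-one convention.  Monomorphic
    locality/locus combinations have undefined G_is and are flagged with
    NaN.  Rows with locus == "overall" pool H_obs and H_exp across loci
    (multilocus Nei G_is).
    """
    rng = np.random.default_rng(seed)
    rows = []
    localities = sorted(set(dataset.localities))
    for loc in localities:
        idx = dataset.indices_for_localities([loc])
        if idx.size < min_n:
            continue
        sum_ho, sum_he = 0.0, 0.0
        for j, locus in enumerate(dataset.loci):
            calls = dataset.calls[idx, j, :]
            h_obs, h_exp, n = _het_stats(calls)
            if n == 0 or not np.isfinite(h_exp):
                continue
            if h_exp == 0:
                rows.append(
                    dict(locality=loc, locus=locus.name, n=n, h_obs=h_obs,
                         h_exp=h_exp, g_is=np.nan, p_perm=np.nan,
                         monomorphic=True)
                )
                continue
            g_is = 1.0 - h_obs / h_exp
            typed = np.all(calls != MISSING, axis=1)
            pool = calls[typed].ravel().copy()
            hits = ties = 0
            for _ in range(n_perms):
                rng.shuffle(pool)
                pairs = pool.reshape(-1, 2)
                ho_p = np.mean(pairs[:, 0] != pairs[:, 1])
                g_p = 1.0 - ho_p / h_exp
                if g_p > g_is + 1e-12:
                    hits += 1
                elif abs(g_p - g_is) <= 1e-12:
                    ties += 1
            p = (1 + hits + 0.5 * ties) / (n_perms + 1)
            sum_ho += h_obs
            sum_he += h_exp
            rows.append(
                dict(locality=loc, locus=locus.name, n=n, h_obs=h_obs,
                     h_exp=h_exp, g_is=g_is, p_perm=p, monomorphic=False)
            )
        if sum_he > 0:
            rows.append(
                dict(locality=loc, locus="overall", n=int(idx.size),
                     h_obs=sum_ho, h_exp=sum_he,
                     g_is=1.0 - sum_ho / sum_he, p_perm=np.nan,
                     monomorphic=False)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fst (Weir & Cockerham theta) and Rst (Slatkin)
# ---------------------------------------------------------------------------

def _wc_components(calls1: np.ndarray, calls2: np.ndarray):
    """Weir-Cockerham variance components (sum a, sum a+b+c) for one locus.

    ``calls1``/``calls2`` are (n_i, 2) diploid calls of the two populations.
    Returns per-locus sums over alleles; NaN-free only if both populations
    have typed individuals.
    """
    r = 2
    pops = []
    for c in (calls1, calls2):
        typed = np.all(c != MISSING, axis=1)
        g = c[typed]
        if g.shape[0] == 0:
            return None
        pops.append(g)
    ns = np.array([g.shape[0] for g in pops], dtype=float)
    nbar = ns.mean()
    if nbar <= 1:
        return None
    n_c = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in pops]))
    # per-population allele frequencies and heterozygote frequencies,
    # vectorized over the allele universe: shapes (r, K)
    p_i = np.stack(
        [np.mean(g.ravel()[:, None] == alleles[None, :], axis=0) for g in pops]
    )
    h_i = np.stack(
        [
            np.mean((g[:, :, None] == alleles[None, None, :]).sum(axis=1) == 1,
                    axis=0)
            for g in pops
        ]
    )
    pbar = ns @ p_i / (r * nbar)
    s2 = ns @ (p_i - pbar) ** 2 / ((r - 1) * nbar)
    hbar = ns @ h_i / (r * nbar)
    inner = pbar * (1 - pbar) - s2 * (r - 1) / r
    va = (nbar / n_c) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
    vb = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    vc = hbar / 2.0
    return float(va.sum()), float((va + vb + vc).sum())


def pairwise_fst(
    dataset: GenotypeDataset, min_n: int = 5, strict: bool = True
) -> DistanceMatrix:
    """Pairwise multi-allelic Weir-Cockerham theta between localities.

    Theta per pair is the ratio of sums of variance components across loci
    and alleles; negative estimates are kept.  Only localities with at least
    ``min_n`` individuals enter the matrix.  A pair sharing no typed locus
    raises in strict mode (NaN otherwise — but the matrix container requires
    finite entries, so strict is the default).
    """
    localities = sorted(
        loc
        for loc in set(dataset.localities)
        if dataset.indices_for_localities([loc]).size >= min_n
    )
    if len(localities) < 2:
        raise ValueError("need at least two localities meeting min_n")
    idx = {loc: dataset.indices_for_localities([loc]) for loc in localities}
    n = len(localities)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num, den = 0.0, 0.0
            for l in range(dataset.n_loci):
                comp = _wc_components(
                    dataset.calls[idx[localities[i]], l, :],
                    dataset.calls[idx[localities[j]], l, :],
                )
                if comp is None:
                    continue
                num += comp[0]
                den += comp[1]
            if den == 0:
                if strict:
                    raise ValueError(
                        f"pair ({localities[i]}, {localities[j]}) shares no "
                        f"informative locus"
                    )
                theta = np.nan
            else:
                theta = num / den
            out[i, j] = out[j, i] = theta
    return DistanceMatrix(localities, out, kind="fst")


def _pair_ss(values: np.ndarray) -> tuple[float, int]:
    """(sum of squared differences over all pairs, number of pairs)."""
    n = values.size
    if n < 2:
        return 0.0, 0
    ss = n * np.sum(values**2) - np.sum(values) ** 2
    return float(ss), n * (n - 1) // 2


def pairwise_rst(dataset: GenotypeDataset, min_n: int = 5) -> DistanceMatrix:
    """Pairwise Slatkin Rst from allele-size variance components.

    Allele identifiers must carry integer fragment sizes.  Per locus,
    S_bar is the average squared size difference over all allele-copy pairs
    in the pooled pair of localities and S_w over within-locality pairs;
    Rst = sum_l (S_bar - S_w) / sum_l S_bar.
    """
    localities = sorted(
        loc
        for loc in set(dataset.localities)
        if dataset.indices_for_localities([loc]).size >= min_n
    )
    if len(localities) < 2:
        raise ValueError("need at least two localities meeting min_n")
    idx = {loc: dataset.indices_for_localities([loc]) for loc in localities}
    n = len(localities)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num, den = 0.0, 0.0
            for l in range(dataset.n_loci):
                xs = []
                for loc in (localities[i], localities[j]):
                    v = dataset.calls[idx[loc], l, :].ravel()
                    xs.append(v[v != MISSING].astype(float))
                pooled = np.concatenate(xs)
                ss_tot, np_tot = _pair_ss(pooled)
                if np_tot == 0:
                    continue
                s_bar = ss_tot / np_tot
                ss_w = sum(_pair_ss(x)[0] for x in xs)
                np_w = sum(_pair_ss(x)[1] for x in xs)
                s_w = ss_w / np_w if np_w else 0.0
                num += s_bar - s_w
                den += s_bar
            out[i, j] = out[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrix(localities, out, kind="rst")


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(dist: DistanceMatrix, eps: float = 1e-10) -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering.

    Eigendecomposition of -0.5 * J D^2 J; axes are ordered by descending
    eigenvalue, coordinates are eigenvectors scaled by sqrt(eigenvalue), and
    percent variance is computed relative to the sum of positive eigenvalues
    (negative eigenvalues, which arise from non-Euclidean distances, are
    excluded from the denominator).
    """
    D = dist.values
    n = dist.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > eps * max(1.0, abs(evals[0]) if evals.size else 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total_pos = evals[evals > 0].sum()
    pct = 100.0 * evals[pos] / total_pos if total_pos > 0 else np.zeros(pos.sum())
    frame = pd.DataFrame(
        coords,
        index=dist.labels,
        columns=[f"axis{k + 1}" for k in range(coords.shape[1])],
    )
    return PcoaResult(frame, evals, pct)


# ---------------------------------------------------------------------------
# geographic distances
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (mean Earth radius)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = la2 - la1, lo2 - lo1
    h = np.sin(dlat / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def geographic_distances(meta: pd.DataFrame, localities=None) -> DistanceMatrix:
    """Pairwise locality distances from the metadata table.

    Uses the haversine great-circle formula for ``coord_system == "lonlat"``
    rows (GPS coordinates) and planar Euclidean distance for synthetic
    ``"planar"`` coordinates; the two systems cannot be mixed.
    """
    m = meta if localities is None else meta[meta["locality"].isin(set(localities))]
    m = m.sort_values("locality").reset_index(drop=True)
    systems = set(m["coord_system"].fillna("lonlat"))
    if len(systems) > 1:
        raise ValueError(f"mixed coordinate systems: {sorted(systems)}")
    system = systems.pop() if systems else "lonlat"
    lat = m["lat"].to_numpy(float)
    lon = m["lon"].to_numpy(float)
    if system == "lonlat" and np.any(np.abs(lat) > 90):
        raise ValueError("latitudes must lie in [-90, 90]")
    n = len(m)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if system == "planar":
                d = float(np.hypot(lat[i] - lat[j], lon[i] - lon[j]))
            else:
                d = float(haversine_km(lat[i], lon[i], lat[j], lon[j]))
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(m["locality"]), out, kind="geographic_km")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perms: int = 10_000,
    seed=None,
) -> tuple[float, float, float]:
    """Mantel test: correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    null jointly permutes rows and columns of the second matrix.  The p is
    one-tailed for positive association with the add-one convention.
    Returns (r, r^2, p).
    """
    if d1.labels != d2.labels:
        raise ValueError("matrices must share the same locality labels")
    n = d1.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 localities")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    y = d2.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a distance triangle: r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perms):
        perm = rng.permutation(n)
        y_p = d2.values[np.ix_(perm, perm)][iu]
        if np.corrcoef(x, y_p)[0, 1] >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perms + 1)
    return r_obs, r_obs**2, p


# ---------------------------------------------------------------------------
# IBD residual randomization
# ---------------------------------------------------------------------------

def _pair_classes(sym: np.ndarray, iu) -> np.ndarray:
    """True for pairs involving at least one sympatric locality."""
    return sym[iu[0]] | sym[iu[1]]


def ibd_residual_randomization(
    fst: DistanceMatrix,
    geo: DistanceMatrix,
    sympatric: dict | pd.Series,
    n_reps: int = 200,
    seed=None,
    mantel_perms: int = 10_000,
    linearize: bool = False,
) -> IbdResult:
    """Test for elevated residual differentiation around sympatric localities.

    Fits ordinary least squares of pairwise Fst on geographic distance
    (optionally on Fst/(1-Fst)); the statistic is the mean regression
    residual over pairs involving at least one sympatric locality minus the
    mean over allopatric-allopatric pairs.  The null permutes the
    sympatric/allopatric labels across localities (residuals are fixed; only
    the pair classes change); the one-tailed p uses the add-one convention.
    """
    if fst.labels != geo.labels:
        raise ValueError("Fst and geographic matrices must share labels")
    sym = np.array([bool(sympatric[l]) for l in fst.labels])
    if sym.all() or (~sym).all():
        raise ValueError("need both sympatric and allopatric localities")
    if sym.sum() < 2 or (~sym).sum() < 2:
        raise ValueError("need at least 2 localities of each class")
    n = fst.n
    iu = np.triu_indices(n, k=1)
    y = fst.values[iu]
    if linearize:
        y = y / (1.0 - y)
    x = geo.values[iu]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    resid_mat = np.zeros((n, n))
    resid_mat[iu] = resid
    resid_mat = resid_mat + resid_mat.T
    mantel_seed = int(np.random.default_rng(seed).integers(2**31 - 1))
    mantel_r, r2, p_mantel = mantel(geo, fst, n_perms=mantel_perms, seed=mantel_seed)
    cls = _pair_classes(sym, iu)
    observed = resid[cls].mean() - resid[~cls].mean()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        perm_sym = rng.permutation(sym)
        c = _pair_classes(perm_sym, iu)
        stat = resid[c].mean() - resid[~c].mean()
        if stat >= observed - 1e-15:
            hits += 1
    p_rand = (1 + hits) / (n_reps + 1)
    return IbdResult(
        slope=float(slope),
        intercept=float(intercept),
        mantel_r=mantel_r,
        r_squared=r2,
        p_mantel=p_mantel,
        residuals=DistanceMatrix(fst.labels, resid_mat, kind="euclidean"),
        sympatry_stat=float(observed),
        p_randomization=p_rand,
        n_reps=n_reps,
        seed=seed,
    )
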