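"""Synthetic contact-zone generator.

Emulates the statistical structure of a two-species reinforcement contact
zone sampled with codominant multi-allelic (microsatellite-style) markers:

* two parental gene pools at 12 loci with 6-32 alleles per locus, diverged
  under a Balding-Nichols/Dirichlet model with a single differentiation
  knob ``f_div``;
* localities laid out on a planar map (km), with species ranges on either
  side of a contact line and sympatric focal regions along it; locality
  allele frequencies accumulate stepping-stone drift along the range so
  that genetic differentiation grows with geographic separation
  (isolation by distance);
* sympatric localities contain pure, F1, F2 and backcross individuals in
  configurable proportions, with asymmetric maternal parentage of F1s;
* advertisement-call variables (pulse rate, pulse number) linear in true
  ancestry with temperature dependence, Gaussian noise, and an additive
  character-displacement offset in sympatry.

All stochastic operations take explicit integer seeds; a master seed
derives independent per-stage streams deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustics import TARGET_TEMP
from .genotypes import GenotypeDataset, LocusDef, validate_metadata
from .hindex import AlleleFrequencyTable
from .resampling import LnPTable

logger = logging.getLogger(__name__)

HYBRID_CLASSES = ("pureA", "pureB", "F1", "F2", "BxA", "BxB")

#: Expected A-ancestry per hybrid class (h = 1 means pure species A).
H_TRUE = {"pureA": 1.0, "pureB": 0.0, "F1": 0.5, "F2": 0.5, "BxA": 0.75, "BxB": 0.25}


@dataclass
class LocalitySpec:
    """One sampling locality: where it is, which species, who lives there."""

    locality: str
    species: str  # "A", "B" (reference species of the sample)
    sympatry: str  # "sympatric" | "allopatric"
    x: float
    y: float
    n: int
    region: str | None = None
    class_mix: dict = None  # proportions over HYBRID_CLASSES; default pure

    def __post_init__(self):
        if self.sympatry not in ("sympatric", "allopatric"):
            raise ValueError(f"bad sympatry {self.sympatry!r}")
        if self.class_mix is None:
            self.class_mix = {("pureA" if self.species == "A" else "pureB"): 1.0}
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"locality {self.locality}: class mix sums to {total}, not 1"
            )
        unknown = set(self.class_mix) - set(HYBRID_CLASSES)
        if unknown:
            raise ValueError(f"unknown hybrid classes {sorted(unknown)}")


@dataclass
class CallModel:
    """Linear model of one call character: value = intercept + slope * h
    + temp_slope * (T - 14) + displacement * h (sympatric only) + noise."""

    intercept: float
    slope: float
    temp_slope: float
    noise_sd: float
    displacement: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass
class SimConfig:
    """Configuration of a synthetic contact zone.

    Defaults mirror the marker panel and zone structure the analysis is
    designed for: 12 loci with 6-32 alleles each, strongly diverged parental
    pools, a locality layout with pooled allopatric reference groups of 188
    (species A) and 80 (species B) individuals and ten sympatric focal
    regions, maternal asymmetry of 0.74 toward species-B mothers in F1s,
    and calls displaced in sympatric species-A males.
    """

    n_loci: int = 12
    alleles_per_locus: tuple[int, int] = (6, 32)
    f_div: float = 0.4
    ancestral_concentration: float = 1.0
    diagnostic: bool = False
    drift_scale: float = 0.0005  # Balding-Nichols F accumulated per km
    maternal_asymmetry: float = 0.74  # P(F1 mother is species B)
    localities: list[LocalitySpec] = field(default_factory=lambda: default_layout())
    call_models: dict = field(
        default_factory=lambda: {
            "pulse_rate": CallModel(6.0, 6.0, 0.8, 1.0, displacement=6.0),
            "pulse_number": CallModel(8.0, 4.0, 0.2, 1.0, displacement=4.0),
        }
    )
    displaced_species: str = "A"
    temp_mean: float = 14.0
    temp_sd: float = 3.0
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.f_div < 1.0):
            raise ValueError("f_div must lie strictly in (0, 1)")
        if not (0.0 <= self.maternal_asymmetry <= 1.0):
            raise ValueError("maternal_asymmetry must lie in [0, 1]")
        lo, hi = self.alleles_per_locus
        if not (2 <= lo <= hi):
            raise ValueError("alleles_per_locus range invalid")


def default_layout() -> list[LocalitySpec]:
    """Study-scale locality layout.

    Sixteen allopatric species-A localities (pooled n = 188) and seven
    allopatric species-B localities (pooled n = 80) spread through the two
    ranges, plus ten sympatric focal regions (R1-R10) along the contact
    line at y = 0, each with co-located species-A and species-B samples and
    a region-specific hybrid mix (hybrid-rich in R2 and R8, hybrid-poor in
    R5-R6, intermediate elsewhere).
    """
    a_sizes = [18, 83, 9, 5, 12, 3, 2, 3, 6, 2, 5, 16, 6, 10, 4, 4]
    b_sizes = [5, 2, 6, 6, 12, 36, 13]
    out = []
    for i, n in enumerate(a_sizes):
        out.append(
            LocalitySpec(
                locality=f"A_allo{i + 1:02d}",
                species="A",
                sympatry="allopatric",
                x=60.0 + 55.0 * i,
                y=80.0 + 40.0 * ((i * 7) % 5),
                n=n,
            )
        )
    for i, n in enumerate(b_sizes):
        out.append(
            LocalitySpec(
                locality=f"B_allo{i + 1:02d}",
                species="B",
                sympatry="allopatric",
                x=90.0 + 120.0 * i,
                y=-80.0 - 40.0 * ((i * 5) % 4),
                n=n,
            )
        )
    rich = {"pureA": 0.18, "pureB": 0.18, "F1": 0.26, "F2": 0.12,
            "BxA": 0.13, "BxB": 0.13}
    poor = {"pureA": 0.44, "pureB": 0.40, "F1": 0.06, "F2": 0.04,
            "BxA": 0.03, "BxB": 0.03}
    mid = {"pureA": 0.35, "pureB": 0.33, "F1": 0.14, "F2": 0.06,
           "BxA": 0.06, "BxB": 0.06}
    region_n = {"R1": 10, "R2": 120, "R3": 24, "R4": 8, "R5": 45,
                "R6": 60, "R7": 29, "R8": 66, "R9": 80, "R10": 26}
    region_mix = {"R1": mid, "R2": rich, "R3": mid, "R4": mid, "R5": poor,
                  "R6": poor, "R7": mid, "R8": rich, "R9": mid, "R10": mid}
    for k, (region, n) in enumerate(region_n.items()):
        x = 50.0 + 95.0 * k
        for sp, frac in (("A", 0.5), ("B", 0.5)):
            out.append(
                LocalitySpec(
                    locality=f"{region}_{sp}",
                    species=sp,
                    sympatry="sympatric",
                    x=x,
                    y=5.0 if sp == "A" else -5.0,
                    n=max(int(round(n * frac)), 2),
                    region=region,
                    class_mix=region_mix[region],
                )
            )
    return out


# ---------------------------------------------------------------------------
# parental allele frequencies
# ---------------------------------------------------------------------------

def _bn_drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw around p with differentiation f."""
    conc = p * (1.0 - f) / f
    # Dirichlet with tiny concentrations can return exact zeros; floor them
    draw = rng.dirichlet(np.maximum(conc, 1e-9))
    draw = np.maximum(draw, 1e-12)
    return draw / draw.sum()


def sim_parental_freqs(config: SimConfig, seed=None) -> AlleleFrequencyTable:
    """Draw diverged parental allele-frequency tables for the two species.

    Per locus: an ancestral frequency vector from a symmetric Dirichlet,
    then per species a Balding-Nichols Dirichlet draw with concentration
    ancestral * (1 - f_div) / f_div.  With ``diagnostic=True`` the two
    species are instead fixed on disjoint halves of the allele universe
    (fully informative markers).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.alleles_per_locus
    names, alleles, p_a, p_b = [], [], [], []
    for j in range(config.n_loci):
        k = int(rng.integers(lo, hi + 1))
        motif = 4 if j % 2 == 0 else 2
        uni = 100 + motif * np.arange(k)
        anc = rng.dirichlet(np.full(k, config.ancestral_concentration))
        anc = np.maximum(anc, 1e-12)
        anc /= anc.sum()
        if config.diagnostic:
            half = max(k // 2, 1)
            pa = np.zeros(k)
            pb = np.zeros(k)
            pa[:half] = anc[:half] / anc[:half].sum()
            pb[half:] = anc[half:] / anc[half:].sum()
        else:
            pa = _bn_drift(anc, config.f_div, rng)
            pb = _bn_drift(anc, config.f_div, rng)
        names.append(f"L{j + 1:02d}")
        alleles.append(uni)
        p_a.append(pa)
        p_b.append(pb)
    big = 10**6  # generating truth, not a finite sample
    return AlleleFrequencyTable(
        names, alleles, p_a, p_b,
        np.full(config.n_loci, big), np.full(config.n_loci, big),
    )


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

_CLASS_POOLS = {
    "pureA": ("A", "A"), "pureB": ("B", "B"), "F1": ("A", "B"),
    "F2": ("mix", "mix"), "BxA": ("A", "mix"), "BxB": ("B", "mix"),
}


def sim_class_batch(
    hybrid_class: str,
    freqs: AlleleFrequencyTable,
    n: int,
    rng: np.random.Generator,
    maternal_asymmetry: float = 0.74,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate ``n`` individuals of one hybrid class (vectorized).

    Returns (genotypes (n, L, 2), h_true (n,), maternal labels (n,)).
    Gamete pools per locus: pure parents draw both copies from their
    species; F1s one copy from each; F2s draw each copy from a 50/50
    gamete mixture; first-generation backcrosses draw one parental copy
    and one 50/50 copy.  Maternal labels: pure individuals carry their own
    species, F1 mothers are species B with probability
    ``maternal_asymmetry``, later-generation hybrids are "unknown".
    """
    if hybrid_class not in HYBRID_CLASSES:
        raise ValueError(f"unknown hybrid class {hybrid_class!r}")
    pools = _CLASS_POOLS[hybrid_class]
    L = freqs.n_loci
    geno = np.empty((n, L, 2), dtype=int)
    for j in range(L):
        uni = freqs.alleles[j]
        for c, pool in enumerate(pools):
            if pool == "mix":
                from_a = rng.random(n) < 0.5
                draw = np.where(
                    from_a,
                    rng.choice(uni, size=n, p=freqs.p_a[j]),
                    rng.choice(uni, size=n, p=freqs.p_b[j]),
                )
            else:
                p = freqs.p_a[j] if pool == "A" else freqs.p_b[j]
                draw = rng.choice(uni, size=n, p=p)
            geno[:, j, c] = draw
    if hybrid_class == "pureA":
        maternal = np.full(n, "A", dtype=object)
    elif hybrid_class == "pureB":
        maternal = np.full(n, "B", dtype=object)
    elif hybrid_class == "F1":
        maternal = np.where(rng.random(n) < maternal_asymmetry, "B", "A").astype(
            object
        )
    else:
        maternal = np.full(n, "unknown", dtype=object)
    return geno, np.full(n, H_TRUE[hybrid_class]), maternal


def sim_individual(
    hybrid_class: str,
    freqs: AlleleFrequencyTable,
    rng: np.random.Generator,
    maternal_asymmetry: float = 0.74,
) -> tuple[np.ndarray, float, str]:
    """Simulate one individual; see :func:`sim_class_batch`."""
    geno, h, mat = sim_class_batch(
        hybrid_class, freqs, 1, rng, maternal_asymmetry
    )
    return geno[0], float(h[0]), str(mat[0])


# ---------------------------------------------------------------------------
# whole zone
# ---------------------------------------------------------------------------

@dataclass
class ZoneData:
    """Everything a simulated zone produces: data plus ground truth."""

    dataset: GenotypeDataset
    calls: pd.DataFrame
    truth: pd.DataFrame
    parental_freqs: AlleleFrequencyTable
    locality_freqs: dict  # locality -> AlleleFrequencyTable


def _drifted_locality_freqs(
    config: SimConfig, base: AlleleFrequencyTable, rng: np.random.Generator
) -> dict:
    """Per-locality frequency tables with stepping-stone drift.

    For each species, localities are chained in order of x-coordinate and
    each drifts from its predecessor by a Balding-Nichols step whose F is
    ``drift_scale`` times the separation, so divergence accumulates with
    distance along the range (isolation by distance).  Species A and B
    drift independently; the A pool of every locality drifts along the
    species-A chain and vice versa, so sympatric hybrids inherit locally
    drifted parental pools.
    """
    out = {spec.locality: None for spec in config.localities}
    chains = {"A": [], "B": []}
    for spec in config.localities:
        chains[spec.species].append(spec)
    drifted = {"A": {}, "B": {}}  # species -> locality -> list of freq vecs
    for sp, chain in chains.items():
        chain = sorted(chain, key=lambda s: (s.x, s.y, s.locality))
        base_p = base.p_a if sp == "A" else base.p_b
        prev = [p.copy() for p in base_p]
        prev_x = None
        for spec in chain:
            if config.drift_scale > 0 and prev_x is not None:
                step = np.hypot(spec.x - prev_x[0], spec.y - prev_x[1])
                f = min(config.drift_scale * step, 0.4)
                if f > 1e-9:
                    prev = [
                        _bn_drift(_support_mask(p, bp), f, rng) * (bp > 0)
                        for p, bp in zip(prev, base_p)
                    ]
                    prev = [_renorm(p) for p in prev]
            drifted[sp][spec.locality] = [p.copy() for p in prev]
            prev_x = (spec.x, spec.y)
    for spec in config.localities:
        # every locality carries both parental pools: its own species'
        # locally drifted pool plus the other species' nearest-chain pool
        pa = drifted["A"].get(spec.locality)
        pb = drifted["B"].get(spec.locality)
        if pa is None:
            pa = _nearest_pool(spec, chains["A"], drifted["A"], base.p_a)
        if pb is None:
            pb = _nearest_pool(spec, chains["B"], drifted["B"], base.p_b)
        out[spec.locality] = AlleleFrequencyTable(
            base.locus_names, base.alleles, pa, pb, base.n_a, base.n_b
        )
    return out


def _support_mask(p, base_p):
    """Restrict a frequency vector to the base support and renormalize."""
    q = np.where(base_p > 0, np.maximum(p, 1e-12), 0.0)
    return q / q.sum()


def _renorm(p):
    q = np.maximum(p, 0.0)
    return q / q.sum()


def _nearest_pool(spec, chain, drifted, base_p):
    if not chain:
        return [p.copy() for p in base_p]
    nearest = min(chain, key=lambda s: np.hypot(s.x - spec.x, s.y - spec.y))
    return [p.copy() for p in drifted[nearest.locality]]


def sim_zone(config: SimConfig, seed=None) -> ZoneData:
    """Simulate a full contact zone: genotypes, calls, and truth tables."""
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    s_freq, s_drift, s_ind, s_call = master.spawn(4)
    parental = sim_parental_freqs(config, seed=s_freq)
    rng_drift = np.random.default_rng(s_drift)
    loc_freqs = _drifted_locality_freqs(config, parental, rng_drift)

    rng_ind = np.random.default_rng(s_ind)
    rng_call = np.random.default_rng(s_call)
    ids, locs, calls_rows, truth_rows, genos, maternal = [], [], [], [], [], []
    meta_rows = []
    counter = 0
    for spec in config.localities:
        if spec.n == 0:
            logger.warning(
                "locality %s has zero individuals: skipped", spec.locality
            )
            continue
        meta_rows.append(
            dict(
                locality=spec.locality,
                species=spec.species,
                region=spec.region,
                sympatry=spec.sympatry,
                lat=spec.y,
                lon=spec.x,
                coord_system="planar",
                group=None,
            )
        )
        classes = list(spec.class_mix)
        probs = np.array([spec.class_mix[c] for c in classes])
        draws = rng_ind.multinomial(spec.n, probs)
        freqs = loc_freqs[spec.locality]
        for cls, count in zip(classes, draws):
            if count == 0:
                continue
            geno_b, h_b, mat_b = sim_class_batch(
                cls, freqs, int(count), rng_ind, config.maternal_asymmetry
            )
            for b in range(int(count)):
                counter += 1
                ind = f"ind{counter:05d}"
                h_true, mat = float(h_b[b]), str(mat_b[b])
                ids.append(ind)
                locs.append(spec.locality)
                genos.append(geno_b[b])
                maternal.append(mat)
                truth_rows.append(
                    dict(individual=ind, locality=spec.locality,
                         region=spec.region, sympatry=spec.sympatry,
                         hybrid_class=cls, h_true=h_true, maternal=mat)
                )
                t = rng_call.normal(config.temp_mean, config.temp_sd)
                displaced = (
                    spec.sympatry == "sympatric"
                    and config.displaced_species == "A"
                )
                row = dict(
                    individual=ind,
                    locality=spec.locality,
                    species={"pureA": "A", "pureB": "B"}.get(cls, "hybrid"),
                    region=spec.region,
                    sympatry=spec.sympatry,
                    temperature=t,
                )
                for var, m in config.call_models.items():
                    val = (
                        m.intercept
                        + m.slope * h_true
                        + m.temp_slope * (t - TARGET_TEMP)
                        + (m.displacement * h_true if displaced else 0.0)
                        + rng_call.normal(0.0, m.noise_sd)
                    )
                    row[var] = max(val, 1.0)
                calls_rows.append(row)
    meta = validate_metadata(pd.DataFrame(meta_rows))
    dataset = GenotypeDataset(
        individual_ids=ids,
        localities=locs,
        loci=[LocusDef(n) for n in parental.locus_names],
        calls=np.stack(genos) if genos else np.empty((0, config.n_loci, 2), int),
        meta=meta,
        maternal=np.array(maternal, dtype=object),
    )
    return ZoneData(
        dataset=dataset,
        calls=pd.DataFrame(calls_rows),
        truth=pd.DataFrame(truth_rows),
        parental_freqs=parental,
        locality_freqs=loc_freqs,
    )


# ---------------------------------------------------------------------------
# log-probability tables for the delta-K rule
# ---------------------------------------------------------------------------

def sim_lnp_table(
    k_range=(1, 10),
    n_reps: int = 10,
    planted_k: int = 2,
    seed=None,
    noise_sd: float = 30.0,
    rise: float = 800.0,
    plateau: float = 20.0,
) -> LnPTable:
    """Synthetic per-K replicate log-probabilities with a kink at planted_k.

    The mean curve climbs steeply (``rise`` per K) up to ``planted_k`` and
    then flattens (``plateau`` per K); replicates add Gaussian noise.  With
    zero noise the replicate SD vanishes and the delta-K statistic is
    flagged infinite at the kink.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per K (SD undefined)")
    ks = np.arange(k_range[0], k_range[1] + 1)
    rng = np.random.default_rng(seed)
    means = -5000.0 + rise * np.minimum(ks, planted_k) + plateau * np.maximum(
        ks - planted_k, 0
    )
    lnp = means[:, None] + rng.normal(0.0, noise_sd, size=(ks.size, n_reps))
    return LnPTable(ks, lnp)
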