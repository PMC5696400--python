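"""Diversity, Fst/Rst, PCoA, geographic distances, Mantel, and IBD tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from hybzone.genotypes import GenotypeDataset, LocusDef, validate_metadata
from hybzone.popstructure import (
    DistanceMatrix,
    diversity,
    geographic_distances,
    haversine_km,
    ibd_residual_randomization,
    mantel,
    pairwise_fst,
    pairwise_rst,
    pcoa,
)


def _two_pop_dataset(calls1, calls2, n_loci=1):
    n1, n2 = calls1.shape[0], calls2.shape[0]
    meta = validate_metadata(
        pd.DataFrame(
            {
                "locality": ["p1", "p2"],
                "species": ["A", "A"],
                "sympatry": ["allopatric", "allopatric"],
            }
        )
    )
    return GenotypeDataset(
        [f"i{k}" for k in range(n1 + n2)],
        ["p1"] * n1 + ["p2"] * n2,
        [LocusDef(f"L{j}") for j in range(n_loci)],
        np.concatenate([calls1, calls2]),
        meta,
    )


# ---------------------------------------------------------------------------
# independent scalar oracle for Weir-Cockerham theta (one locus, two pops)
# ---------------------------------------------------------------------------

def wc_theta_oracle(calls1, calls2):
    """Longhand per-allele variance components, scalar arithmetic only."""
    pops = [calls1, calls2]
    r = 2
    ns = [len(p) for p in pops]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    alleles = sorted(
        {int(a) for p in pops for g in p for a in g}
    )
    a_sum = bc_sum = 0.0
    for allele in alleles:
        p_i, h_i = [], []
        for pop in pops:
            copies = [a for g in pop for a in g]
            p_i.append(sum(1 for a in copies if a == allele) / len(copies))
            h_i.append(
                sum(1 for g in pop if sorted(g).count(allele) == 1) / len(pop)
            )
        pbar = sum(n * p for n, p in zip(ns, p_i)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, h_i)) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        bc_sum += a + b + c
    return a_sum / bc_sum


def rst_oracle(calls1, calls2):
    """Brute-force average squared allele-size differences over all pairs."""
    def mean_sq(vals):
        pairs = list(itertools.combinations(vals, 2))
        return sum((x - y) ** 2 for x, y in pairs) / len(pairs), len(pairs)

    pooled = [a for g in np.concatenate([calls1, calls2]) for a in g]
    s_bar, _ = mean_sq(pooled)
    ss_w = n_w = 0
    for pop in (calls1, calls2):
        vals = [a for g in pop for a in g]
        s, n = mean_sq(vals)
        ss_w += s * n
        n_w += n
    return (s_bar - ss_w / n_w) / s_bar


class TestDiversity:
    def test_heterozygote_excess_sign(self):
        # every individual heterozygous 100/120: H_obs = 1 > H_exp, G_is < 0
        calls = np.tile([[100, 120]], (20, 1))[:, None, :]
        ds = _two_pop_dataset(calls, calls)
        out = diversity(ds, min_n=10, n_perms=99, seed=1)
        row = out[(out.locality == "p1") & (out.locus == "L0")].iloc[0]
        assert row["h_obs"] == 1.0
        assert row["h_obs"] > row["h_exp"]
        assert row["g_is"] < 0

    def test_hand_computed_five_individual_fixture(self):
        """n=5, genotypes (100/100, 100/120, 100/120, 120/120, 100/100):
        H_obs = 2/5; allele copies of 100: 2+1+1+0+2 = 6 of 10, so
        p(100) = 0.6 and p(120) = 0.4;
        H_exp = (10/9) * (1 - 0.36 - 0.16) = 0.5333...; G_is = 1 - 0.4/H_exp."""
        calls = np.array(
            [[[100, 100]], [[100, 120]], [[100, 120]], [[120, 120]],
             [[100, 100]]]
        )
        ds = _two_pop_dataset(calls, calls)
        out = diversity(ds, min_n=5, n_perms=49, seed=0)
        row = out[(out.locality == "p1") & (out.locus == "L0")].iloc[0]
        h_exp = (10 / 9) * (1 - 0.6**2 - 0.4**2)
        assert row["h_obs"] == pytest.approx(0.4, abs=1e-12)
        assert row["h_exp"] == pytest.approx(h_exp, abs=1e-12)
        assert row["g_is"] == pytest.approx(1 - 0.4 / h_exp, abs=1e-12)

    def test_monomorphic_locus_flagged(self):
        calls = np.tile([[100, 100]], (25, 1))[:, None, :]
        ds = _two_pop_dataset(calls, calls)
        out = diversity(ds, min_n=10, n_perms=9, seed=0)
        row = out[(out.locality == "p1") & (out.locus == "L0")].iloc[0]
        assert bool(row["monomorphic"]) and np.isnan(row["g_is"])

    def test_null_permutation_p_roughly_uniform(self, rng):
        """Genotypes drawn under Hardy-Weinberg give approximately uniform
        permutation p-values across loci (KS test)."""
        n, n_loci = 100, 200
        freqs = rng.dirichlet(np.ones(4), size=n_loci)
        calls = np.empty((n + 5, n_loci, 2), int)
        for j in range(n_loci):
            calls[:, j, :] = rng.choice(
                [100, 104, 108, 112], p=freqs[j], size=(n + 5, 2)
            )
        ds = _two_pop_dataset(calls[:n], calls[n:], n_loci=n_loci)
        out = diversity(ds, min_n=50, n_perms=199, seed=7)
        ps = out[(out.locality == "p1") & (out.locus != "overall")]["p_perm"]
        ps = ps.dropna()
        assert len(ps) > 150
        assert kstest(ps, "uniform").pvalue > 0.01


class TestFst:
    def test_identical_frequencies_near_zero(self, rng):
        pool = rng.choice([100, 104, 108], size=(200, 1, 2))
        ds = _two_pop_dataset(pool[:100], pool[100:])
        fst = pairwise_fst(ds)
        assert abs(fst.values[0, 1]) < 0.02

    def test_fixed_differences_near_one(self):
        c1 = np.tile([[100, 100]], (50, 1))[:, None, :]
        c2 = np.tile([[120, 120]], (50, 1))[:, None, :]
        fst = pairwise_fst(_two_pop_dataset(c1, c2))
        assert fst.values[0, 1] >= 0.97

    def test_matches_scalar_oracle_on_toy_tables(self, rng):
        for trial in range(5):
            c1 = rng.choice([100, 104, 108], size=(8, 1, 2))
            c2 = rng.choice([100, 104, 112], size=(6, 1, 2))
            ds = _two_pop_dataset(c1, c2)
            got = pairwise_fst(ds).values[0, 1]
            want = wc_theta_oracle(c1[:, 0, :], c2[:, 0, :])
            assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_individual_ordering(self, rng):
        c1 = rng.choice([100, 104, 108], size=(12, 2, 2))
        c2 = rng.choice([100, 104, 112], size=(9, 2, 2))
        ds = _two_pop_dataset(c1, c2, n_loci=2)
        base = pairwise_fst(ds).values[0, 1]
        perm = rng.permutation(ds.n_individuals)
        shuffled = ds.subset(perm)
        assert pairwise_fst(shuffled).values[0, 1] == pytest.approx(base, 1e-12)


class TestRst:
    def test_fixed_size_difference_gives_one(self):
        c1 = np.tile([[100, 100]], (30, 1))[:, None, :]
        c2 = np.tile([[120, 120]], (30, 1))[:, None, :]
        rst = pairwise_rst(_two_pop_dataset(c1, c2))
        assert rst.values[0, 1] == pytest.approx(1.0)

    def test_exchangeable_individuals_give_near_zero(self, rng):
        pool = rng.choice([100, 104, 108, 116], size=(60, 1, 2))
        vals = []
        for _ in range(100):
            perm = rng.permutation(60)
            ds = _two_pop_dataset(pool[perm[:30]], pool[perm[30:]])
            vals.append(pairwise_rst(ds).values[0, 1])
        assert abs(np.mean(vals)) < 0.02

    def test_matches_brute_force_pair_sums(self, rng):
        for trial in range(5):
            c1 = rng.choice([100, 104, 108], size=(7, 1, 2))
            c2 = rng.choice([104, 112, 120], size=(5, 1, 2))
            ds = _two_pop_dataset(c1, c2)
            got = pairwise_rst(ds).values[0, 1]
            want = rst_oracle(c1[:, 0, :], c2[:, 0, :])
            assert got == pytest.approx(want, abs=1e-10)


class TestPcoa:
    def test_two_points(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 4.0], [4.0, 0.0]]))
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        assert coords.shape == (2, 1)
        assert sorted(coords.ravel()) == pytest.approx([-2.0, 2.0])
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_reconstructs_euclidean_configuration(self, rng):
        pts = rng.normal(size=(12, 2))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        res = pcoa(DistanceMatrix([f"l{i}" for i in range(12)], D))
        emb = res.coordinates.to_numpy()
        D2 = np.linalg.norm(emb[:, None, :] - emb[None, :, :], axis=-1)
        assert np.allclose(D, D2, atol=1e-9)

    def test_zero_matrix_gives_zero_eigenvalues(self):
        res = pcoa(DistanceMatrix(["a", "b", "c"], np.zeros((3, 3))))
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_agrees_with_skbio(self, rng):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        pts = rng.normal(size=(8, 3))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        ours = pcoa(DistanceMatrix([f"l{i}" for i in range(8)], D))
        theirs = skbio_ordination.pcoa(skbio_distance.DistanceMatrix(D))
        np.testing.assert_allclose(
            ours.eigenvalues[:3],
            theirs.eigvals.to_numpy()[:3],
            atol=1e-8,
        )
        for k in range(3):
            a = ours.coordinates.to_numpy()[:, k]
            b = theirs.samples.to_numpy()[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPhylipExport:
    def test_round_trippable_square_format(self, tmp_path, rng):
        d = _random_distance_matrix(rng, ["loc_one", "loc_two", "loc_three"])
        path = tmp_path / "dist.phy"
        d.to_phylip(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "3"
        vals = np.array(
            [[float(x) for x in ln[10:].split()] for ln in lines[1:]]
        )
        assert np.allclose(vals, d.values, atol=1e-6)


class TestGeographicDistances:
    def _meta(self, rows, system="lonlat"):
        return validate_metadata(
            pd.DataFrame(
                {
                    "locality": [r[0] for r in rows],
                    "species": "A",
                    "sympatry": "allopatric",
                    "lat": [r[1] for r in rows],
                    "lon": [r[2] for r in rows],
                    "coord_system": system,
                }
            )
        )

    def test_identical_coordinates_zero(self):
        meta = self._meta([("a", 31.0, -85.0), ("b", 31.0, -85.0)])
        assert geographic_distances(meta).values[0, 1] == 0.0

    def test_one_degree_longitude_at_equator(self):
        meta = self._meta([("a", 0.0, 0.0), ("b", 0.0, 1.0)])
        d = geographic_distances(meta).values[0, 1]
        assert d == pytest.approx(111.19, abs=0.01)

    def test_haversine_symmetric_and_metric(self, rng):
        lat = rng.uniform(25, 40, 20)
        lon = rng.uniform(-90, -75, 20)
        meta = self._meta(
            [(f"l{i:02d}", lat[i], lon[i]) for i in range(20)]
        )
        D = geographic_distances(meta).values
        assert np.allclose(D, D.T)
        for i, j, k in itertools.combinations(range(20), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_planar_coordinates(self):
        meta = self._meta([("a", 0.0, 0.0), ("b", 3.0, 4.0)], system="planar")
        assert geographic_distances(meta).values[0, 1] == pytest.approx(5.0)

    def test_bad_latitude_rejected(self):
        meta = self._meta([("a", 95.0, 0.0), ("b", 0.0, 0.0)])
        with pytest.raises(ValueError, match="lat"):
            geographic_distances(meta)


def _random_distance_matrix(rng, labels):
    n = len(labels)
    pts = rng.normal(size=(n, 3))
    D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return DistanceMatrix(labels, D)


class TestMantel:
    def test_perfect_correlation(self, rng):
        labels = [f"l{i}" for i in range(6)]
        d1 = _random_distance_matrix(rng, labels)
        d2 = DistanceMatrix(labels, 3.0 * d1.values)
        r, r2, p = mantel(d1, d2, n_perms=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_exact_enumeration_at_n_four(self, rng):
        """With 4 localities the permutation null has only 4! = 24 states;
        the sampled p must match the exhaustive value."""
        labels = list("abcd")
        d1 = _random_distance_matrix(rng, labels)
        d2 = _random_distance_matrix(rng, labels)
        iu = np.triu_indices(4, 1)
        x = d1.values[iu]
        r_obs = np.corrcoef(x, d2.values[iu])[0, 1]
        hits = total = 0
        for perm in itertools.permutations(range(4)):
            y = d2.values[np.ix_(perm, perm)][iu]
            if np.corrcoef(x, y)[0, 1] >= r_obs - 1e-12:
                hits += 1
            total += 1
        exact = hits / total
        _, _, p = mantel(d1, d2, n_perms=20_000, seed=11)
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(p - exact) < 3 * se + 2 / 20_001

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        labels = [f"l{i}" for i in range(8)]
        for _ in range(100):
            d1 = _random_distance_matrix(rng, labels)
            d2 = _random_distance_matrix(rng, labels)
            ps.append(mantel(d1, d2, n_perms=499, seed=rng.integers(2**31))[2])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_joint_relabeling_invariance(self, rng):
        labels = [f"l{i}" for i in range(7)]
        d1 = _random_distance_matrix(rng, labels)
        d2 = _random_distance_matrix(rng, labels)
        r, _, _ = mantel(d1, d2, n_perms=9, seed=0)
        perm = rng.permutation(7)
        relabel = lambda d: DistanceMatrix(
            labels, d.values[np.ix_(perm, perm)]
        )
        r2, _, _ = mantel(relabel(d1), relabel(d2), n_perms=9, seed=0)
        assert r2 == pytest.approx(r, abs=1e-12)

    def test_zero_variance_rejected(self):
        labels = list("abcd")
        d1 = DistanceMatrix(labels, np.ones((4, 4)) - np.eye(4))
        d2 = _random_distance_matrix(np.random.default_rng(0), labels)
        with pytest.raises(ValueError, match="variance"):
            mantel(d1, d2)


class TestIbdRandomization:
    def _setup(self, rng, n=10, noise=0.0):
        labels = [f"l{i}" for i in range(n)]
        xy = rng.uniform(0, 300, size=(n, 2))
        geo = DistanceMatrix(
            labels,
            np.linalg.norm(xy[:, None] - xy[None, :], axis=-1),
            "geographic_km",
        )
        fst_vals = 0.01 + 4e-4 * geo.values + rng.normal(0, noise, (n, n))
        fst_vals = (fst_vals + fst_vals.T) / 2
        np.fill_diagonal(fst_vals, 0.0)
        fst = DistanceMatrix(labels, fst_vals, "fst")
        sym = pd.Series([True] * (n // 2) + [False] * (n - n // 2), index=labels)
        return fst, geo, sym

    def test_zero_residuals_give_null_result(self, rng):
        fst, geo, sym = self._setup(rng, noise=0.0)
        res = ibd_residual_randomization(fst, geo, sym, n_reps=99, seed=1)
        assert res.sympatry_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_randomization == 1.0

    def test_statistic_invariant_to_constant_fst_shift(self, rng):
        fst, geo, sym = self._setup(rng, noise=0.003)
        res1 = ibd_residual_randomization(fst, geo, sym, n_reps=99, seed=5)
        shifted = DistanceMatrix(
            fst.labels,
            fst.values + 0.05 * (1 - np.eye(fst.n)),
            "fst",
        )
        res2 = ibd_residual_randomization(shifted, geo, sym, n_reps=99, seed=5)
        assert res2.sympatry_stat == pytest.approx(res1.sympatry_stat, abs=1e-12)
        assert res2.p_randomization == res1.p_randomization

    def test_planted_sympatric_excess_detected(self, rng):
        fst, geo, sym = self._setup(rng, noise=0.003)
        vals = fst.values.copy()
        symv = sym[fst.labels].to_numpy()
        iu = np.triu_indices(fst.n, 1)
        bump = 0.02
        for i, j in zip(*iu):
            if symv[i] or symv[j]:
                vals[i, j] += bump
                vals[j, i] += bump
        res = ibd_residual_randomization(
            DistanceMatrix(fst.labels, vals, "fst"), geo, sym,
            n_reps=999, seed=2,
        )
        assert res.p_randomization <= 0.05

    def test_single_class_rejected(self, rng):
        fst, geo, sym = self._setup(rng)
        with pytest.raises(ValueError):
            ibd_residual_randomization(
                fst, geo, pd.Series(True, index=fst.labels), n_reps=9
            )

    def test_mantel_outputs_propagate(self, rng):
        fst, geo, sym = self._setup(rng, noise=0.001)
        res = ibd_residual_randomization(
            fst, geo, sym, n_reps=99, seed=3, mantel_perms=499
        )
        assert res.r_squared > 0.5  # strong planted linear IBD
        assert res.p_mantel < 0.05
        assert -1 <= res.mantel_r <= 1
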