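"""Pairwise LD, background LD, decay curves, persistence of linkage phase."""

import numpy as np
import pandas as pd
import pytest

from curdpred import ld, simulate
from curdpred.genotypes import GenotypeMatrix

from conftest import toy_matrix


def haplotype_panel(joint_freqs, n, seed, pos=(100, 50_100)):
    """Genotypes built from phased haplotypes with known two-locus freqs.

    Returns the panel and the haplotype-counting r² truth.
    """
    rng = np.random.default_rng(seed)
    haps = rng.choice(4, size=2 * n, p=joint_freqs)  # AB, Ab, aB, ab
    a = np.isin(haps, [0, 1]).astype(float)
    b = np.isin(haps, [0, 2]).astype(float)
    ga, gb = a[0::2] + a[1::2], b[0::2] + b[1::2]
    f = np.array([np.mean(haps == k) for k in range(4)])
    p_a, p_b = f[0] + f[1], f[0] + f[2]
    D = f[0] - p_a * p_b
    r = D / np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    G = toy_matrix(np.column_stack([ga, gb]), pos=list(pos))
    return G, f, r


class TestPairwiseLD:
    def test_perfect_ld(self):
        g = np.array([0.0, 0, 1, 1, 2, 2] * 10)
        G = toy_matrix(np.column_stack([g, g]))
        row = ld.pairwise_ld(G, [(0, 1)]).table.iloc[0]
        assert row["r2"] == pytest.approx(1.0)
        assert row["r"] == pytest.approx(1.0)

    def test_equilibrium(self):
        """p_ab = p_a p_b gives r² = 0 (constructed from independent phased
        haplotypes with exact half frequencies)."""
        # haplotypes: all four combinations equally frequent
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        haps = np.tile(base, (25, 1))
        g = haps[0::2] + haps[1::2]
        G = toy_matrix(g)
        row = ld.pairwise_ld(G, [(0, 1)]).table.iloc[0]
        assert row["r2"] == pytest.approx(0.0, abs=1e-12)
        assert row["D"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_em_matches_phased_truth(self, seed):
        G, f_true, r_true = haplotype_panel([0.35, 0.15, 0.1, 0.4], 800, seed)
        row = ld.pairwise_ld(G, [(0, 1)]).table.iloc[0]
        assert row["p_ab"] == pytest.approx(f_true[0], abs=1e-3 + 0.03)
        assert row["r"] == pytest.approx(r_true, abs=0.05)
        assert row["r2"] == pytest.approx(row["r"] ** 2, abs=1e-12)

    def test_em_equals_counting_without_double_hets(self):
        """When no individual is heterozygous at both loci the EM solution is
        the direct haplotype count."""
        # haplotypes coded (alt@locus1, alt@locus2); pairs avoid (1,1) genotypes
        AB, Ab, aB, ab = (1, 1), (1, 0), (0, 1), (0, 0)
        pairs = [(AB, AB), (ab, ab), (AB, Ab), (Ab, ab), (aB, ab), (AB, aB), (Ab, Ab)]
        h1 = np.array([p[0] for p in pairs])
        h2 = np.array([p[1] for p in pairs])
        ga = (h1[:, 0] + h2[:, 0]).astype(float)
        gb = (h1[:, 1] + h2[:, 1]).astype(float)
        assert not np.any((ga == 1) & (gb == 1))
        f = ld._two_locus_em(ga, gb)
        haps = np.vstack([h1, h2])
        count = np.array(
            [
                np.mean((haps[:, 0] == 1) & (haps[:, 1] == 1)),
                np.mean((haps[:, 0] == 1) & (haps[:, 1] == 0)),
                np.mean((haps[:, 0] == 0) & (haps[:, 1] == 1)),
                np.mean((haps[:, 0] == 0) & (haps[:, 1] == 0)),
            ]
        )
        np.testing.assert_allclose(f, count, atol=1e-12)

    def test_monomorphic_errors(self):
        G = toy_matrix(np.column_stack([np.zeros(10), np.tile([0.0, 1], 5)]))
        with pytest.raises(ValueError, match="monomorphic|no jointly"):
            ld.pairwise_ld(G, [(0, 1)])

    def test_signed_consistency_property(self, structured_panel):
        _, G, _ = structured_panel
        rng = np.random.default_rng(3)
        pairs = [tuple(rng.choice(G.n_markers, 2, replace=False)) for _ in range(40)]
        tbl = ld.pairwise_ld(G, pairs).table
        np.testing.assert_allclose(tbl["r2"], tbl["r"] ** 2, atol=1e-12)
        assert np.all(np.abs(tbl["r"]) <= 1 + 1e-12)
        np.testing.assert_allclose(
            tbl["D"], tbl["p_ab"] - tbl["p_a"] * tbl["p_b"], atol=1e-12
        )


class TestBackgroundLD:
    def test_matches_exhaustive_oracle(self):
        """Sampled-pair percentile agrees with the exhaustive-pair percentile
        on a small panel."""
        cfg = simulate.SimConfig(
            n_individuals=174, n_chromosomes=3, markers_per_chromosome=30,
            ld_correlation=0.0, n_clusters=1, F=0.0, traits=(),
        )
        G, _ = simulate.simulate_population(cfg, seed=12)
        chroms = G.markers["chrom"].to_numpy()
        all_pairs = [
            (i, j)
            for i in range(G.n_markers)
            for j in range(i + 1, G.n_markers)
            if chroms[i] != chroms[j]
        ]
        r2 = ld.pairwise_ld(G, all_pairs).table["r2"]
        oracle = float(np.percentile(r2, 95))
        est = ld.background_ld(G, n_pairs=2400, seed=0)
        assert est == pytest.approx(oracle, abs=0.01)

    def test_duplicated_chromosome_gives_one(self):
        """A chromosome copied verbatim puts >5% of inter-chromosomal pairs
        in total LD, pinning the 95th percentile at 1."""
        rng = np.random.default_rng(1)
        block = rng.integers(0, 3, size=(50, 10)).astype(float)
        G = toy_matrix(
            np.column_stack([block, block]),
            chrom=["C1"] * 10 + ["C2"] * 10,
            pos=list(range(100, 1100, 100)) * 2,
        )
        assert ld.background_ld(G, n_pairs=600, seed=0) == pytest.approx(1.0)

    def test_single_chromosome_errors(self):
        G = toy_matrix(np.tile([0.0, 1, 2], (4, 1)))
        with pytest.raises(ValueError, match="two chromosomes"):
            ld.background_ld(G)

    def test_percentile_monotone(self, structured_panel):
        _, G, _ = structured_panel
        vals = [
            ld.background_ld(G, n_pairs=400, seed=5, percentile=q)
            for q in (50, 75, 95, 99)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestDecay:
    def test_recovers_generating_curve_crossing(self):
        """Fitting noiseless drift-expectation data recovers the intensity
        and the closed-form background crossing."""
        from scipy.optimize import brentq

        rho_true, n = 2e-5, 174
        rng = np.random.default_rng(0)
        d = np.sort(rng.integers(500, 500_000, size=400)).astype(float)
        r2 = ld.hill_weir_expected_r2(d, rho_true, n)
        background = 0.17
        # independent closed-form crossing of the generating curve
        oracle = brentq(
            lambda x: ld.hill_weir_expected_r2(x, rho_true, n) - background,
            1.0, 5e5,
        )
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(
            lambda dd, rho: ld.hill_weir_expected_r2(dd, rho, n), d, r2, p0=[1e-6]
        )
        fitted_cross = brentq(
            lambda x: ld.hill_weir_expected_r2(x, popt[0], n) - background, 1.0, 5e5
        )
        assert fitted_cross == pytest.approx(oracle, rel=1e-6)

    def test_decay_on_simulated_panel(self):
        cfg = simulate.SimConfig(
            n_individuals=150, n_chromosomes=2, markers_per_chromosome=60,
            chromosome_length_bp=2_000_000, ld_correlation=0.9,
            n_clusters=1, F=0.0, traits=(),
        )
        G, _ = simulate.simulate_population(cfg, seed=3)
        bg = ld.background_ld(G, n_pairs=500, seed=1)
        curve = ld.ld_decay(G, "C01", background=bg)
        d = np.linspace(0, 2_000_000, 200)
        vals = curve.expected_r2(d)
        assert np.all(np.diff(vals) <= 1e-12)  # non-increasing
        if curve.intersection_bp is not None:
            assert curve.expected_r2(curve.intersection_bp) == pytest.approx(
                bg, abs=1e-6
            )

    def test_flat_series_has_no_intersection(self):
        """If fitted LD never drops to the background level the crossing is
        flagged as absent."""
        g = np.array([0.0, 0, 1, 1, 2, 2] * 20)
        cols = [g] * 60  # perfect LD everywhere
        G = toy_matrix(np.column_stack(cols), pos=list(range(100, 100 + 600, 10)))
        curve = ld.ld_decay(G, "C1", background=0.2)
        assert curve.intersection_bp is None

    def test_too_few_pairs_errors(self):
        G = toy_matrix(np.tile([0.0, 1, 2, 1], (5, 1)))
        with pytest.raises(ValueError, match="50 intra"):
            ld.ld_decay(G, "C1", background=0.1)


@pytest.fixture(scope="module")
def ld_panel():
    cfg = simulate.SimConfig(
        n_individuals=200, n_chromosomes=2, markers_per_chromosome=120,
        ld_correlation=0.85, n_clusters=1, F=0.0, traits=(),
    )
    G, _ = simulate.simulate_population(cfg, seed=14)
    return G


class TestPhasePersistence:
    def test_identical_samples_give_unit_correlation(self, ld_panel):
        res = ld.phase_persistence(ld_panel, ld_panel, bin_size=50)
        assert res.overall == pytest.approx(1.0)
        assert np.allclose(res.per_bin["correlation"], 1.0)

    def test_allele_swap_flips_sign(self, ld_panel):
        """Recoding one locus swaps the sign of every adjacent r involving it
        when orientation is fixed by the shared map."""
        G = ld_panel
        cols = np.arange(G.n_markers)
        ra = ld._signed_r_adjacent(G, cols)
        j = 30
        d = G.dosages.copy()
        d[:, j] = 2.0 - d[:, j]
        Gs = GenotypeMatrix(list(G.ids), G.markers.copy(), d)
        rb = ld._signed_r_adjacent(Gs, cols)
        lefts_a, _, r_a = ra
        lefts_b, _, r_b = rb
        touching = np.isin(lefts_a, [j - 1, j])
        np.testing.assert_allclose(r_b[touching], -r_a[touching], atol=1e-9)
        np.testing.assert_allclose(r_b[~touching], r_a[~touching], atol=1e-9)

    def test_independent_panels_uncorrelated(self):
        cfg = simulate.SimConfig(
            n_individuals=150, n_chromosomes=2, markers_per_chromosome=150,
            ld_correlation=0.6, n_clusters=1, F=0.0, traits=(),
        )
        GA, _ = simulate.simulate_population(cfg, seed=21)
        GB0, _ = simulate.simulate_population(cfg, seed=22)
        # same map, independently generated genotype content
        GB = GenotypeMatrix(list(GA.ids), GA.markers.copy(), GB0.dosages)
        res = ld.phase_persistence(GA, GB, bin_size=50)
        assert abs(res.overall) < 0.15

    def test_mismatched_maps_error(self, ld_panel):
        other = toy_matrix(np.tile([0.0, 1, 2], (4, 1)))
        with pytest.raises(ValueError, match="marker map"):
            ld.phase_persistence(ld_panel, other)

    def test_single_bin_fallback_warns(self):
        g1 = np.tile([0.0, 1, 2, 1, 0, 2], 5)
        g2 = np.tile([0.0, 1, 1, 2, 0, 2], 5)
        g3 = np.tile([2.0, 1, 0, 1, 2, 0], 5)
        G = toy_matrix(np.column_stack([g1, g2, g3]))
        with pytest.warns(UserWarning, match="single bin"):
            ld.phase_persistence(G, G, bin_size=50)
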