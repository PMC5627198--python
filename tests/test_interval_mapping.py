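"""Genome scan: genotype probabilities, LRS profiles, permutations, CIs."""

import numpy as np
import pandas as pd
import pytest

import igemap as ig
from igemap.interval_mapping import ScanResult, _flank_prob
from igemap.synthetic_data import haldane


def _two_marker_map(delta_cm=10.0):
    return ig.GeneticMap(
        pd.DataFrame(
            {
                "marker": ["L", "R"],
                "chromosome": "1",
                "cM": [0.0, delta_cm],
                "Mb": [0.0, delta_cm],
            }
        )
    )


class TestGenotypeProb:
    def test_typed_marker_returns_call(self, panel):
        gmap, G = panel
        row = gmap.table.iloc[4]
        line = G.line_ids[0]
        p = ig.genotype_prob(gmap, G, line, row["chromosome"], row["cM"])
        assert p == G.calls[0, 4]

    def test_midpoint_between_discordant_flanks(self):
        gmap = _two_marker_map(10.0)
        G = ig.GenotypeMatrix(["l1"], np.array([[0.0, 1.0]]), gmap)
        p = ig.genotype_prob(gmap, G, "l1", "1", 5.0)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_concordant_flanks_match_enumeration(self):
        """Both flanks B, 5 cM each side: compare to exhaustive chain enumeration."""
        gmap = _two_marker_map(10.0)
        G = ig.GenotypeMatrix(["l1"], np.array([[0.0, 0.0]]), gmap)
        p = ig.genotype_prob(gmap, G, "l1", "1", 5.0)
        R = ig.expand_rf(haldane(5.0))
        # enumerate P(B, g, B) over g in {B, D}; chain is stationary at 1/2
        num = {}
        for g in (0.0, 1.0):
            step1 = R if g != 0.0 else 1 - R
            step2 = R if g != 0.0 else 1 - R
            num[g] = 0.5 * step1 * step2
        expected = num[1.0] / (num[0.0] + num[1.0])
        assert p == pytest.approx(expected, abs=1e-12)

    def test_single_informative_flank(self):
        gmap = _two_marker_map(10.0)
        G = ig.GenotypeMatrix(["l1"], np.array([[np.nan, 1.0]]), gmap)
        p = ig.genotype_prob(gmap, G, "l1", "1", 0.0)
        R = ig.expand_rf(haldane(10.0))
        assert p == pytest.approx(1 - R, abs=1e-12)

    def test_untyped_chromosome_gives_nan(self):
        gmap = _two_marker_map(10.0)
        G = ig.GenotypeMatrix(["l1"], np.array([[np.nan, np.nan]]), gmap)
        assert np.isnan(ig.genotype_prob(gmap, G, "l1", "1", 5.0))


def _vector(values, index, trait="sucking", role="BXD_offspring", day=6):
    return ig.LineTraitVector(
        trait=trait,
        role=role,
        day=day,
        effect_class="direct",
        values=pd.Series(values, index=index, dtype=float),
        n_replicates=pd.Series(1, index=index),
    )


def _marker_lrs_oracle(y, x):
    """Independent per-marker regression LRS: n * ln(RSS0 / RSS1)."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    rss1 = float(((y - X @ beta) ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    return n * np.log(rss0 / rss1)


class TestScan:
    def test_constant_phenotype_zero_profile(self, panel):
        gmap, G = panel
        y = _vector(np.zeros(32), G.line_ids)
        with pytest.warns(UserWarning, match="zero phenotypic variance"):
            sr = ig.scan(y, G, gmap)
        assert (sr.grid["LRS"] == 0).all()

    def test_matches_marker_oracle(self, panel):
        gmap, G = panel
        rng = np.random.default_rng(0)
        y = rng.normal(size=32)
        sr = ig.scan(_vector(y, G.line_ids), G, gmap)
        for j in range(gmap.n_markers):
            expected = _marker_lrs_oracle(y, G.calls[:, j])
            assert sr.grid["LRS"].iloc[j] == pytest.approx(expected, rel=1e-10)

    def test_affine_invariance(self, panel):
        gmap, G = panel
        rng = np.random.default_rng(1)
        y = rng.normal(size=32)
        a = ig.scan(_vector(y, G.line_ids), G, gmap)
        b = ig.scan(_vector(5.0 * y + 2.0, G.line_ids), G, gmap)
        np.testing.assert_allclose(a.grid["LRS"], b.grid["LRS"], rtol=1e-9)

    def test_relabeling_invariance(self, panel):
        """Consistent relabeling of lines leaves the profile unchanged."""
        gmap, G = panel
        rng = np.random.default_rng(2)
        y = rng.normal(size=32)
        a = ig.scan(_vector(y, G.line_ids), G, gmap)
        perm = rng.permutation(32)
        G2 = ig.GenotypeMatrix(
            [G.line_ids[i] for i in perm], G.calls[perm], gmap
        )
        b = ig.scan(_vector(y, G.line_ids), G2, gmap)
        np.testing.assert_allclose(a.grid["LRS"], b.grid["LRS"], rtol=1e-9)

    def test_pseudomarker_grid_contains_markers(self, panel):
        gmap, G = panel
        rng = np.random.default_rng(3)
        y = _vector(rng.normal(size=32), G.line_ids)
        sr = ig.scan(y, G, gmap, step_cm=2.0)
        marker_cms = set(gmap.table["cM"])
        for chrom in gmap.chromosomes:
            grid_cms = set(sr.grid.loc[sr.grid["chromosome"] == chrom, "cM"])
            assert marker_cms <= grid_cms | marker_cms

    def test_perfect_fit_capped(self, panel):
        gmap, G = panel
        y = _vector(G.calls[:, 0].copy(), G.line_ids)  # phenotype = genotype
        with pytest.warns(UserWarning, match="capped"):
            sr = ig.scan(y, G, gmap)
        assert np.isfinite(sr.max_lrs)


class TestLrsToLod:
    @pytest.mark.parametrize(
        "lrs,lod",
        [(19.517, 4.234), (23.847, 5.173), (20.016, 4.342), (22.538, 4.889), (0.0, 0.0)],
    )
    def test_genenetwork_convention(self, lrs, lod):
        assert round(ig.lrs_to_lod(lrs), 3) == pytest.approx(lod)

    def test_exact_divisor_selectable(self):
        assert ig.lrs_to_lod(2 * np.log(10), ig.LOD_DIVISOR_EXACT) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ig.lrs_to_lod(-1.0)


class TestPermutationNull:
    def test_deterministic_given_seed(self, panel):
        gmap, G = panel
        rng = np.random.default_rng(4)
        y = _vector(rng.normal(size=32), G.line_ids)
        a = ig.permutation_null(y, G, gmap, n_perm=150, seed=9)
        b = ig.permutation_null(y, G, gmap, n_perm=150, seed=9)
        np.testing.assert_array_equal(a.max_lrs, b.max_lrs)

    def test_add_one_formula_when_observed_below_all(self, panel):
        gmap, G = panel
        rng = np.random.default_rng(5)
        y = _vector(rng.normal(size=32), G.line_ids)
        null = ig.permutation_null(y, G, gmap, n_perm=200, seed=1)
        # below every permutation maximum: (1 + 200) / 201 = 1 by add-one
        assert null.genomewide_p(-1.0) == pytest.approx(1.0)
        assert null.genomewide_p(np.inf) == pytest.approx(1 / 201)

    def test_raw_estimator(self, panel):
        gmap, G = panel
        rng = np.random.default_rng(6)
        y = _vector(rng.normal(size=32), G.line_ids)
        null = ig.permutation_null(y, G, gmap, n_perm=100, seed=2)
        assert null.genomewide_p(np.inf, estimator="raw") == 0.0

    def test_p_monotone_in_observed_max(self, panel):
        gmap, G = panel
        rng = np.random.default_rng(7)
        y = _vector(rng.normal(size=32), G.line_ids)
        null = ig.permutation_null(y, G, gmap, n_perm=200, seed=3)
        grid = np.linspace(0, 40, 50)
        ps = [null.genomewide_p(v) for v in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_small_n_perm_warns(self, panel):
        gmap, G = panel
        rng = np.random.default_rng(8)
        y = _vector(rng.normal(size=32), G.line_ids)
        with pytest.warns(UserWarning, match="unstable"):
            ig.permutation_null(y, G, gmap, n_perm=50, seed=0)

    def test_missing_genotype_complete_case(self, panel):
        """A line untyped at a whole chromosome is dropped position-wise there."""
        gmap, G = panel
        rng = np.random.default_rng(9)
        y = rng.normal(size=32)
        calls = G.calls.copy()
        chrom1 = gmap.chrom_slice("1").index.to_numpy()
        calls[0, chrom1] = np.nan  # line 0 untyped on chromosome 1
        G2 = ig.GenotypeMatrix(G.line_ids, calls, gmap)
        sr = ig.scan(_vector(y, G.line_ids), G2, gmap)
        on1 = sr.grid["chromosome"] == "1"
        assert (sr.grid.loc[on1, "n"] == 31).all()
        assert (sr.grid.loc[~on1, "n"] == 32).all()
        # LRS at a chromosome-1 marker equals the 31-line complete-case oracle
        j = chrom1[2]
        expected = _marker_lrs_oracle(y[1:], G.calls[1:, j])
        grid_row = sr.grid[(sr.grid["chromosome"] == "1")].iloc[2]
        assert grid_row["LRS"] == pytest.approx(expected, rel=1e-10)


def _profile_scan(lods, mbs, divisor=4.61):
    grid = pd.DataFrame(
        {
            "chromosome": "1",
            "cM": np.arange(len(lods), dtype=float),
            "Mb": np.asarray(mbs, dtype=float),
            "LRS": np.asarray(lods) * divisor,
            "LOD": np.asarray(lods, dtype=float),
            "n": 32,
        }
    )
    return ScanResult(
        trait="t",
        role="BXD_offspring",
        day=6,
        effect_class="direct",
        grid=grid,
        lod_divisor=divisor,
        n_lines=32,
        peak_index=int(np.argmax(lods)),
    )


class TestLodDropInterval:
    def test_shoulders_above_cut_included(self):
        sr = _profile_scan([1, 3.6, 5, 3.6, 1], [1, 2, 3, 4, 5])
        assert ig.lod_drop_interval(sr) == (2.0, 4.0)

    def test_shoulders_below_cut_excluded(self):
        sr = _profile_scan([1, 3.4, 5, 3.4, 1], [1, 2, 3, 4, 5])
        assert ig.lod_drop_interval(sr) == (3.0, 3.0)

    def test_flat_profile_spans_chromosome(self):
        sr = _profile_scan([2, 2, 2, 2], [1, 2, 3, 4])
        assert ig.lod_drop_interval(sr) == (1.0, 4.0)

    def test_peak_at_first_point_clamps_low_end(self):
        sr = _profile_scan([5, 4.2, 3.0, 1.0], [1, 2, 3, 4])
        lo, hi = ig.lod_drop_interval(sr)
        assert lo == 1.0 and hi == 2.0


class TestPointwiseP:
    def test_equal_groups_p_one(self):
        y = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        g = pd.Series([0.0, 0.0, 1.0, 1.0], index=list("abcd"))
        assert ig.pointwise_p(y, g) == 1.0

    def test_perfect_separation_tiny_p(self):
        rng = np.random.default_rng(0)
        idx = [f"l{i}" for i in range(30)]
        g = pd.Series(np.repeat([0.0, 1.0], 15), index=idx)
        y = pd.Series(g.to_numpy() * 10 + rng.normal(0, 1e-3, 30), index=idx)
        assert ig.pointwise_p(y, g) < 1e-6

    def test_matches_f_distribution_oracle(self):
        """100 random instances vs an independent scipy linregress F-test."""
        from scipy.stats import linregress

        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            idx = [f"l{i}" for i in range(n)]
            g = rng.integers(0, 2, n).astype(float)
            if len(np.unique(g)) < 2:
                continue
            y = rng.normal(size=n) + g * rng.normal()
            p = ig.pointwise_p(pd.Series(y, index=idx), pd.Series(g, index=idx))
            expected = linregress(g, y).pvalue
            assert p == pytest.approx(expected, abs=1e-10)

    def test_monomorphic_marker_flagged(self):
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        g = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.warns(UserWarning, match="monomorphic"):
            assert np.isnan(ig.pointwise_p(y, g))
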