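import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucmorph import synthgen
from nucmorph.qtlmap import (CIMConfig, QTLCall, call_qtl, cim_scan, colocate,
                             genotype_probs, permutation_threshold,
                             select_cofactors)
from nucmorph.synthgen import (GeneticMap, QTLSpecItem, ril_recomb_fraction,
                               simulate_ril_genotypes, simulate_trait_values)


def _two_marker_map(distance):
    return GeneticMap(pd.DataFrame({"marker": ["m1", "m2"], "chrom": [1, 1],
                                    "pos_cM": [0.0, distance]}))


class TestGenotypeProbs:
    def test_indicator_at_observed_marker(self, five_chrom_map, ril_population):
        grid = genotype_probs(five_chrom_map, ril_population, 1.0)
        for marker in ("C1M1", "C3M11", "C5M21"):
            chrom, pos = five_chrom_map.position_of(marker)
            j = np.flatnonzero((grid.chrom == chrom) & (grid.pos == pos))[0]
            expect = (ril_population[marker] == "A").astype(float).to_numpy()
            assert np.array_equal(grid.prob[:, j], expect)

    def test_midpoint_of_AB_interval_is_half(self):
        gmap = _two_marker_map(20.0)
        geno = pd.DataFrame({"m1": ["A"], "m2": ["B"]}, index=["L1"])
        grid = genotype_probs(gmap, geno, 10.0)
        j = np.flatnonzero(grid.pos == 10.0)[0]
        assert grid.prob[0, j] == pytest.approx(0.5)

    def test_midpoint_of_AA_interval_enumeration_oracle(self):
        # oracle: enumerate the middle genotype of the two-segment chain
        gmap = _two_marker_map(20.0)
        geno = pd.DataFrame({"m1": ["A"], "m2": ["A"]}, index=["L1"])
        grid = genotype_probs(gmap, geno, 10.0)
        R = float(ril_recomb_fraction(10.0))
        p_oracle = (1 - R) ** 2 / ((1 - R) ** 2 + R ** 2)
        j = np.flatnonzero(grid.pos == 10.0)[0]
        assert grid.prob[0, j] == pytest.approx(p_oracle, abs=1e-12)

    def test_missing_chromosome_gives_half_with_warning(self, five_chrom_map):
        geno = simulate_ril_genotypes(five_chrom_map, 3, seed=0)
        geno.loc["RIL001", five_chrom_map.chrom_markers(2)] = np.nan
        with pytest.warns(UserWarning, match="no genotype"):
            grid = genotype_probs(five_chrom_map, geno, 5.0)
        sel = grid.chrom == 2
        assert np.allclose(grid.prob[0, sel], 0.5)

    def test_extrapolation_beyond_terminal_marker(self):
        gmap = _two_marker_map(20.0)
        geno = pd.DataFrame({"m1": ["B"], "m2": [np.nan]}, index=["L1"])
        grid = genotype_probs(gmap, geno, 20.0)
        j = np.flatnonzero(grid.pos == 20.0)[0]
        assert grid.prob[0, j] == pytest.approx(float(ril_recomb_fraction(20.0)))


def _independent_stepwise(X, y, p_in=0.05, p_out=0.05, max_cof=None):
    """Brute-force stepwise oracle using statsmodels-style full refits."""
    n, m = X.shape
    max_cof = max_cof or int(np.floor(np.sqrt(n)))
    inc = []
    while len(inc) < max_cof:
        best_p, best_j = np.inf, None
        for j in range(m):
            if j in inc:
                continue
            Z = np.column_stack([np.ones(n)] + [X[:, k] for k in inc + [j]])
            if np.linalg.matrix_rank(Z) < Z.shape[1] or n - Z.shape[1] <= 0:
                continue
            beta, res, *_ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ beta
            df = n - Z.shape[1]
            s2 = resid @ resid / df
            cov = s2 * np.linalg.inv(Z.T @ Z)
            t = beta[-1] / np.sqrt(cov[-1, -1])
            p = 2 * stats.t.sf(abs(t), df)
            if p < best_p - 1e-15:
                best_p, best_j = p, j
        if best_j is None or best_p >= p_in:
            break
        inc.append(best_j)
        while len(inc) > 1:
            Z = np.column_stack([np.ones(n)] + [X[:, k] for k in inc])
            beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ beta
            df = n - Z.shape[1]
            s2 = resid @ resid / df
            cov = s2 * np.linalg.inv(Z.T @ Z)
            pv = 2 * stats.t.sf(np.abs(beta[1:] / np.sqrt(np.diag(cov)[1:])), df)
            worst = int(np.argmax(pv))
            if pv[worst] <= p_out:
                break
            del inc[worst]
    return inc


class TestSelectCofactors:
    def test_constant_phenotype_empty(self, prob_grid):
        assert select_cofactors(prob_grid, np.ones(46)) == []

    def test_matches_independent_stepwise_oracle(self, prob_grid):
        rng = np.random.default_rng(9)
        name = prob_grid.marker_names
        for _ in range(5):
            y = rng.normal(size=46)
            ours = select_cofactors(prob_grid, y)
            oracle = _independent_stepwise(prob_grid.marker_scores, y)
            assert ours == [name[j] for j in oracle]

    def test_planted_qtl_marker_recovered(self, five_chrom_map):
        hits = 0
        for seed in range(50):
            geno = simulate_ril_genotypes(five_chrom_map, 100, seed=seed)
            tbl, _ = simulate_trait_values(geno, five_chrom_map,
                                           [QTLSpecItem(4, 50.0, 1.0)], 1.0,
                                           0.0, 1, 1, seed=seed + 999)
            y = tbl.groupby("line_id")["trait"].mean().loc[geno.index]
            grid = genotype_probs(five_chrom_map, geno, 5.0)
            cof = select_cofactors(grid, y)
            ok = any(five_chrom_map.position_of(c)[0] == 4
                     and abs(five_chrom_map.position_of(c)[1] - 50.0) <= 10.0
                     for c in cof)
            hits += ok
        assert hits >= 45  # >=90%

    def test_null_selection_small_and_capped(self, five_chrom_map):
        geno = simulate_ril_genotypes(five_chrom_map, 100, seed=1)
        grid = genotype_probs(five_chrom_map, geno, 5.0)
        rng = np.random.default_rng(10)
        counts = [len(select_cofactors(grid, rng.normal(size=100)))
                  for _ in range(50)]
        assert max(counts) <= 10  # floor(sqrt(100)) cap
        assert np.median(counts) <= 5  # spurious pickup stays small


class TestCIMScan:
    def test_single_marker_closed_form_oracle(self, five_chrom_map, ril_population):
        grid = genotype_probs(five_chrom_map, ril_population, 5.0)
        rng = np.random.default_rng(11)
        y = rng.normal(size=46)
        prof = cim_scan(grid, y, [], CIMConfig(step_cM=5.0))
        n = 46
        rss0 = float(((y - y.mean()) ** 2).sum())
        for marker in ("C2M5", "C4M12"):
            chrom, pos = five_chrom_map.position_of(marker)
            x = np.where(ril_population[marker] == "A", 1.0, -1.0)
            X = np.column_stack([np.ones(n), x])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = float(((y - X @ beta) ** 2).sum())
            lod_oracle = (n / 2) * np.log10(rss0 / rss1)
            j = np.flatnonzero((grid.chrom == chrom) & (grid.pos == pos))[0]
            assert prof.lod[j] == pytest.approx(lod_oracle, abs=1e-8)
            assert prof.add[j] == pytest.approx(beta[1], abs=1e-8)

    def test_affine_invariance_of_lod(self, prob_grid):
        rng = np.random.default_rng(12)
        y = rng.normal(size=46)
        p1 = cim_scan(prob_grid, y, [])
        p2 = cim_scan(prob_grid, 5.0 * y - 7.0, [])
        assert np.allclose(p1.lod, p2.lod, atol=1e-9)

    def test_planted_effect_recovered_within_2se(self, five_chrom_map):
        a, sigma = 1.0, 1.0
        geno = simulate_ril_genotypes(five_chrom_map, 200, seed=13)
        tbl, _ = simulate_trait_values(geno, five_chrom_map,
                                       [QTLSpecItem(2, 50.0, a)], sigma, 0.0,
                                       1, 1, seed=14)
        y = tbl.groupby("line_id")["trait"].mean().loc[geno.index]
        grid = genotype_probs(five_chrom_map, geno, 1.0)
        prof = cim_scan(grid, y, [])
        j = np.flatnonzero((grid.chrom == 2) & (grid.pos == 50.0))[0]
        se = sigma / np.sqrt(200)
        assert abs(prof.add[j] - a) <= 2 * se

    def test_cofactor_window_exclusion_near_cofactor(self, five_chrom_map,
                                                     ril_population):
        grid = genotype_probs(five_chrom_map, ril_population, 5.0)
        rng = np.random.default_rng(15)
        y = rng.normal(size=46)
        cof = ["C1M11"]  # chr1 @ 50 cM
        prof = cim_scan(grid, y, cof, CIMConfig(step_cM=5.0))
        prof0 = cim_scan(grid, y, [], CIMConfig(step_cM=5.0))
        near = (grid.chrom == 1) & (np.abs(grid.pos - 50.0) <= 10.0)
        # within the window the cofactor is inactive: identical to no-cofactor scan
        assert np.allclose(prof.lod[near], prof0.lod[near])
        far = (grid.chrom == 1) & (np.abs(grid.pos - 50.0) > 10.0)
        assert not np.allclose(prof.lod[far], prof0.lod[far])


class TestPermutationThreshold:
    def test_constant_phenotype_threshold_zero(self, prob_grid):
        cfg = CIMConfig(n_permutations=25, seed=1)
        assert permutation_threshold(prob_grid, np.full(46, 3.0), cfg) == 0.0

    def test_deterministic_under_seed(self, prob_grid):
        rng = np.random.default_rng(16)
        y = rng.normal(size=46)
        cfg = CIMConfig(n_permutations=30, seed=99)
        t1 = permutation_threshold(prob_grid, y, cfg)
        t2 = permutation_threshold(prob_grid, y, cfg)
        assert t1 == t2

    def test_too_few_permutations_rejected(self, prob_grid):
        with pytest.raises(ValueError):
            permutation_threshold(prob_grid, np.zeros(46),
                                  CIMConfig(n_permutations=10))

    def test_fast_mode_runs(self, prob_grid):
        rng = np.random.default_rng(17)
        y = rng.normal(size=46)
        cfg = CIMConfig(n_permutations=30, seed=5)
        thr = permutation_threshold(prob_grid, y, cfg, reselect_cofactors=False)
        assert thr > 0


class TestCallAndColocate:
    def _profile(self, lods, chrom=2, start=160):
        n = len(lods)
        from nucmorph.qtlmap import LODProfile
        return LODProfile(chrom=np.array([chrom] * n, dtype=object),
                          pos=np.arange(start, start + n, dtype=float),
                          lod=np.asarray(lods, dtype=float),
                          add=np.zeros(n), r2=np.zeros(n))

    def test_all_below_threshold_empty(self):
        assert call_qtl(self._profile([1, 2, 1.5]), 3.0) == []

    def test_single_run_start_top_end(self):
        # run at 164-166 peaking at 165
        prof = self._profile([1, 1, 1, 1, 3.2, 4.0, 3.5, 1, 1], start=160)
        calls = call_qtl(prof, 3.0)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.top, c.end) == (164.0, 165.0, 166.0)
        assert c.lod == 4.0

    def test_two_runs_split_by_valley(self):
        prof = self._profile([4, 4, 1, 1, 4, 4])
        assert len(call_qtl(prof, 3.0)) == 2

    def test_runs_do_not_merge_across_chromosomes(self):
        from nucmorph.qtlmap import LODProfile
        prof = LODProfile(chrom=np.array([1, 1, 2, 2], dtype=object),
                          pos=np.array([99.0, 100.0, 0.0, 1.0]),
                          lod=np.array([4.0, 4.0, 4.0, 4.0]),
                          add=np.zeros(4), r2=np.zeros(4))
        assert len(call_qtl(prof, 3.0)) == 2

    def test_colocate_touching_intervals(self):
        a = QTLCall(None, 2, 158.0, 164.0, 161.0, 4.9, 0.01, 15.7)
        b = QTLCall(None, 2, 164.0, 166.0, 165.0, 3.0, -2.2, 11.6)
        hit, shared = colocate(a, b)
        assert hit and shared == (164.0, 164.0)

    def test_colocate_different_chromosomes(self):
        a = QTLCall(None, 2, 158.0, 164.0, 161.0, 4.9, 0.01, 15.7)
        b = QTLCall(None, 4, 158.0, 164.0, 161.0, 3.0, -2.2, 11.6)
        assert colocate(a, b) == (False, None)

    def test_colocate_identical_intervals(self):
        a = QTLCall(None, 1, 10.0, 20.0, 15.0, 4.0, 1.0, 10.0)
        hit, shared = colocate(a, a)
        assert hit and shared == (10.0, 20.0)

    def test_colocate_different_maps_rejected(self):
        a = QTLCall(None, 1, 10.0, 20.0, 15.0, 4.0, 1.0, 10.0, map_name="m1")
        b = QTLCall(None, 1, 12.0, 22.0, 15.0, 4.0, 1.0, 10.0, map_name="m2")
        with pytest.raises(ValueError):
            colocate(a, b)
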