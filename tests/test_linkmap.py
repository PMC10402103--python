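import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from piedmap import linkmap, simdata
from piedmap.cross import GeneticMap, MISSING, MarkerGenotypes, haldane_cM
from piedmap.linkmap import (
    _pair_loglik,
    collapse_duplicates,
    drop_one_marker_eval,
    error_lod_clean,
    error_lod_scores,
    estimate_rf,
    form_groups,
    genotyping_rate_filter,
    order_and_space,
    segregation_filter,
)
from piedmap.simdata import CrossSpec


def _mk(calls, scaffolds=None, positions=None, chrom_class=None):
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[0]
    meta = pd.DataFrame(
        {
            "scaffold": scaffolds or [f"s{i}" for i in range(m)],
            "pos": positions or list(range(1, m + 1)),
            "chrom_class": chrom_class or ["autosomal"] * m,
        },
        index=[f"m{i}" for i in range(m)],
    )
    return MarkerGenotypes(meta, [f"i{j}" for j in range(calls.shape[1])], calls)


class TestSegregationFilter:
    def test_perfect_ratio_retained(self):
        calls = np.array([[0] * 25 + [1] * 50 + [2] * 25])
        g, report = segregation_filter(_mk(calls))
        assert g.n_markers == 1
        assert report.empty

    def test_extreme_distortion_dropped(self):
        # all-AA marker among many clean ones: X^2 = 300 for n=100
        counts = np.array([100, 0, 0])
        exp = 100 * np.array([0.25, 0.5, 0.25])
        x2 = ((counts - exp) ** 2 / exp).sum()
        assert x2 == pytest.approx(300.0)
        assert chi2.sf(x2, 2) < 1e-5 / 1000  # survives M=1000 Bonferroni
        distorted = [0] * 100
        clean = [0] * 25 + [1] * 50 + [2] * 25
        g, report = segregation_filter(_mk([distorted, clean]))
        assert list(g.markers.index) == ["m1"]
        assert report["reason"].tolist() == ["distorted"]

    def test_z_linked_never_tested(self):
        distorted = [0] * 100
        g, _ = segregation_filter(_mk([distorted], chrom_class=["Z-linked"]))
        assert g.n_markers == 1


class TestCollapseDuplicates:
    def test_identical_pair_collapsed_to_lowest_position(self):
        row = [0, 1, 2, 1] * 5
        g, mapping = collapse_duplicates(
            _mk([row, row], scaffolds=["s1", "s1"], positions=[500, 100])
        )
        assert list(g.markers.index) == ["m1"]  # lower bp wins
        assert mapping == {"m0": "m1"}

    def test_near_identical_with_missing_kept(self):
        a = [0, 1, 2, 1]
        b = [0, 1, 2, MISSING]
        g, mapping = collapse_duplicates(_mk([a, b]))
        assert g.n_markers == 2 and not mapping

    def test_k_copies_keep_one(self):
        row = [0, 1, 2, 0, 1]
        g, mapping = collapse_duplicates(_mk([row] * 4))
        assert g.n_markers == 1 and len(mapping) == 3


class TestRateFilter:
    def _with_rate(self, rate, n=100):
        row = np.ones(n, dtype=np.int8)
        row[: int(round((1 - rate) * n))] = MISSING
        return row

    def test_low_rate_removed_in_pass_one(self):
        g = genotyping_rate_filter(_mk([self._with_rate(0.49), self._with_rate(0.9)]))
        assert list(g.markers.index) == ["m1"]

    def test_pass_two_only_on_large_scaffolds(self):
        # 10-marker scaffold: 60% marker survives
        rows = [self._with_rate(0.60)] + [self._with_rate(0.9)] * 9
        g = genotyping_rate_filter(_mk(rows, scaffolds=["sc"] * 10))
        assert g.n_markers == 10
        # 60-marker scaffold: 60% marker removed in pass two
        rows = [self._with_rate(0.60)] + [self._with_rate(0.9)] * 59
        g = genotyping_rate_filter(
            _mk(rows, scaffolds=["sc"] * 60, positions=list(range(1, 61)))
        )
        assert g.n_markers == 59
        assert "m0" not in g.markers.index


class TestEstimateRF:
    def test_identical_markers_fully_linked(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 100).astype(np.int8)
        pl = estimate_rf(a, a)
        assert pl.r_hat == 0.0
        assert pl.lod_linkage > 0

    def test_independent_markers_near_half(self):
        spec = CrossSpec(10_000, [(2, 1e6)], seed=2)  # effectively unlinked
        truth, _, _ = simdata.sim_f2_cross(spec)
        pl = estimate_rf(truth.calls[0], truth.calls[1])
        assert abs(pl.r_hat - 0.5) < 0.02
        assert pl.lod_linkage < 1.0

    def test_parameter_recovery_at_r010(self):
        errs = []
        d = float(haldane_cM(0.10))
        for rep in range(50):
            truth, _, _ = simdata.sim_f2_cross(CrossSpec(200, [(2, d)], seed=100 + rep))
            errs.append(abs(estimate_rf(truth.calls[0], truth.calls[1]).r_hat - 0.10))
        assert np.mean(errs) < 0.02

    def test_matches_likelihood_grid_oracle(self):
        grid = np.arange(0.0, 0.5 + 1e-12, 1e-4)
        for rep in range(5):
            truth, _, _ = simdata.sim_f2_cross(CrossSpec(80, [(2, 25.0)], seed=rep))
            a, b = truth.calls[0], truth.calls[1]
            counts = np.zeros((3, 3))
            np.add.at(counts, (a.astype(int), b.astype(int)), 1.0)
            lls = np.array([_pair_loglik(counts, r) for r in grid])
            i = int(np.argmax(lls))
            got = estimate_rf(a, b)
            assert abs(got.r_hat - grid[i]) < 1e-3
            grid_lod = (lls[i] - _pair_loglik(counts, 0.5)) / np.log(10)
            assert abs(got.lod_linkage - grid_lod) < 0.01

    def test_monomorphic_flagged(self):
        a = np.zeros(50, dtype=np.int8)
        b = np.array([0, 1, 2] * 16 + [0, 1], dtype=np.int8)
        pl = estimate_rf(a, b)
        assert pl.flag == "monomorphic" and np.isnan(pl.r_hat)


class TestFormGroups:
    def test_transitive_chain_joined(self):
        pairs = pd.DataFrame(
            {
                "marker_a": ["A", "B", "A"],
                "marker_b": ["B", "C", "C"],
                "r_hat": [0.05, 0.05, 0.4],
                "lod_linkage": [10.0, 10.0, 10.0],
            }
        )
        groups, singles = form_groups(pairs, ["A", "B", "C"])
        assert groups == [["A", "B", "C"]] and not singles

    def test_both_conditions_required(self):
        pairs = pd.DataFrame(
            {"marker_a": ["A"], "marker_b": ["B"], "r_hat": [0.10], "lod_linkage": [3.0]}
        )
        groups, singles = form_groups(pairs, ["A", "B"])
        assert not groups and set(singles) == {"A", "B"}

    def test_two_chromosomes_recovered(self, small_cross):
        truth, _, _ = small_cross
        sub = truth.subset(truth.markers.index[::2])  # thin for speed
        pairs = linkmap.pairwise_linkage(sub)
        groups, singles = form_groups(pairs, list(sub.markers.index))
        assert len(groups) == 2 and not singles
        scaffolds = [{sub.markers.loc[m, "scaffold"] for m in grp} for grp in groups]
        assert all(len(s) == 1 for s in scaffolds)


class TestOrderAndSpace:
    def test_single_scaffold_bp_order(self, small_cross):
        truth, _, _ = small_cross
        members = [m for m in truth.markers.index if truth.markers.loc[m, "scaffold"] == "scf1"]
        frag, capped = order_and_space(truth, members)
        pos = frag["pos"].tolist()
        assert pos == sorted(pos) or pos == sorted(pos, reverse=True)
        assert not capped

    def test_zero_recombination_zero_spacing(self):
        row = np.array([0, 1, 2, 1, 0, 2] * 20, dtype=np.int8)
        g = _mk([row, row], scaffolds=["s", "s"], positions=[1, 100])
        frag, _ = order_and_space(g, ["m0", "m1"])
        assert frag["cM"].tolist() == [0.0, 0.0]

    def test_haldane_spacing_closed_form(self):
        assert float(haldane_cM(0.15)) == pytest.approx(-50 * np.log(0.7), abs=1e-9)
        assert float(haldane_cM(0.15)) == pytest.approx(17.83, abs=0.01)

    def test_r_half_capped_and_flagged(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 400).astype(np.int8)
        b = rng.permutation(a)
        g = _mk([a, b], scaffolds=["s1", "s2"], positions=[1, 1])
        frag, capped = order_and_space(g, ["m0", "m1"], max_spacing_cM=50.0)
        if capped:  # independent markers usually hit the cap
            assert frag["cM"].max() <= 50.0


class TestErrorLod:
    def test_isolated_marker_nothing_removable(self):
        rng = np.random.default_rng(4)
        row = rng.integers(0, 3, 100).astype(np.int8)
        g = _mk([row], scaffolds=["s"], positions=[1])
        gmap = GeneticMap(pd.DataFrame(
            {"group": ["LG1"], "marker_id": ["m0"], "scaffold": ["s"],
             "pos": [1], "cM": [0.0]}))
        cleaned, removed = error_lod_clean(g, gmap)
        assert removed.empty
        assert (cleaned.calls == g.calls).all()

    def test_double_recombinant_flagged_and_matches_enumeration(self):
        # AA-AA-BB-AA-AA with 1-cM spacing: a double-recombinant artifact
        # flanked by two supporting markers per side. Enumerate all 3^5
        # true-genotype paths as the oracle. (With only one flank per
        # side the HMM prefers to explain a flank as an error and the
        # error LOD stays below the removal threshold.)
        from itertools import product

        calls = np.array([[0], [0], [2], [0], [0]], dtype=np.int8)
        g = _mk(calls, scaffolds=["s"] * 5, positions=[1, 2, 3, 4, 5])
        gmap = GeneticMap(pd.DataFrame(
            {"group": ["LG1"] * 5, "marker_id": [f"m{i}" for i in range(5)],
             "scaffold": ["s"] * 5, "pos": [1, 2, 3, 4, 5],
             "cM": [0.0, 1.0, 2.0, 3.0, 4.0]}))
        e = 0.01
        scores = error_lod_scores(g, gmap, genotype_error_prob=e)
        got = scores.set_index("marker_id").loc["m2", "error_lod"]

        from piedmap.qtlscan import transition_matrix
        from piedmap.cross import haldane_r

        T = transition_matrix(float(haldane_r(1.0)))
        prior = np.array([0.25, 0.5, 0.25])
        em = {0: np.array([1 - e, e / 2, e / 2]),
              2: np.array([e / 2, e / 2, 1 - e])}
        obs, mid = [0, 0, 2, 0, 0], 2
        q = np.zeros(3)
        for path in product(range(3), repeat=5):
            w = prior[path[0]]
            for k in range(4):
                w *= T[path[k], path[k + 1]]
            for k in range(5):
                if k != mid:  # leave-one-out: flanking observations only
                    w *= em[obs[k]][path[k]]
            q[path[mid]] += w
        q /= q.sum()
        oracle = np.log10(((1 - q[2]) * (e / 2)) / (q[2] * (1 - e)))
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got > 5  # removed at the default threshold

    def test_zero_noise_simulation_no_removals(self, small_cross):
        truth, _, tmap = small_cross
        sub_ids = tmap.table[tmap.table["group"] == "LG1"]["marker_id"]
        g = truth.subset(sub_ids)
        gmap = GeneticMap(tmap.table[tmap.table["group"] == "LG1"].reset_index(drop=True))
        _, removed = error_lod_clean(g, gmap)
        assert removed.empty


class TestDropOneMarker:
    def _forced_map(self, g):
        frag, _ = order_and_space(g, list(g.markers.index))
        frag.insert(0, "group", "LG1")
        return GeneticMap(frag)

    def test_clean_map_no_drops(self):
        truth, _, _ = simdata.sim_f2_cross(CrossSpec(150, [(12, 40.0)], seed=7))
        gmap, dropped = drop_one_marker_eval(self._forced_map(truth), truth)
        assert dropped == []

    def test_planted_noisy_marker_dropped(self):
        truth, _, _ = simdata.sim_f2_cross(CrossSpec(200, [(20, 50.0)], seed=21))
        rng = np.random.default_rng(5)
        bad = 10
        calls = truth.calls.copy()
        err = rng.random(200) < 0.30
        calls[bad] = np.where(
            err, (calls[bad] + rng.integers(1, 3, 200)) % 3, calls[bad]
        ).astype(np.int8)
        g = truth.copy()
        g.calls = calls
        gmap, dropped = drop_one_marker_eval(self._forced_map(g), g)
        assert g.markers.index[bad] in dropped

    def test_terminal_marker_shrink_rule_not_applied(self):
        # terminal marker separated by inflated distance but clean data:
        # rule (b) applies to non-terminal markers only
        truth, _, _ = simdata.sim_f2_cross(CrossSpec(150, [(10, 30.0)], seed=8))
        frag, _ = order_and_space(truth, list(truth.markers.index))
        frag.insert(0, "group", "LG1")
        frag.loc[frag.index[-1], "cM"] += 20.0  # inflate terminal spacing
        gmap, dropped = drop_one_marker_eval(GeneticMap(frag), truth)
        assert truth.markers.index[-1] not in dropped
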