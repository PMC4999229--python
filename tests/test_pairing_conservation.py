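"""Pair construction, conservation fractions, distance windows, pool similarity."""

from __future__ import annotations

import numpy as np
import pytest

from trnactx.annotation_io import OrthologMap, TRNAGene
from trnactx.genome_context import IntronicAssignment, classify_trnas
from trnactx.pairing_conservation import (
    AnticodonHostPair,
    WindowConfig,
    build_pairs,
    conservation_fraction,
    copy_number_similarity,
    extrapolate_zero,
    neighbor_pairs,
    neighbor_records,
    windowed_conservation,
)


def trna(tid, ac, pseudo=False):
    return TRNAGene(tid, "chrI", "+", 0, 80, "Trp", ac, pseudo)


def intronic(tid, host):
    return IntronicAssignment(tid, "intronic", host, 1, True)


def non_intronic(tid, up=None, down=None):
    return IntronicAssignment(
        tid, "non_intronic", upstream_neighbor=up, downstream_neighbor=down
    )


def pairs(*tups):
    return {AnticodonHostPair(ac, g) for ac, g in tups}


def identity_map(genes):
    return OrthologMap(("a", "b"), {g: g for g in genes})


class TestBuildPairs:
    def test_same_anticodon_same_host_collapses_to_one_pair(self):
        trnas = [trna("t1", "CCA"), trna("t2", "CCA")]
        assignments = [intronic("t1", "gA"), intronic("t2", "gA")]
        assert build_pairs(assignments, trnas) == pairs(("CCA", "gA"))

    def test_distinct_anticodons_same_host_stay_distinct(self):
        trnas = [trna("t1", "CCA"), trna("t2", "TGG")]
        assignments = [intronic("t1", "gA"), intronic("t2", "gA")]
        assert build_pairs(assignments, trnas) == pairs(("CCA", "gA"), ("TGG", "gA"))

    def test_no_intronic_trnas_gives_empty_set(self):
        assert build_pairs([non_intronic("t1")], [trna("t1", "CCA")]) == set()

    def test_pseudo_and_functional_never_mix(self):
        trnas = [trna("t1", "CCA"), trna("p1", "TGG", pseudo=True)]
        assignments = [intronic("t1", "gA"), intronic("p1", "gB")]
        assert build_pairs(assignments, trnas, "functional") == pairs(("CCA", "gA"))
        assert build_pairs(assignments, trnas, "pseudo") == pairs(("TGG", "gB"))


class TestConservationFraction:
    def test_identity_orthology_gives_one(self):
        p = pairs(("CCA", "g1"), ("TGG", "g2"))
        res = conservation_fraction(p, p, identity_map(["g1", "g2"]))
        assert res.fraction == 1.0

    def test_hand_count_with_missing_ortholog(self):
        """4 reference pairs, 1 without ortholog, 2 of remaining 3 conserved."""
        ref = pairs(("CCA", "g1"), ("TGG", "g2"), ("GCA", "g3"), ("TTT", "g4"))
        omap = OrthologMap(("a", "b"), {"g1": "h1", "g2": "h2", "g3": "h3", "g4": None})
        target = pairs(("CCA", "h1"), ("TGG", "h2"), ("AAA", "h3"))
        res = conservation_fraction(ref, target, omap)
        assert (res.n_pairs, res.n_no_ortholog, res.n_evaluable) == (4, 1, 3)
        assert res.n_conserved == 2
        assert res.fraction == pytest.approx(2 / 3)

    def test_empty_target_gives_zero_with_same_denominator(self):
        ref = pairs(("CCA", "g1"), ("TGG", "g2"))
        res = conservation_fraction(ref, set(), identity_map(["g1", "g2"]))
        assert res.fraction == 0.0 and res.n_evaluable == 2

    def test_no_evaluable_pairs_is_explicitly_undefined(self):
        ref = pairs(("CCA", "g1"))
        res = conservation_fraction(ref, set(), OrthologMap(("a", "b"), {"g1": None}))
        assert res.fraction is None and res.n_evaluable == 0

    def test_monotone_in_target_pairs(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        ref = pairs(*[(f"AC{i % 9}", g) for i, g in enumerate(genes)])
        omap = identity_map(genes)
        target = set()
        prev = -1.0
        for p in sorted(ref, key=lambda p: p.host_gene_id):
            target.add(p)
            frac = conservation_fraction(ref, target, omap).fraction
            assert frac >= prev
            prev = frac

    def test_excluding_no_ortholog_never_changes_numerator(self):
        ref = pairs(("CCA", "g1"), ("TGG", "g2"), ("GCA", "g3"))
        target = pairs(("CCA", "g1"))
        full = conservation_fraction(ref, target, identity_map(["g1", "g2", "g3"]))
        partial = conservation_fraction(
            ref, target, OrthologMap(("a", "b"), {"g1": "g1", "g2": "g2", "g3": None})
        )
        assert full.n_conserved == partial.n_conserved == 1
        assert partial.n_evaluable == full.n_evaluable - 1


class TestNeighborPairs:
    def test_sides_are_independent_and_none_skipped(self):
        trnas = [trna("t1", "CCA"), trna("t2", "TGG")]
        assignments = [
            non_intronic("t1", up=("gA", 100), down=("gB", 50)),
            non_intronic("t2", up=("gA", 10)),
        ]
        assert neighbor_pairs(assignments, trnas, "upstream") == pairs(
            ("CCA", "gA"), ("TGG", "gA")
        )
        assert neighbor_pairs(assignments, trnas, "downstream") == pairs(("CCA", "gB"))

    def test_count_matches_enumeration_oracle(self, small_bundle):
        ref = small_bundle.ref
        assignments, _ = classify_trnas(ref.trnas, ref.genes)
        by_id = {t.trna_id: t for t in ref.trnas}
        expected = {
            (by_id[a.trna_id].anticodon, a.upstream_neighbor[0])
            for a in assignments
            if a.status == "non_intronic"
            and a.upstream_neighbor
            and not by_id[a.trna_id].is_pseudo
        }
        got = neighbor_pairs(assignments, ref.trnas, "upstream")
        assert {(p.anticodon, p.host_gene_id) for p in got} == expected


class TestWindowedConservation:
    @staticmethod
    def records(n, conserved_prob=1.0, rng=None):
        rng = rng or np.random.default_rng(0)
        recs, target = [], set()
        for i in range(n):
            ac, gene, dist = f"AC{i % 11}", f"g{i}", int(rng.integers(1, 5000))
            recs.append((ac, gene, dist))
            if rng.random() < conserved_prob:
                target.add(AnticodonHostPair(ac, gene))
        omap = identity_map([f"g{i}" for i in range(n)])
        return recs, target, omap

    def test_step_rule_reproduces_57_percent_overlap(self):
        cfg = WindowConfig(40, 20)
        assert cfg.step(363) == 17
        assert (40 - 17) / 40 == pytest.approx(0.575)

    def test_windows_have_fixed_size_and_cover_prefix(self):
        recs, target, omap = self.records(363)
        points = windowed_conservation(recs, target, omap)
        assert len(points) == 20
        assert all(p.n_records == 40 for p in points)
        # consecutive windows advance by the step, covering [0, 19*17 + 40)
        assert points[-1].index == 19

    def test_all_conserved_gives_unit_fractions(self):
        recs, target, omap = self.records(120)
        points = windowed_conservation(recs, target, omap, WindowConfig(30, 5))
        assert all(p.fraction == 1.0 for p in points)

    def test_too_few_records_rejected(self):
        recs, target, omap = self.records(10)
        with pytest.raises(ValueError, match="window"):
            windowed_conservation(recs, target, omap, WindowConfig(40, 20))

    def test_planted_distance_decay_recovered(self):
        """Conservation drawn as p(d) = 0.9 * exp(-d / 1500) must fall with
        distance across windows and straddle the generating curve."""
        rng = np.random.default_rng(8)
        recs, target = [], set()
        for i in range(400):
            d = int(rng.exponential(1200)) + 1
            ac, gene = f"AC{i % 13}", f"g{i}"
            recs.append((ac, gene, d))
            if rng.random() < 0.9 * np.exp(-d / 1500):
                target.add(AnticodonHostPair(ac, gene))
        omap = identity_map([f"g{i}" for i in range(400)])
        points = windowed_conservation(recs, target, omap, WindowConfig(80, 10))
        fracs = [p.fraction for p in points]
        truth = [0.9 * np.exp(-p.median_distance / 1500) for p in points]
        # early windows conserve more than late ones, tracking the curve
        assert np.mean(fracs[:3]) > np.mean(fracs[-3:]) + 0.2
        for f, t, p in zip(fracs, truth, points):
            se = np.sqrt(t * (1 - t) / p.n_evaluable)
            assert abs(f - t) < 4 * se + 0.02


class TestExtrapolateZero:
    @staticmethod
    def points(x, y):
        from trnactx.pairing_conservation import WindowPoint

        return [
            WindowPoint(i, float(xi), float(yi), 40, int(40 * yi), 40)
            for i, (xi, yi) in enumerate(zip(x, y))
        ]

    def test_exact_linear_trend_recovered_with_zero_se(self):
        x = np.array([100.0, 300, 700, 1100, 1700, 2500])
        y = 0.1 + 0.001 * x
        res = extrapolate_zero(self.points(x, y))
        assert res.value_at_zero == pytest.approx(0.1, abs=1e-8)
        assert res.se_at_zero == pytest.approx(0.0, abs=1e-6)

    def test_constant_fractions_recovered(self):
        x = [100.0, 300, 700, 1100, 1700, 2500]
        res = extrapolate_zero(self.points(x, [0.4] * 6))
        assert res.value_at_zero == pytest.approx(0.4, abs=1e-8)

    def test_noisy_cubic_intercept_covered_by_3se(self):
        """Over repeated noisy draws from a known cubic, the fitted intercept
        falls within 3 SE of the true intercept in >= 95% of runs."""
        rng = np.random.default_rng(10)
        b = 0.35
        hits = 0
        n_runs = 100
        for _ in range(n_runs):
            x = np.linspace(50, 3000, 20)
            y = b - 1e-4 * x + 2e-8 * x**2 - 2e-12 * x**3 + rng.normal(0, 0.03, 20)
            res = extrapolate_zero(self.points(x, np.clip(y, 0, 1)))
            if abs(res.value_at_zero - b) <= 3 * res.se_at_zero:
                hits += 1
        assert hits >= 95

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_zero(self.points([1.0, 2, 3], [0.1, 0.2, 0.3]))


class TestCopyNumberSimilarity:
    def test_identical_pools_give_rho_one(self):
        v = {"CCA": 3, "TGG": 1, "GCA": 5}
        assert copy_number_similarity(v, v).rho == 1.0

    def test_hand_spearman(self):
        a = {"x": 1, "y": 2, "z": 3}
        b = {"x": 3, "y": 1, "z": 2}
        assert copy_number_similarity(a, b).rho == pytest.approx(-0.5)

    def test_disjoint_pools_use_union_with_zeros(self):
        a = {"AAA": 2, "CCC": 1}
        b = {"GGG": 4, "TTT": 3}
        res = copy_number_similarity(a, b)
        # hand-ranked oracle over the union with zeros
        keys = sorted(set(a) | set(b))
        from scipy.stats import spearmanr

        ref = spearmanr([a.get(k, 0) for k in keys], [b.get(k, 0) for k in keys])
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.n == 4

    def test_intersection_mode(self):
        a = {"AAA": 2, "CCC": 1, "GGG": 9, "TTT": 4}
        b = {"AAA": 1, "CCC": 5, "GGG": 2, "TTT": 8}
        res = copy_number_similarity(a, b, mode="intersection")
        assert res.n == 4

    def test_self_comparison_across_all_pair_classes(self, small_bundle):
        """A species compared with itself under identity orthology conserves
        every pair class fully."""
        ref = small_bundle.ref
        assignments, _ = classify_trnas(ref.trnas, ref.genes)
        omap = identity_map([g.gene_id for g in ref.genes])
        for builder in (
            lambda: build_pairs(assignments, ref.trnas, "functional"),
            lambda: build_pairs(assignments, ref.trnas, "pseudo"),
            lambda: neighbor_pairs(assignments, ref.trnas, "upstream"),
            lambda: neighbor_pairs(assignments, ref.trnas, "downstream"),
        ):
            p = builder()
            if p:
                assert conservation_fraction(p, p, omap).fraction == 1.0
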