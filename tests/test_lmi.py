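"""Local Moran's Index: transform, computation, exclusion rules, selection."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from moranprio import lmi
from moranprio.ldpanel import LDPanel, LDUndefinedError, Variant
from moranprio.lmi import LMIRecord


def make_panel(dosage_rows, spacing=10_000, chrom="1"):
    variants = [
        Variant(f"s{i}", chrom, 1_000_000 + i * spacing, "A", "G")
        for i in range(len(dosage_rows))
    ]
    return LDPanel(variants, np.asarray(dosage_rows, dtype=float))


class TestStandardizeOR:
    def test_single_snp_maps_to_zero(self):
        assert lmi.standardize_or({"a": 1.3}) == {"a": 0.0}

    def test_three_distinct_ors(self):
        z = lmi.standardize_or({"a": 1.1, "b": 1.2, "c": 1.3})
        expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        assert z["a"] == pytest.approx(expected[0], abs=1e-4)
        assert z["a"] == pytest.approx(-0.9674, abs=1e-4)
        assert z["b"] == pytest.approx(0.0, abs=1e-12)
        assert z["c"] == pytest.approx(0.9674, abs=1e-4)

    def test_ties_get_midrank_zero(self):
        z = lmi.standardize_or({"a": 1.5, "b": 1.5})
        assert z["a"] == pytest.approx(0.0, abs=1e-12)
        assert z["b"] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_or(self):
        rng = np.random.default_rng(5)
        ors = {f"v{i}": float(x) for i, x in enumerate(rng.uniform(1.0, 3.0, 50))}
        z = lmi.standardize_or(ors)
        order_or = sorted(ors, key=ors.get)
        order_z = sorted(z, key=z.get)
        assert order_or == order_z

    def test_empty_input(self):
        assert lmi.standardize_or({}) == {}


class TestComputeLMI:
    def test_hand_weighted_average(self):
        # focal + two neighbors in perfect LD (weights 0.5 after scaling
        # is irrelevant: local mean is weight-normalized)
        base = [0.0, 0.0, 1.0, 1.0, 2.0, 0.0, 1.0, 2.0]
        panel = make_panel([base, base, base])
        zmap = {"s0": 2.0, "s1": 1.0, "s2": 3.0}
        recs = {r.id: r for r in lmi.compute_lmi(zmap, panel, maf_tolerance=1.0)}
        r = recs["s0"]
        # both neighbors have r2 = 1: local mean = (1 + 3) / 2 = 2, LMI = 4
        assert r.estimable
        assert r.local_mean == pytest.approx(2.0)
        assert r.lmi == pytest.approx(4.0)

    def test_identity_case_lmi_is_z_squared(self):
        base = [0.0, 1.0, 1.0, 2.0, 0.0, 2.0]
        panel = make_panel([base, base, base])
        zmap = {"s0": 1.5, "s1": 1.5, "s2": 1.5}
        recs = {r.id: r for r in lmi.compute_lmi(zmap, panel, maf_tolerance=1.0)}
        for r in recs.values():
            assert r.lmi == pytest.approx(1.5**2)

    def test_no_estimable_neighbors(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 30).astype(float)
        panel = make_panel([a, np.ones(30)])  # neighbor has zero variance
        recs = {r.id: r for r in lmi.compute_lmi({"s0": 1.0, "s1": 1.0}, panel, maf_tolerance=1.0)}
        assert not recs["s0"].estimable
        assert math.isnan(recs["s0"].lmi)

    def test_snp_missing_from_panel_not_estimable(self):
        base = [0.0, 1.0, 2.0, 1.0]
        panel = make_panel([base, base])
        recs = {r.id: r for r in lmi.compute_lmi({"s0": 1.0, "s1": 0.5, "ghost": 2.0}, panel)}
        assert not recs["ghost"].estimable

    def test_rare_panel_snp_not_estimable(self):
        common = [0.0, 1.0, 2.0, 1.0] * 25
        rare = [1.0] + [0.0] * 99  # panel MAF 0.005 < 0.01
        panel = make_panel([common, rare, common])
        recs = {r.id: r for r in lmi.compute_lmi({"s0": 1.0, "s1": 1.0, "s2": 1.0}, panel, maf_tolerance=1.0)}
        assert recs["s0"].estimable
        assert not recs["s1"].estimable

    def test_neighbors_outside_scored_set_ignored(self):
        base = [0.0, 1.0, 1.0, 2.0, 0.0, 2.0]
        panel = make_panel([base, base, base])
        # s2 has no z: contributes nothing, but does not zero the denominator
        recs = {r.id: r for r in lmi.compute_lmi({"s0": 2.0, "s1": 1.0}, panel, maf_tolerance=1.0)}
        assert recs["s0"].neighbor_ids == ["s1"]
        assert recs["s0"].lmi == pytest.approx(2.0)

    def test_windows_never_span_chromosomes(self):
        base = [0.0, 1.0, 1.0, 2.0]
        v = [
            Variant("a", "1", 1_000_000, "A", "G"),
            Variant("b", "2", 1_000_100, "A", "G"),
        ]
        panel = LDPanel(v, np.array([base, base]))
        recs = {r.id: r for r in lmi.compute_lmi({"a": 1.0, "b": 1.0}, panel, maf_tolerance=1.0)}
        assert not recs["a"].estimable and not recs["b"].estimable

    def test_scale_law_exact(self):
        rng = np.random.default_rng(9)
        panel = make_panel(rng.integers(0, 3, size=(20, 40)).astype(float))
        zmap = {f"s{i}": float(z) for i, z in enumerate(rng.normal(size=20))}
        base = {r.id: r.lmi for r in lmi.compute_lmi(zmap, panel, maf_tolerance=1.0) if r.estimable}
        c = 2.5
        scaled = {
            r.id: r.lmi
            for r in lmi.compute_lmi({k: c * v for k, v in zmap.items()}, panel, maf_tolerance=1.0)
            if r.estimable
        }
        assert set(base) == set(scaled)
        for k in base:
            assert scaled[k] == pytest.approx(c**2 * base[k], rel=1e-12)

    def test_local_mean_bounded_by_neighbor_z(self):
        rng = np.random.default_rng(13)
        panel = make_panel(rng.integers(0, 3, size=(30, 50)).astype(float))
        zmap = {f"s{i}": float(z) for i, z in enumerate(rng.normal(size=30))}
        for r in lmi.compute_lmi(zmap, panel, maf_tolerance=1.0):
            if r.estimable:
                zs = [zmap[j] for j in r.neighbor_ids]
                assert min(zs) - 1e-12 <= r.local_mean <= max(zs) + 1e-12


from conftest import brute_force_lmi


class TestOracleEquivalence:
    def test_windowed_equals_brute_force_on_seeded_fixtures(self):
        max_diff = 0.0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_snps = int(rng.integers(40, 120))
            # irregular positions so windows differ per SNP
            pos = np.sort(rng.choice(np.arange(1, 3_000_000, 1000), n_snps, replace=False))
            variants = [Variant(f"s{i}", "1", int(p), "A", "G") for i, p in enumerate(pos)]
            panel = LDPanel(variants, rng.integers(0, 3, size=(n_snps, 30)).astype(float))
            zmap = {f"s{i}": float(z) for i, z in enumerate(rng.normal(size=n_snps))}
            expected = brute_force_lmi(zmap, panel)
            got = {r.id: (r.lmi if r.estimable else None) for r in lmi.compute_lmi(zmap, panel)}
            assert set(expected) == set(got)
            for k, e in expected.items():
                if e is None:
                    assert got[k] is None
                else:
                    max_diff = max(max_diff, abs(got[k] - e))
        assert max_diff < 1e-10


class TestFilterLMI:
    def make(self, id_, z, lmi_val, estimable=True):
        return LMIRecord(id=id_, z=z, lmi=lmi_val, local_mean=lmi_val / z if z else 0.0, estimable=estimable)

    def test_negative_lmi_discarded(self):
        recs = [self.make("a", 1.0, -0.2), self.make("b", 1.0, 0.5), self.make("c", -1.0, 0.1)]
        kept = lmi.filter_lmi(recs)
        assert recs[0].excluded_negative and not recs[0].excluded_bottom_tail
        assert "a" not in [r.id for r in kept]

    def test_bottom_tail_discarded_even_with_positive_lmi(self):
        # z = -0.5 with negative local mean: LMI = 0.2 >= 0 but z below median
        recs = [
            self.make("low", -0.5, 0.2),
            self.make("mid", 0.4, 0.3),
            self.make("high", 1.0, 0.5),
        ]
        kept = lmi.filter_lmi(recs)
        assert recs[0].excluded_bottom_tail and not recs[0].excluded_negative
        assert [r.id for r in kept] == ["mid", "high"]

    def test_median_boundary_retained(self):
        recs = [self.make("a", -1.0, 0.1), self.make("b", 0.0, 0.1), self.make("c", 1.0, 0.1)]
        kept = lmi.filter_lmi(recs)  # median z = 0; z == median retained
        assert {r.id for r in kept} == {"b", "c"}

    def test_flags_mutually_exclusive_and_absent_on_inestimable(self):
        rng = np.random.default_rng(21)
        recs = [
            self.make(f"r{i}", float(z), float(l), estimable=bool(e))
            for i, (z, l, e) in enumerate(
                zip(rng.normal(size=50), rng.normal(size=50), rng.random(50) < 0.8)
            )
        ]
        lmi.filter_lmi(recs)
        for r in recs:
            assert not (r.excluded_negative and r.excluded_bottom_tail)
            if not r.estimable:
                assert not r.excluded_negative and not r.excluded_bottom_tail
            elif r.lmi < 0:
                assert r.excluded_negative


class TestSelectTopFraction:
    def make_records(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [
            LMIRecord(id=f"r{i:06d}", z=1.0, lmi=float(v), estimable=True, p=float(p))
            for i, (v, p) in enumerate(zip(rng.normal(size=n), rng.uniform(size=n)))
        ]

    def test_genome_scale_count(self):
        selected, threshold = lmi.select_top_fraction(self.make_records(102_146), 0.005)
        assert len(selected) == 510
        assert threshold == selected[-1].lmi

    @pytest.mark.parametrize("n,k", [(1000, 5), (200, 1), (100, 0)])
    def test_floor_rule(self, n, k):
        selected, _ = lmi.select_top_fraction(self.make_records(n), 0.005)
        assert len(selected) == k

    def test_ranks_follow_lmi_descending(self):
        selected, _ = lmi.select_top_fraction(self.make_records(1000), 0.01)
        assert [r.rank for r in selected] == list(range(1, 11))
        lmis = [r.lmi for r in selected]
        assert lmis == sorted(lmis, reverse=True)

    def test_ties_broken_by_p_then_id(self):
        recs = [
            LMIRecord(id="b", z=1.0, lmi=2.0, estimable=True, p=0.5),
            LMIRecord(id="a", z=1.0, lmi=2.0, estimable=True, p=0.9),
            LMIRecord(id="c", z=1.0, lmi=2.0, estimable=True, p=0.5),
        ]
        selected, _ = lmi.select_top_fraction(recs, 2 / 3)
        assert [r.id for r in selected] == ["b", "c"]
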