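"""Tests for RRA, FOO, RSBC, alpha diversity and rarefaction."""

import numpy as np
import pandas as pd
import pytest

from dietbarcode import metrics, synthetic
from dietbarcode.amplicon import OtuTable
from dietbarcode.metrics import (
    DietProfile,
    aggregate_mean_rra,
    alpha_diversity,
    compute_foo,
    compute_rra,
    compute_rsbc,
    drop_unknown,
    expected_rarefied_richness,
    rarefaction_curve,
)
from dietbarcode.synthetic import CameraItem


def _taxonomy(rows):
    """rows: otu_id -> (order, family)"""
    data = []
    for otu, (order, family) in rows.items():
        data.append(
            {
                "otu_id": otu, "kingdom": "Animalia", "phylum": "Arthropoda",
                "class": "Insecta", "order": order, "family": family,
                "genus": "", "species": "", "flag": "reliable",
            }
        )
    return pd.DataFrame(data).set_index("otu_id")


def _item(session, order, family="", size=1.0, n=[0]):
    n[0] += 1
    lineage = ("Animalia", "Arthropoda", "Insecta" if order else "",
               order, family, "", "")
    return CameraItem(session_id=session, item_id=f"i{n[0]}",
                      lineage=lineage, size_multiplier=size)


class TestRra:
    def test_simple_normalization(self):
        table = OtuTable(counts=pd.DataFrame({"s1": [75, 25]}, index=["a", "b"]))
        tax = _taxonomy({"a": ("Diptera", "F1"), "b": ("Araneae", "F2")})
        (profile,) = compute_rra(table, tax, "order", exclude=None)
        assert profile.proportions == {"Diptera": 0.75, "Araneae": 0.25}

    def test_parasite_exclusion_renormalizes(self):
        table = OtuTable(counts=pd.DataFrame({"s1": [50, 50]}, index=["a", "b"]))
        tax = _taxonomy({"a": ("Diptera", "F1"), "b": ("Siphonaptera", "F2")})
        (profile,) = compute_rra(table, tax, "order")
        assert profile.proportions == {"Diptera": 1.0}

    def test_unknown_pooling_at_family(self):
        table = OtuTable(counts=pd.DataFrame({"s1": [40, 40, 20]},
                                             index=["a", "b", "c"]))
        tax = _taxonomy({"a": ("Diptera", "F1"), "b": ("Diptera", ""),
                         "c": ("Araneae", "")})
        (profile,) = compute_rra(table, tax, "family", exclude=None)
        assert profile.proportions["F1"] == pytest.approx(0.4)
        assert profile.proportions[metrics.UNKNOWN] == pytest.approx(0.6)

    def test_empty_sample_warns(self):
        table = OtuTable(counts=pd.DataFrame({"s1": [10], "s2": [0]}, index=["a"]))
        tax = _taxonomy({"a": ("Diptera", "F1")})
        with pytest.warns(UserWarning, match="s2"):
            profiles = compute_rra(table, tax, "order", exclude=None)
        assert profiles[1].proportions == {}

    def test_family_sums_match_order_rra(self):
        rng = np.random.default_rng(3)
        otus = {f"o{i}": (f"Order{i % 3}", f"Fam{i}") for i in range(9)}
        counts = pd.DataFrame(
            {"s1": rng.integers(1, 50, 9), "s2": rng.integers(1, 50, 9)},
            index=list(otus),
        )
        table = OtuTable(counts=counts)
        tax = _taxonomy(otus)
        order_profiles = compute_rra(table, tax, "order", exclude=None)
        family_profiles = compute_rra(table, tax, "family", exclude=None)
        fam_to_order = {f: o for o, f in otus.values()}
        for op, fp in zip(order_profiles, family_profiles):
            rollup = {}
            for fam, v in fp.proportions.items():
                rollup[fam_to_order[fam]] = rollup.get(fam_to_order[fam], 0) + v
            for order, v in op.proportions.items():
                assert rollup[order] == pytest.approx(v, abs=1e-12)


class TestAggregation:
    def test_two_step_rule(self):
        p1 = DietProfile("u1", "order", {"A": 1.0}, "reads")
        p2 = DietProfile("u2", "order", {"A": 0.5, "B": 0.5}, "reads")
        out = aggregate_mean_rra([p1, p2])
        assert out.loc["A", "mean"] == pytest.approx(0.75)
        assert out.loc["B", "mean"] == pytest.approx(0.25)

    def test_single_unit_is_itself(self):
        p = DietProfile("u1", "order", {"A": 0.6, "B": 0.4}, "reads")
        out = aggregate_mean_rra([p])
        assert out["mean"].to_dict() == pytest.approx({"A": 0.6, "B": 0.4})

    def test_identical_units_zero_sd(self):
        p = {"A": 0.3, "B": 0.7}
        out = aggregate_mean_rra(
            [DietProfile(f"u{i}", "order", p, "reads") for i in range(4)]
        )
        assert out["sd"].max() == pytest.approx(0.0, abs=1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_mean_rra([])

    def test_mixed_rank_rejected(self):
        with pytest.raises(ValueError):
            aggregate_mean_rra(
                [DietProfile("u1", "order", {"A": 1.0}, "reads"),
                 DietProfile("u2", "family", {"A": 1.0}, "reads")]
            )


class TestFoo:
    def test_counts_units_at_threshold(self):
        units = {"s1": {"t": 5.0}, "s2": {}, "s3": {"t": 2.0}}
        assert compute_foo(units)["t"] == 2
        assert compute_foo(units, min_reads=3)["t"] == 1

    def test_absent_taxon_zero(self):
        units = {"s1": {"a": 1.0}, "s2": {"b": 1.0}}
        foo = compute_foo(units)
        assert foo == {"a": 1, "b": 1}
        assert foo.get("c", 0) == 0

    def test_ubiquitous_taxon_counts_all_units(self):
        units = {f"s{i}": {"t": 1.0} for i in range(8)}
        assert compute_foo(units)["t"] == 8

    def test_foo_rra_divergence_constructed(self):
        # a taxon present everywhere at 1% has maximal FOO but tiny mean RRA
        n_units = 10
        profiles, units = [], {}
        for i in range(n_units):
            profiles.append(
                DietProfile(f"u{i}", "order", {"rare": 0.01, "bulk": 0.99}, "reads")
            )
            units[f"u{i}"] = {"rare": 1.0, "bulk": 99.0}
        assert compute_foo(units)["rare"] == n_units
        out = aggregate_mean_rra(profiles)
        assert out.loc["rare", "mean"] == pytest.approx(0.01)


class TestRsbc:
    def test_weighted_sum(self):
        items = [_item("c1", "Diptera", size=2.0) for _ in range(3)] + [
            _item("c1", "Araneae", size=0.5) for _ in range(2)
        ]
        (profile,) = compute_rsbc(items, "order", exclude=None)
        assert profile.proportions["Diptera"] == pytest.approx(6 / 7)
        assert profile.proportions["Araneae"] == pytest.approx(1 / 7)

    def test_all_unknown_at_family(self):
        items = [_item("c1", "Diptera", family="", size=1.0) for _ in range(4)]
        (profile,) = compute_rsbc(items, "family", exclude=None)
        assert profile.proportions == {metrics.UNKNOWN: 1.0}

    def test_recovers_biomass_within_sampling_error(self, community):
        # sampling design: delivery prob ~ biomass/size, contribution ~ size
        items = []
        for i in range(20):
            items.extend(
                synthetic.simulate_camera_session(
                    community, 150, rank_precision_probs={"order": 1.0},
                    seed=100 + i, session_id=f"c{i}",
                )
            )
        profiles = compute_rsbc(items, "order", exclude=None)
        mean = aggregate_mean_rra(profiles)["mean"]
        true = {}
        for m in community.members:
            if not m.is_parasite:
                o = m.ref.rank("order")
                true[o] = true.get(o, 0.0) + m.biomass_proportion
        total = sum(true.values())
        for o, v in true.items():
            p = v / total
            se = np.sqrt(p * (1 - p) / (150 * 20)) * np.sqrt(20)
            assert mean.get(o, 0.0) == pytest.approx(p, abs=max(3 * se, 0.03))

    def test_drop_unknown_renormalizes(self):
        p = DietProfile("u", "order", {"A": 0.5, metrics.UNKNOWN: 0.5}, "biomass")
        out = drop_unknown(p)
        assert out.proportions == {"A": 1.0}


class TestAlphaDiversity:
    def test_two_equal_taxa(self):
        richness, h = alpha_diversity({"a": 10, "b": 10})
        assert richness == 2
        assert h == pytest.approx(np.log(2))

    def test_single_taxon_zero_entropy(self):
        assert alpha_diversity({"a": 5}) == (1, 0.0)

    def test_direct_formula_oracle(self):
        counts = np.array([1, 2, 3, 4], dtype=float)
        _, h = alpha_diversity(counts)
        p = counts / counts.sum()
        assert h == pytest.approx(float(-(p * np.log(p)).sum()), abs=1e-12)

    def test_integerize_rounds_half_up(self):
        richness, _ = alpha_diversity({"a": 0.5, "b": 0.4}, integerize=True)
        assert richness == 1  # 0.5 -> 1, 0.4 -> 0

    def test_all_zero_unit(self):
        assert alpha_diversity({"a": 0.0}) == (0, 0.0)


class TestRarefaction:
    def test_full_depth_equals_observed_richness(self):
        reads = ["a"] * 5 + ["b"] * 3 + ["c"] * 2
        out = rarefaction_curve(reads, [10], n_rep=5, seed=1)
        assert out[10] == 3.0

    def test_depth_one(self):
        out = rarefaction_curve(["a"] * 5 + ["b"] * 5, [1], n_rep=20, seed=2)
        assert out[1] == 1.0

    def test_hypergeometric_closed_form(self):
        reads = ["common"] * 99 + ["rare"]
        out = rarefaction_curve(reads, [10], n_rep=400, seed=3)
        expected = expected_rarefied_richness({"common": 99, "rare": 1}, 10)
        # E = 1 + P(rare drawn) = 1 + (1 - C(99,10)/C(100,10)) = 1.1
        assert expected == pytest.approx(1.1, abs=1e-9)
        assert out[10] == pytest.approx(expected, abs=0.05)

    def test_monotone_in_depth(self):
        rng = np.random.default_rng(4)
        reads = list(rng.choice(list("abcdefgh"), size=200))
        out = rarefaction_curve(reads, [10, 50, 100, 200], n_rep=30, seed=5)
        values = [out[d] for d in (10, 50, 100, 200)]
        assert all(b >= a - 0.2 for a, b in zip(values, values[1:]))

    def test_depth_above_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve(["a"], [2], n_rep=1, seed=0)
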