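"""Unit and property tests for the read-processing stages."""

import numpy as np
import pytest

from conftest import make_merged, mutate_seq, oracle_revcomp

from dietbarcode import amplicon
from dietbarcode.align import revcomp
from dietbarcode.amplicon import (
    MalformedInputError,
    MergedRead,
    Otu,
    OtuTable,
    PipelineSettings,
    ReadPair,
    UniqueSeq,
)

import pandas as pd


def _template(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _pair_from_template(template, read_len, q=40, rid="p1"):
    fwd = template[:read_len]
    rev = oracle_revcomp(template)[:read_len]
    qual = chr(q + 33) * read_len
    return ReadPair(id=rid, fwd_seq=fwd, rev_seq=rev, fwd_qual=qual, rev_qual=qual)


class TestMergePairs:
    def test_exact_overlap_reconstructs_template(self):
        template = _template(220, seed=1)
        pair = _pair_from_template(template, 150)
        merged = amplicon.merge_pairs([pair], min_overlap=16)
        assert len(merged) == 1
        assert merged[0].seq == template
        assert len(merged[0].qual) == 220

    def test_short_overlap_drops_pair(self):
        template = _template(290, seed=2)
        # 150 bp reads of a 290 bp template overlap by 10 < 16
        pair = _pair_from_template(template, 150)
        assert amplicon.merge_pairs([pair], min_overlap=16) == []

    def test_quality_difference_rule(self):
        # one disagreement in a full overlap: fwd Q40 vs rev Q20 at column 5
        template = _template(60, seed=3)
        fwd = template
        rev_template = mutate_seq(template, [5], np.random.default_rng(0))
        rev = oracle_revcomp(rev_template)
        pair = ReadPair(
            id="q", fwd_seq=fwd, rev_seq=rev,
            fwd_qual=chr(40 + 33) * 60, rev_qual=chr(20 + 33) * 60,
        )
        merged = amplicon.merge_pairs([pair], min_overlap=16, max_diff_rate=0.25)
        assert merged[0].seq == template  # higher-Q fwd base wins
        assert merged[0].qual[5] == 20  # posterior Q = |40 - 20|
        assert merged[0].qual[6] == 41  # agreement: 40 + 40 capped at 41

    def test_length_mismatch_raises_with_read_id(self):
        with pytest.raises(MalformedInputError, match="badread"):
            ReadPair(id="badread", fwd_seq="ACGT", rev_seq="ACGT",
                     fwd_qual="III", rev_qual="IIII")


class TestTruncate:
    def test_270bp_read_becomes_220(self):
        r = make_merged(_template(270))
        out = amplicon.truncate([r], primer_trunc=25, trunc_len=220)
        assert len(out) == 1 and len(out[0].seq) == 220
        assert out[0].seq == r.seq[25:245]

    def test_268bp_read_discarded(self):
        r = make_merged(_template(268))
        assert amplicon.truncate([r], primer_trunc=25, trunc_len=220) == []

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            amplicon.truncate([], primer_trunc=0, trunc_len=0)
        with pytest.raises(ValueError):
            PipelineSettings(trunc_len=0)


class TestExpectedErrors:
    def test_all_q20_rejected_all_q40_retained(self):
        q20 = make_merged(_template(220), q=20, read_id="a")
        q40 = make_merged(_template(220), q=40, read_id="b")
        assert q20.expected_errors() == pytest.approx(2.20, abs=1e-12)
        assert q40.expected_errors() == pytest.approx(0.022, abs=1e-12)
        retained, rejected = amplicon.filter_expected_errors([q20, q40], 0.4)
        assert [r.id for r in retained] == ["b"]
        assert [r.id for r in rejected] == ["a"]

    def test_empty_input(self):
        assert amplicon.filter_expected_errors([], 0.4) == ([], [])

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_max_ee(self, seed):
        rng = np.random.default_rng(seed)
        reads = [
            MergedRead(id=f"r{i}", seq=_template(50, i),
                       qual=rng.integers(2, 41, size=50).astype(np.int16))
            for i in range(50)
        ]
        kept = [
            len(amplicon.filter_expected_errors(reads, ee)[0])
            for ee in (0.1, 0.4, 1.0, 5.0)
        ]
        assert kept == sorted(kept)


class TestDereplicate:
    def test_reverse_complement_merged(self):
        reads = [make_merged("ACGT", read_id=i) for i in "ab"]
        reads.append(make_merged(oracle_revcomp("ACGT"), read_id="c"))
        out = amplicon.dereplicate(reads, remove_singletons=False)
        assert len(out) == 1
        assert out[0].abundance == 3

    def test_singleton_removal(self):
        reads = [make_merged("AAAA", read_id="a"), make_merged("AAAA", read_id="b"),
                 make_merged("CCCC", read_id="c")]
        out = amplicon.dereplicate(reads, remove_singletons=True)
        assert [u.seq for u in out] == ["AAAA"]

    def test_sort_and_tiebreak_stable(self):
        reads = (
            [make_merged("GGGG", read_id=f"g{i}") for i in range(2)]
            + [make_merged("AAAA", read_id=f"a{i}") for i in range(2)]
        )
        out = amplicon.dereplicate(reads, remove_singletons=False)
        # equal abundance: lexicographically smaller canonical first
        assert [u.seq for u in out] == ["AAAA", "CCCC"]  # GGGG canonical = CCCC


class TestClusterOtus:
    def test_five_differences_one_otu(self):
        rng = np.random.default_rng(1)
        a = _template(220, seed=10)
        b = mutate_seq(a, [10, 50, 90, 130, 170], rng)
        uniques = [
            UniqueSeq(seq=min(a, oracle_revcomp(a)), abundance=10, member_ids=()),
            UniqueSeq(seq=min(b, oracle_revcomp(b)), abundance=5, member_ids=()),
        ]
        uniques.sort(key=lambda u: (-u.abundance, u.seq))
        assert len(amplicon.cluster_otus(uniques, 0.97)) == 1  # identity 215/220

    def test_ten_differences_two_otus(self):
        rng = np.random.default_rng(2)
        a = _template(220, seed=11)
        b = mutate_seq(a, list(range(10, 210, 20)), rng)
        uniques = sorted(
            [
                UniqueSeq(seq=min(a, oracle_revcomp(a)), abundance=10, member_ids=()),
                UniqueSeq(seq=min(b, oracle_revcomp(b)), abundance=5, member_ids=()),
            ],
            key=lambda u: (-u.abundance, u.seq),
        )
        assert len(amplicon.cluster_otus(uniques, 0.97)) == 2  # identity 210/220

    def test_single_sequence(self):
        u = UniqueSeq(seq="ACGT" * 30, abundance=3, member_ids=())
        otus = amplicon.cluster_otus([u], 0.97)
        assert len(otus) == 1 and otus[0].centroid == u.seq and otus[0].size == 3

    def test_unsorted_input_rejected(self):
        uniques = [
            UniqueSeq(seq="A" * 100, abundance=1, member_ids=()),
            UniqueSeq(seq="C" * 100, abundance=5, member_ids=()),
        ]
        with pytest.raises(ValueError, match="order"):
            amplicon.cluster_otus(uniques)

    def test_radius_property(self):
        # members >= 97% to own centroid, centroids pairwise < 97%
        rng = np.random.default_rng(3)
        base = [_template(220, seed=s) for s in range(4)]
        uniques = []
        for i, b in enumerate(base):
            uniques.append(UniqueSeq(seq=b, abundance=20 - i, member_ids=()))
            variant = mutate_seq(b, [7, 33, 61], rng)
            uniques.append(UniqueSeq(seq=variant, abundance=3, member_ids=()))
        uniques.sort(key=lambda u: (-u.abundance, u.seq))
        otus = amplicon.cluster_otus(uniques, 0.97)
        from dietbarcode.align import oriented_identity

        for u in uniques:
            best = max(oriented_identity(u.seq, o.centroid)[0] for o in otus)
            assert best >= 0.97
        for i, a in enumerate(otus):
            for b in otus[i + 1:]:
                assert oriented_identity(a.centroid, b.centroid)[0] < 0.97


class TestChimera:
    def _centroids(self):
        a = _template(220, seed=20)
        b = mutate_seq(a, list(range(0, 220, 10)), np.random.default_rng(4))
        return a, b, [Otu("OTU_1", a, 100), Otu("OTU_2", b, 100)]

    def test_constructed_splice_detected(self):
        a, b, centroids = self._centroids()
        query = UniqueSeq(seq=a[:110] + b[110:], abundance=2, member_ids=())
        assert amplicon.is_chimeric(query, centroids)

    def test_identical_to_parent_not_chimeric(self):
        a, _, centroids = self._centroids()
        assert not amplicon.is_chimeric(
            UniqueSeq(seq=a, abundance=2, member_ids=()), centroids
        )

    def test_unrelated_query_not_chimeric(self):
        _, _, centroids = self._centroids()
        q = UniqueSeq(seq=_template(220, seed=99), abundance=2, member_ids=())
        assert not amplicon.is_chimeric(q, centroids)

    def test_low_abundance_parents_not_called(self):
        a, b, _ = self._centroids()
        centroids = [Otu("OTU_1", a, 3), Otu("OTU_2", b, 3)]
        query = UniqueSeq(seq=a[:110] + b[110:], abundance=2, member_ids=())
        assert not amplicon.is_chimeric(query, centroids)  # parents < 2x abundance


class TestMapping:
    def test_divergent_read_unassigned(self):
        cent = _template(220, seed=30)
        far = mutate_seq(cent, list(range(0, 220, 10)), np.random.default_rng(5))
        table, unassigned = amplicon.map_reads_to_otus(
            {"s": [make_merged(far)]}, [Otu("OTU_1", cent, 10)], 0.97
        )
        assert unassigned == {"s": 1}
        assert table.counts.values.sum() == 0

    def test_empty_otu_list(self):
        table, unassigned = amplicon.map_reads_to_otus(
            {"s": [make_merged(_template(220))]}, [], 0.97
        )
        assert unassigned == {"s": 1}

    def test_count_conservation(self):
        cent = _template(220, seed=31)
        rng = np.random.default_rng(6)
        reads = [make_merged(cent, read_id=f"r{i}") for i in range(5)] + [
            make_merged(mutate_seq(cent, list(range(0, 220, 8)), rng), read_id="far")
        ]
        table, unassigned = amplicon.map_reads_to_otus(
            {"s": reads}, [Otu("OTU_1", cent, 10)], 0.97
        )
        assert table.counts["s"].sum() + unassigned["s"] == len(reads)


class TestSubtraction:
    def _table(self):
        counts = pd.DataFrame(
            {"s1": [12, 5, 7], "s2": [3, 0, 9]}, index=["OTU_1", "OTU_2", "OTU_3"]
        )
        return OtuTable(counts=counts)

    def test_examples_and_floor(self):
        out = amplicon.subtract_negative_controls(
            self._table(), {"OTU_1": 10, "OTU_2": 10}
        )
        assert out.counts.loc["OTU_1"].tolist() == [2, 0]
        assert out.counts.loc["OTU_2"].tolist() == [0, 0]
        assert out.counts.loc["OTU_3"].tolist() == [7, 9]

    def test_zero_controls_identity(self):
        t = self._table()
        out = amplicon.subtract_negative_controls(t, {})
        assert out.counts.equals(t.counts)

    def test_negative_controls_rejected(self):
        with pytest.raises(ValueError):
            amplicon.subtract_negative_controls(self._table(), {"OTU_1": -1})

    @pytest.mark.parametrize("seed", range(5))
    def test_removed_reads_equal_sum_of_min(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(4, 3)),
            index=[f"OTU_{i}" for i in range(4)],
            columns=list("abc"),
        )
        table = OtuTable(counts=counts)
        controls = {f"OTU_{i}": int(rng.integers(0, 15)) for i in range(4)}
        out = amplicon.subtract_negative_controls(table, controls)
        assert (out.counts.values >= 0).all()
        for otu in counts.index:
            removed = (counts.loc[otu] - out.counts.loc[otu]).sum()
            expected = sum(min(c, controls[otu]) for c in counts.loc[otu])
            assert removed == expected


def test_otu_count_monotone_in_identity_threshold():
    rng = np.random.default_rng(7)
    base = _template(220, seed=40)
    uniques = [UniqueSeq(seq=base, abundance=50, member_ids=())]
    for i in range(8):
        v = mutate_seq(base, list(rng.choice(220, size=2 + 3 * i, replace=False)), rng)
        uniques.append(UniqueSeq(seq=v, abundance=40 - i, member_ids=()))
    uniques.sort(key=lambda u: (-u.abundance, u.seq))
    n_otus = [
        len(amplicon.cluster_otus(uniques, t)) for t in (0.90, 0.95, 0.97, 0.99)
    ]
    assert n_otus == sorted(n_otus)
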