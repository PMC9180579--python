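"""Taxonomy, codec, descriptor conversion, and task aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apindel.labels import (
    Kind,
    LabelError,
    OutOfTaxonomy,
    RepairLabel,
    aggregate_outcomes,
    descriptor_to_label,
    enumerate_label_space,
    format_label,
    frame_class,
    parse_indel_descriptor,
    parse_label,
    tasks_from_distribution,
)


class TestEnumeration:
    def test_default_counts(self, space):
        assert len(space) == 557
        assert space.n_deletions() == 536
        assert space.n_insertions() == 21

    def test_insertion_sublist(self, space):
        kinds = [lab.kind for lab in space if lab.kind is not Kind.DELETION]
        assert kinds.count(Kind.INS1) == 4
        assert kinds.count(Kind.INS2) == 16
        assert kinds.count(Kind.INS3PLUS) == 1

    def test_no_deletions_when_max_len_zero(self):
        assert len(enumerate_label_space(max_del_len=0)) == 21

    def test_every_deletion_overlaps_window(self, space):
        for lab in space:
            if lab.kind is Kind.DELETION:
                positions = range(lab.start, lab.start + lab.length)
                assert any(-3 <= p <= 1 for p in positions)

    def test_ordering_is_deletions_then_insertions(self, space):
        kinds = [lab.kind for lab in space]
        assert kinds[:536] == [Kind.DELETION] * 536
        # deletions sorted by (length, start)
        keys = [(lab.length, lab.start) for lab in space[:536]]
        assert keys == sorted(keys)


class TestCodec:
    @pytest.mark.parametrize(
        "label,expected",
        [
            (RepairLabel(Kind.DELETION, start=-5, length=6), "-5+6"),
            (RepairLabel(Kind.DELETION, start=0, length=1), "0+1"),
            (RepairLabel(Kind.INS1, inserted="T"), "1+T"),
            (RepairLabel(Kind.INS2, inserted="AG"), "2+AG"),
            (RepairLabel(Kind.INS3PLUS), "3"),
        ],
    )
    def test_format(self, label, expected):
        assert format_label(label) == expected

    def test_roundtrip_whole_space(self, space):
        for lab in space:
            assert parse_label(format_label(lab)) == lab

    def test_unicode_minus_and_whitespace(self):
        assert parse_label(" −5 + 6 ") == RepairLabel(Kind.DELETION, start=-5, length=6)

    @pytest.mark.parametrize("bad", ["", "x", "1+", "2+A", "1+N", "5", "3+2+1"])
    def test_malformed_raises(self, bad):
        with pytest.raises(LabelError):
            parse_label(bad)


class TestDescriptors:
    @pytest.mark.parametrize(
        "s,ins,op,size,left,right,mh",
        [
            ("D1_L-2C1R1", "", "D", 1, -2, 1, 1),
            ("D4_L-6R-1", "", "D", 4, -6, -1, 0),
            ("I1_L-1R0", "T", "I", 1, -1, 0, 0),
        ],
    )
    def test_parse_fields(self, s, ins, op, size, left, right, mh):
        d = parse_indel_descriptor(s, ins)
        assert (d.op, d.size, d.left, d.right, d.mh_shift) == (op, size, left, right, mh)

    def test_inconsistent_deletion_size(self):
        with pytest.raises(LabelError, match="inconsistent"):
            parse_indel_descriptor("D3_L-2R1")

    @pytest.mark.parametrize(
        "s,ins,expected",
        [
            ("D1_L-2C1R1", "", "0+1"),
            ("I1_L-1R0", "T", "1+T"),
            ("D4_L-6R-1", "", "-5+4"),
            ("I2_L-1R0_CA", "", "2+CA"),
            ("I5_L-1R0", "", "3"),
        ],
    )
    def test_worked_conversions(self, space, s, ins, expected):
        lab = descriptor_to_label(parse_indel_descriptor(s, ins), space)
        assert format_label(lab) == expected

    def test_out_of_taxonomy_is_sentinel_not_drop(self, space):
        big = parse_indel_descriptor("D35_L-40R-4")
        assert isinstance(descriptor_to_label(big, space), OutOfTaxonomy)
        far = parse_indel_descriptor("D2_L-30R-27")
        assert isinstance(descriptor_to_label(far, space), OutOfTaxonomy)

    @given(start=st.integers(-26, 1), length=st.integers(1, 29))
    @settings(max_examples=200, deadline=None)
    def test_inverse_reconstruction_identity(self, start, length):
        """label -> consistent mh-free descriptor -> label is the identity."""
        space = enumerate_label_space()
        lab = RepairLabel(Kind.DELETION, start=start, length=length)
        if lab not in space:
            return
        s = f"D{length}_L{start - 1}R{start + length}"
        d = parse_indel_descriptor(s)
        assert d.left + 1 == start and d.right - d.left - 1 == length
        assert descriptor_to_label(d, space) == lab


class TestFrameAndTasks:
    @pytest.mark.parametrize(
        "label,expected",
        [
            (RepairLabel(Kind.DELETION, start=0, length=3), 0),
            (RepairLabel(Kind.DELETION, start=0, length=4), 1),
            (RepairLabel(Kind.INS1, inserted="A"), 1),
            (RepairLabel(Kind.INS2, inserted="AT"), 2),
            (RepairLabel(Kind.INS3PLUS), 0),
        ],
    )
    def test_frame_class(self, label, expected):
        assert frame_class(label) == expected

    def test_tasks_all_mass_on_ins1(self, space):
        p = np.zeros(len(space))
        p[space.index_of(parse_label("1+T"))] = 1.0
        t = tasks_from_distribution(p, space)
        assert t == pytest.approx((1, 0, 0, 1, 0, 1))

    def test_tasks_all_mass_on_1bp_deletion(self, space):
        p = np.zeros(len(space))
        p[space.index_of(parse_label("0+1"))] = 1.0
        t = tasks_from_distribution(p, space)
        assert t == pytest.approx((0, 1, 1, 1, 0, 1))

    def test_uniform_deletion_share(self, space):
        p = np.full(len(space), 1.0 / len(space))
        t = tasks_from_distribution(p, space)
        assert t.deletion == pytest.approx(536 / 557)

    def test_frameshift_sum_identity(self, space, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(len(space)))
            t = tasks_from_distribution(p, space)
            assert t.frameshift_overall == pytest.approx(t.frameshift1 + t.frameshift2)
            assert all(0 <= v <= 1 + 1e-12 for v in t)

    def test_renormalization_stability(self, space, rng):
        p = rng.dirichlet(np.ones(len(space)))
        q = p + 1e-12
        q = q / q.sum()
        a = np.array(tasks_from_distribution(p, space))
        b = np.array(tasks_from_distribution(q, space))
        assert np.abs(a - b).max() < 1e-9

    def test_not_a_distribution_raises(self, space):
        with pytest.raises(LabelError):
            tasks_from_distribution(np.full(len(space), 0.5), space)


class TestAggregation:
    def test_equal_counts(self, space):
        res = aggregate_outcomes([("1+T", 2), ("0+1", 2)], space)
        assert res.distribution.sum() == pytest.approx(1, abs=1e-9)
        assert res.distribution[space.index_of(parse_label("1+T"))] == 0.5
        assert res.distribution[space.index_of(parse_label("0+1"))] == 0.5

    def test_single_row_indicator(self, space):
        res = aggregate_outcomes([("1+T", 1)], space)
        assert res.distribution.max() == 1.0

    def test_descriptor_rows_normalized(self, space):
        res = aggregate_outcomes([("D4_L-6R-1", 3), ("I1_L-1R0_T", 1)], space)
        assert res.distribution[space.index_of(parse_label("-5+4"))] == pytest.approx(0.75)
        assert res.distribution[space.index_of(parse_label("1+T"))] == pytest.approx(0.25)

    def test_out_of_taxonomy_dropped_then_renormalized(self, space):
        res = aggregate_outcomes([("1+T", 1), ("D35_L-40R-4", 9)], space)
        assert res.distribution.sum() == pytest.approx(1, abs=1e-9)
        assert len(res.dropped) == 1

    def test_zero_mass_errors(self, space):
        with pytest.raises(LabelError):
            aggregate_outcomes([("D35_L-40R-4", 9)], space)
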