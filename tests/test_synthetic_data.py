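import pytest

from utrscope.conservation import HotspotConfig, call_hotspots, profile_columns
from utrscope.overlap_stats import hotspot_overlap
from utrscope.synthetic_data import (
    FamilySpec,
    GroupSpec,
    SpecError,
    UorfSpec,
    abca1_like_family,
    generate_family,
    plant_variants,
)
from utrscope.upstream_elements import call_uorfs


class TestSpecValidation:
    def test_default_spec_is_consistent(self):
        spec = abca1_like_family()
        assert sum(g.n_species for g in spec.groups) == 59

    def test_inconsistent_after_len_rejected(self):
        spec = abca1_like_family()
        spec.groups[0].after_len += 1
        with pytest.raises(SpecError, match="inconsistent"):
            spec.validate()

    def test_block_needs_exactly_one_atg(self):
        with pytest.raises(SpecError, match="exactly one ATG"):
            FamilySpec(groups=[], block_seq="ATGATGAA")

    def test_in_frame_uatg_rejected(self):
        # gap 3 makes head - after_len a multiple of 3: uATG in frame
        grp = GroupSpec("other", 2, 6 + 90 + 3, (50, 60), ("gap", 3))
        spec = FamilySpec(groups=[grp])
        with pytest.raises(SpecError, match="in frame"):
            spec.validate()


class TestGenerateFamily:
    def test_deterministic_given_seed(self):
        a = generate_family(abca1_like_family(seed=7))
        b = generate_family(abca1_like_family(seed=7))
        assert [r.seq for r in a[0]] == [r.seq for r in b[0]]
        assert a[1].rows == b[1].rows
        assert a[2].to_json() == b[2].to_json()

    def test_different_seeds_differ(self):
        a = generate_family(abca1_like_family(seed=1))
        b = generate_family(abca1_like_family(seed=2))
        assert [r.seq for r in a[0]] != [r.seq for r in b[0]]

    def test_zero_rates_give_identical_after_sections(self):
        spec = abca1_like_family(
            seed=0, sub_rate=0.0, block_sub_rate=0.0, indel_rate=0.0
        )
        records, aln, truth = generate_family(spec)
        profiles = profile_columns(aln)
        # every column of the shared conserved block is perfectly identical
        for col in truth.block_columns:
            assert profiles[col - 1].identity_pct == 100.0
            assert profiles[col - 1].occupancy_pct == 100.0

    def test_single_group_zero_rates_all_columns_identical(self):
        grp = GroupSpec("other", 6, 6 + 90 + 1, (80, 80), ("gap", 1))
        spec = FamilySpec(
            groups=[grp], sub_rate=0.0, block_sub_rate=0.0, indel_rate=0.0, seed=3
        )
        records, aln, _ = generate_family(spec)
        assert len({seq for _, seq in aln.rows}) == 1
        for p in profile_columns(aln):
            assert p.identity_pct == 100.0 and p.occupancy_pct == 100.0

    def test_planted_uorf_recovered_exactly_without_mutation(self, clean_family):
        """With substitution and indel rates at zero the uORF caller returns
        the planted coordinates for every record, with the planted
        gap/overlap relation to the mORF."""
        spec, records, _, truth = clean_family
        relations = {g.label: spec.group_relation(g) for g in spec.groups}
        for rec in records:
            rt = truth.records[rec.id]
            hits = [
                u
                for u in call_uorfs(rec)
                if (u.start, u.stop_end) == (rt.uorf_start, rt.uorf_stop_end)
            ]
            assert len(hits) == 1
            rel, k = relations[rt.group]
            expected_gap = k if rel == "gap" else -k
            assert hits[0].gap_to_morf == expected_gap
            assert hits[0].overlaps_morf == (rel == "overlap")
            assert hits[0].frame_offset != 0  # planted uATG is out of frame

    def test_annotations_consistent_with_truth(self, default_family):
        _, records, aln, truth = default_family
        aln.validate_against({r.id: r for r in records})
        for rec in records:
            rt = truth.records[rec.id]
            assert rec.intron1_offset == rt.before_len
            assert rec.morf_start == rt.morf_start == rec.utr5_len + 1
            assert rec.seq[rec.morf_start - 1 : rec.morf_start + 2] == "ATG"
            # the uATG survives at its planted position (block mutations off
            # the codon may perturb it only at block_sub_rate > 0)
            lo, hi = rt.block_interval
            assert 1 <= lo <= hi <= rec.utr5_len

    def test_block_contains_planted_uatg_in_clean_family(self, clean_family):
        _, records, _, truth = clean_family
        for rec in records:
            rt = truth.records[rec.id]
            assert rec.seq[rt.uorf_start - 1 : rt.uorf_start + 2] == "ATG"
            lo, hi = rt.block_interval
            assert rec.utr5_seq()[lo - 1 : hi] == abca1_like_family().block_seq


class TestPlantVariants:
    def _rec(self):
        return next(
            r
            for r in generate_family(abca1_like_family(seed=0))[0]
            if r.group == "primates"
        )

    def test_161_39_reproduces_24pct(self):
        rec = self._rec()
        intervals = [(rec.intron1_offset + 1, rec.intron1_offset + 60)]
        vs = plant_variants(rec, intervals, 161, 39, seed=11)
        assert hotspot_overlap(vs, intervals).pct == 24

    @pytest.mark.parametrize("n_total, n_inside, pct", [(10, 0, 0), (5, 5, 100)])
    def test_degenerate_fractions(self, n_total, n_inside, pct):
        rec = self._rec()
        intervals = [(10, 40)]
        vs = plant_variants(rec, intervals, n_total, n_inside, seed=2)
        assert hotspot_overlap(vs, intervals).pct == pct

    def test_infeasible_counts_rejected(self):
        rec = self._rec()
        with pytest.raises(ValueError, match="inside"):
            plant_variants(rec, [(1, 5)], 10, 8, seed=0)

    def test_positions_distinct_and_in_range(self):
        rec = self._rec()
        vs = plant_variants(rec, [(20, 80)], 50, 20, seed=9)
        assert len(vs.positions) == 50
        assert all(1 <= p <= rec.utr5_len for p in vs.positions)


def test_gc_targets_recovered_with_background_mutation():
    """Substitutions resample from the section distribution, so pooled GC of
    sections of at least 300 nt stays within 2 pp of the targets even at the
    default 0.35 background rate.  The after section here is gap-dominated
    (>= 300 nt) so the fixed conserved block contributes little."""
    from utrscope.composition import gc_percent

    # after_len = 6 + 90 + 205 = 301; gap 205 keeps the uATG out of frame
    grp = GroupSpec("other", 12, 301, (300, 340), ("gap", 205))
    spec = FamilySpec(groups=[grp], seed=4)
    records, _, _ = generate_family(spec)
    before = "".join(r.utr5_seq()[: r.intron1_offset] for r in records)
    after = "".join(r.utr5_seq()[r.intron1_offset :] for r in records)
    assert min(len(before), len(after)) >= 300
    assert abs(gc_percent(before) - spec.gc_targets["before"]) <= 2.0
    assert abs(gc_percent(after) - spec.gc_targets["after"]) <= 2.0


def test_hotspot_caller_sees_full_occupancy_on_block(default_family):
    _, records, aln, truth = default_family
    hs = call_hotspots(profile_columns(aln), HotspotConfig(), aln)
    assert set(truth.block_columns) <= set(hs.columns)
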