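"""Association-table construction, module calling, architectures, identity bins."""

import random

import numpy as np
import pytest

from rumenmt.cazy_annotation import (
    AssociationEntry,
    ContigAnnotation,
    ModuleCall,
    UNCLASSIFIED,
    annotate_contigs,
    bin_identity,
    build_association_table,
    call_modules,
    family_contig_counts,
    merge_calls,
    resolve_architectures,
)
from rumenmt.core_io import AlignmentHit, DomainHit
from rumenmt.synthetic_data import CazyFamilyDef


def _fam(fam_id, n=20, cls=None):
    cls = cls or ("CBM" if fam_id.startswith("CBM") else fam_id[:2])
    return CazyFamilyDef(fam_id, cls, tuple(f"{fam_id}_m{i}" for i in range(n)))


def _hits(fam_id, model, k, n=20):
    return [(f"{fam_id}_m{i}", model, True) for i in range(k)]


class TestAssociationTable:
    def test_pure_family_above_coverage_accepted(self):
        table = build_association_table([_fam("GH6")], _hits("GH6", "PB1", 17))
        assert table == [AssociationEntry("PB1", "GH6", "B", True)]

    def test_coverage_exactly_80_percent_accepted(self):
        (e,) = build_association_table([_fam("GH6")], _hits("GH6", "PB1", 16))
        assert e.accepted  # 16/20 = 0.80, boundary inclusive

    def test_low_coverage_rejected(self):
        (e,) = build_association_table([_fam("GH6")], _hits("GH6", "PB1", 15))
        assert not e.accepted and e.rejection_reason == "low_coverage"

    def test_combined_group_when_all_families_pass(self):
        fams = [_fam("CE2"), _fam("CE3")]
        rows = _hits("CE3", "PB9", 18) + _hits("CE2", "PB9", 17)
        (e,) = build_association_table(fams, rows)
        assert e.accepted and e.label == "CE2/CE3"  # parts sorted, "/"-joined

    def test_mixed_coverage_rejected_as_impure(self):
        fams = [_fam("CE2"), _fam("CE3")]
        rows = _hits("CE2", "PB9", 17) + _hits("CE3", "PB9", 3)
        (e,) = build_association_table(fams, rows)
        assert not e.accepted and e.rejection_reason == "impure"

    def test_all_families_below_coverage_rejected(self):
        fams = [_fam("CE2"), _fam("CE3")]
        rows = _hits("CE2", "PB9", 5) + _hits("CE3", "PB9", 3)
        (e,) = build_association_table(fams, rows)
        assert not e.accepted and e.rejection_reason == "low_coverage"

    def test_insignificant_hits_ignored(self):
        rows = _hits("GH6", "PB1", 16) + [("GH6_m19", "PB1", False)]
        (e,) = build_association_table([_fam("GH6")], rows)
        assert e.accepted and e.label == "GH6"

    def test_unknown_member_is_error(self):
        with pytest.raises(KeyError, match="ghost"):
            build_association_table([_fam("GH6")], [("ghost", "PB1", True)])

    def test_order_independent(self):
        fams = [_fam("GH6"), _fam("CE2"), _fam("CE3")]
        rows = (_hits("GH6", "PB1", 17) + _hits("CE2", "PB9", 17)
                + _hits("CE3", "PB9", 18) + _hits("GH6", "PB2", 4))
        reference = build_association_table(fams, rows)
        rng = random.Random(5)
        for _ in range(10):
            shuffled = rows[:]
            rng.shuffle(shuffled)
            assert build_association_table(fams, shuffled) == reference


def _dh(contig, model, score, qs, qe):
    return DomainHit(contig, model, score, 1e-10, qs, qe, "hmm")


DIRECT = {"PF_GH48": "GH48", "PF_CBM10": "CBM10", "PF_GH6": "GH6"}


class TestCallModules:
    def test_score_cutoff_boundary_inclusive(self):
        hits = [_dh("c1", "PF_GH48", 52.0, 1, 100),
                _dh("c1", "PF_CBM10", 51.9, 200, 300)]
        calls = call_modules(hits, direct_models=DIRECT)
        assert [c.label for c in calls] == ["GH48"]

    def test_stacked_distinct_modules_kept_in_coordinate_order(self):
        hits = [_dh("c1", "PF_CBM10", 80, 950, 1050),
                _dh("c1", "PF_GH48", 120, 10, 900)]
        calls = call_modules(hits, direct_models=DIRECT)
        assert [(c.label, c.q_start, c.q_end) for c in calls] == [
            ("GH48", 10, 900), ("CBM10", 950, 1050)]

    def test_overlapping_same_label_hits_merge_with_max_score(self):
        hits = [_dh("c1", "PF_GH6", 60, 10, 200), _dh("c1", "PF_GH6", 90, 150, 400)]
        (call,) = call_modules(hits, direct_models=DIRECT)
        assert (call.q_start, call.q_end, call.score) == (10, 400, 90.0)

    def test_unrouted_model_warned_and_unclassified(self):
        with pytest.warns(UserWarning, match="no route"):
            (call,) = call_modules([_dh("c1", "PF_MYSTERY", 99, 1, 100)])
        assert call.label == UNCLASSIFIED

    def test_association_route_labels_hits(self):
        assoc = [AssociationEntry("PB9", "CE2/CE3", "B", True),
                 AssociationEntry("PB2", "GH9", "B", False, "low_coverage")]
        with pytest.warns(UserWarning):
            calls = call_modules(
                [_dh("c1", "PB9", 70, 1, 100), _dh("c1", "PB2", 70, 200, 300)],
                assoc=assoc)
        assert [c.label for c in calls] == ["CE2/CE3", UNCLASSIFIED]

    def test_blast_representative_route(self):
        rep_hit = AlignmentHit("c1", "rep_GH77", 85, 120, 10, 0, 5, 124, 1, 120,
                               1e-30, 77.0)
        (call,) = call_modules([], blast_reps=[rep_hit],
                               rep_labels={"rep_GH77": "GH77"})
        assert call.label == "GH77" and call.source == "blast"

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(11)
        calls = []
        for _ in range(200):
            qs = int(rng.integers(1, 500))
            calls.append(ModuleCall(f"c{rng.integers(1, 6)}",
                                    ["GH6", "GH48"][rng.integers(0, 2)],
                                    qs, qs + int(rng.integers(1, 200)),
                                    float(rng.uniform(52, 150)), "hmm"))
        once = merge_calls(calls)
        assert merge_calls(once) == once

    def test_merge_matches_interval_union_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            intervals = []
            for _ in range(int(rng.integers(2, 12))):
                qs = int(rng.integers(1, 100))
                intervals.append((qs, qs + int(rng.integers(0, 40))))
            calls = [ModuleCall("c1", "GH6", qs, qe, 60.0, "hmm")
                     for qs, qe in intervals]
            merged = merge_calls(calls)
            # oracle: a position is covered iff it lies inside some interval;
            # merged spans must cover exactly the covered set, disjointly
            covered = {p for qs, qe in intervals for p in range(qs, qe + 1)}
            spans = [set(range(c.q_start, c.q_end + 1)) for c in merged]
            assert set().union(*spans) == covered
            for i, a in enumerate(spans):
                for b in spans[i + 1:]:
                    assert not a & b


def _ann(cid, labels, length=800, identity=None):
    mods = [ModuleCall(cid, l, 1 + 100 * i, 80 + 100 * i, 60.0, "hmm")
            for i, l in enumerate(labels)]
    top = None if identity is None else {"percent_identity": identity,
                                         "e_value": 1e-30, "annotation": "x"}
    return ContigAnnotation(cid, length, 0, mods, top)


class TestArchitectures:
    def test_repeated_same_family_is_not_multi_domain(self):
        out = resolve_architectures([_ann("c1", ["GH6", "GH6"])])
        assert out["n_multi_domain"] == 0

    def test_distinct_labels_make_multi_domain(self):
        out = resolve_architectures([_ann("c1", ["GH48", "CBM10"]),
                                     _ann("c2", ["GH6"])])
        assert out["multi_domain_contigs"] == ["c1"]
        assert out["cooccurrence"] == {("CBM10", "GH48"): 1}

    def test_short_contigs_excluded_by_length_floor(self):
        out = resolve_architectures([_ann("c1", ["GH48", "CBM10"], length=499)])
        assert out["n_considered"] == 0 and out["n_multi_domain"] == 0

    def test_label_percent_over_multi_domain_contigs(self):
        anns = ([_ann(f"m{i}", ["GH48", "CBM10"]) for i in range(3)]
                + [_ann("m3", ["GH6", "GH5"])])
        out = resolve_architectures(anns)
        assert out["label_percents"]["CBM10"] == 75.0

    def test_cooccurrence_counted_once_per_contig(self):
        ann = ContigAnnotation("c1", 900, 0, [
            ModuleCall("c1", "GH48", 1, 80, 60, "hmm"),
            ModuleCall("c1", "CBM10", 100, 160, 60, "hmm"),
            ModuleCall("c1", "CBM10", 300, 360, 60, "hmm"),
        ])
        out = resolve_architectures([ann])
        assert out["cooccurrence"] == {("CBM10", "GH48"): 1}


class TestIdentityBins:
    @pytest.mark.parametrize("identity,bin_", [
        (88.6, ">70"), (37.8, "<50"), (50.0, "50-70"), (70.0, "50-70"),
        (49.99, "<50"), (70.01, ">70"),
    ])
    def test_bin_edges(self, identity, bin_):
        out = bin_identity([_ann("c1", ["GH6"], identity=identity)])
        assert out["counts"][bin_] == 1

    def test_no_hit_counted_separately_and_sum_conserved(self):
        anns = [_ann("c1", ["GH6"], identity=88.6),
                _ann("c2", ["GH6"], identity=55.0),
                _ann("c3", ["GH6"])]
        out = bin_identity(anns)
        assert out["no_hit"] == 1
        assert sum(out["counts"].values()) + out["no_hit"] == len(anns)
        assert out["percents"][">70"] == 50.0

    def test_identity_out_of_range_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            bin_identity([_ann("c1", ["GH6"], identity=120.0)])


def test_annotate_contigs_collects_counts_and_top_hits():
    calls = call_modules(
        [_dh("c1", "PF_GH48", 120, 10, 900), _dh("c1", "PF_CBM10", 60, 950, 1050)],
        direct_models=DIRECT)
    top = AlignmentHit("c1", "Piromyces_prot01", 78.2, 500, 80, 2, 1, 500,
                       1, 500, 1e-120, 300, "Piromyces", "cellulase Cel48A precursor")
    (ann,) = annotate_contigs(calls, {"c1": 2292}, {"c1": 52778}, {"c1": top})
    assert ann.read_count == 52778
    assert [m.label for m in ann.modules] == ["GH48", "CBM10"]
    assert ann.top_hit["percent_identity"] == 78.2
    assert family_contig_counts(calls) == {"GH48": 1, "CBM10": 1}
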