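"""TMH prediction, median filtering, rank-sum statistics and composition."""

from itertools import combinations

import numpy as np
import pytest

from memlipid import (
    FilterConfig,
    OrthologGroup,
    TmhAnnotation,
    count_difference_distribution,
    filter_by_median,
    length_comparison,
    predict_tmh_hydropathy,
    rank_sum_test,
    residue_class_composition,
    single_span_orthologs,
)
from memlipid.tmh import median_filter_cutoff


class TestHydropathyPredictor:
    def test_poly_leucine_core_detected(self):
        seq = "D" * 30 + "L" * 30 + "D" * 30
        ann = predict_tmh_hydropathy(seq)
        assert len(ann.segments) == 1
        start, end = ann.segments[0]
        assert 31 <= start and end <= 60  # inside the hydrophobic core

    def test_hydrophilic_sequence_has_no_segments(self):
        assert predict_tmh_hydropathy("D" * 80).segments == ()

    def test_planted_21mer_length(self):
        rng = np.random.default_rng(5)
        bg = "DEKRNQH"
        flank1 = "".join(rng.choice(list(bg), 60))
        flank2 = "".join(rng.choice(list(bg), 60))
        seq = flank1 + "L" * 21 + flank2
        ann = predict_tmh_hydropathy(seq)
        assert len(ann.segments) == 1
        assert abs(ann.lengths[0] - 21) <= 9  # within (window-1)/2

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            predict_tmh_hydropathy("ACDEFGHIKLMNOPQRSTVWY")

    def test_deterministic(self):
        seq = "D" * 25 + "LIVFLIVFLIVFLIVFLIVFL" + "E" * 25
        assert predict_tmh_hydropathy(seq) == predict_tmh_hydropathy(seq)


def _ann(pid, sp, lengths, start=10, gap=30):
    segs = []
    pos = start
    for ln in lengths:
        segs.append((pos, pos + ln - 1))
        pos += ln + gap
    return TmhAnnotation(pid, sp, tuple(segs))


class TestMedianFilter:
    def test_stated_cutoff_from_median_23(self):
        med, cutoff = median_filter_cutoff([23] * 5)
        assert (med, cutoff) == (23.0, 12)

    def test_35aa_segment_discarded_at_median_23(self):
        anns = [_ann("a", "x", [23] * 11), _ann("b", "x", [35])]
        kept, med, cutoff = filter_by_median(anns)
        assert med == 23 and cutoff == 12
        assert kept[1].segments == ()

    def test_deviation_12_both_sides_discarded(self):
        anns = [_ann("a", "x", [23, 23, 23]), _ann("b", "x", [11, 35])]
        kept, *_ = filter_by_median(anns)
        assert [len(a.segments) for a in kept] == [3, 0]

    def test_median_length_always_kept(self):
        anns = [_ann("a", "x", [23, 19, 27, 23])]
        kept, med, _ = filter_by_median(anns)
        assert all(
            any(e - s + 1 == med for s, e in a.segments) for a in kept if a.segments
        )

    def test_idempotent(self):
        anns = [_ann("a", "x", [20, 23, 26, 23, 40, 10])]
        once, med1, _ = filter_by_median(anns)
        twice, med2, _ = filter_by_median(once)
        assert med1 == med2
        assert [a.segments for a in once] == [a.segments for a in twice]


SPECIES = ("pombe", "japonicus", "octosporus", "cryophilus")


def _group(gid, n_ref_segments):
    members = {sp: f"{sp}|{gid}" for sp in SPECIES}
    anns = {
        f"{sp}|{gid}": _ann(f"{sp}|{gid}", sp, [23] * (n_ref_segments if sp == "pombe" else 1))
        for sp in SPECIES
    }
    return OrthologGroup(gid, members), anns


class TestSingleSpan:
    def test_selection_by_reference_span_count(self):
        groups, annotations = [], {}
        for gid, n in (("g1", 1), ("g2", 0), ("g3", 2), ("g4", 1)):
            g, anns = _group(gid, n)
            groups.append(g)
            annotations.update(anns)
        kept = single_span_orthologs(groups, annotations, "pombe")
        assert [g.group_id for g in kept] == ["g1", "g4"]

    def test_missing_annotation_skipped_with_warning(self):
        g, anns = _group("g1", 1)
        del anns["pombe|g1"]
        with pytest.warns(UserWarning, match="missing annotation"):
            assert single_span_orthologs([g], anns, "pombe") == []


def _enumerated_p(a, b):
    """Exact two-sided rank-sum p by brute-force enumeration (oracle)."""
    pooled = np.concatenate([a, b])
    ranks = np.empty(len(pooled))
    order = np.argsort(pooled, kind="stable")
    sorted_vals = pooled[order]
    # midranks with ties
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    n_a = len(a)
    observed = ranks[:n_a].sum()
    mean = ranks.sum() * n_a / len(pooled)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total


class TestRankSum:
    def test_identical_samples_p_is_one(self):
        _, p = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    @pytest.mark.parametrize(
        "a, b",
        [
            ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]),
            ([1.0, 4.0, 6.0], [2.0, 3.0, 5.0]),
            ([1.0, 2.0, 2.0, 7.0], [2.0, 5.0, 8.0]),  # with ties
            ([10.0, 11.0], [1.0, 2.0, 3.0, 12.0]),
            ([3.0, 3.0, 3.0, 9.0, 10.0], [3.0, 4.0, 5.0, 6.0, 7.0]),
        ],
    )
    def test_exact_matches_enumeration_oracle(self, a, b):
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(_enumerated_p(np.array(a), np.array(b)), abs=1e-9)

    def test_planted_shift_detected(self, proteome_cohort):
        from memlipid import predict_tmh_hydropathy

        anns = {
            pid: predict_tmh_hydropathy(seq, pid, pid.split("|")[0])
            for pid, seq in proteome_cohort.sequences.items()
        }
        kept, *_ = filter_by_median(anns.values())
        fmap = {a.protein_id: a for a in kept}
        groups = single_span_orthologs(proteome_cohort.groups, fmap, "pombe")
        res = length_comparison(groups, fmap, "pombe", "japonicus")
        assert res["p_value"] < 0.05
        assert res["median_b"] < res["median_a"]

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])


class TestCountDifferences:
    def test_identical_annotations_all_zero(self):
        g, anns = _group("g1", 1)
        df = count_difference_distribution([g], anns, "pombe")
        assert (df["count_difference"] == 0).all()
        assert len(df) == 3  # one row per non-reference species

    def test_reference_swap_negates(self):
        g, anns = _group("g1", 2)
        d1 = count_difference_distribution([g], anns, "pombe")
        d2 = count_difference_distribution([g], anns, "japonicus")
        v1 = d1.set_index("species")["count_difference"]["japonicus"]
        v2 = d2.set_index("species")["count_difference"]["pombe"]
        assert v1 == -v2

    def test_planted_dropout_fraction(self):
        rng_groups, annotations = [], {}
        for i in range(20):
            g, anns = _group(f"g{i}", 1)
            if i < 4:  # 20% of groups lose one helix in japonicus
                pid = f"japonicus|g{i}"
                anns[pid] = TmhAnnotation(pid, "japonicus", ())
            rng_groups.append(g)
            annotations.update(anns)
        df = count_difference_distribution(rng_groups, annotations, "pombe")
        jap = df[df["species"] == "japonicus"]["count_difference"]
        assert (jap == -1).mean() == pytest.approx(0.2)


class TestComposition:
    def test_poly_alanine_is_all_small_nonpolar(self):
        ann = TmhAnnotation("p", "x", ((1, 10),))
        df = residue_class_composition([ann], {"p": "A" * 10})
        assert df.loc[df["residue_class"] == "small_nonpolar", "fraction"].iloc[0] == 1.0

    def test_half_and_half(self):
        ann = TmhAnnotation("p", "x", ((1, 4),))
        df = residue_class_composition([ann], {"p": "AAFF"})
        fr = df.set_index("residue_class")["fraction"]
        assert fr["small_nonpolar"] == pytest.approx(0.5)
        assert fr["large_nonpolar"] == pytest.approx(0.5)

    def test_fractions_sum_to_one_per_species(self, proteome_cohort):
        anns = [
            predict_tmh_hydropathy(seq, pid, pid.split("|")[0])
            for pid, seq in list(proteome_cohort.sequences.items())[:40]
        ]
        df = residue_class_composition(anns, proteome_cohort.sequences)
        sums = df.groupby("species")["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_unknown_residue_rejected(self):
        ann = TmhAnnotation("p", "x", ((1, 2),))
        with pytest.raises(ValueError, match="absent from class table"):
            residue_class_composition([ann], {"p": "AA"}, class_table={"G": "x"})
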