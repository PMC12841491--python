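"""Recurrence masking, RPKM/CV/GC/mappability annotation and the
problematic-vs-random feature comparison."""

import numpy as np
import pandas as pd
import pytest

import cnvbench as cb
from cnvbench.problematic import BaitFeatures, annotate, compare_features

from conftest import make_baits


def calls_at_bait(baits, bait_id, samples, caller="x", cnv_type="DEL"):
    r = baits.set_index("bait_id").loc[bait_id]
    return pd.DataFrame(
        {
            "chrom": r["chrom"], "start": int(r["start"]), "end": int(r["end"]),
            "type": cnv_type, "sample": list(samples), "caller": caller,
        }
    )


@pytest.fixture
def baits():
    return make_baits(40, spacing=200, length=100, chroms=("1", "2"))


class TestRecurrence:
    def test_strict_threshold_boundary_18_vs_19_of_180(self, baits):
        """Called in exactly 10% of the cohort is NOT problematic; one more is."""
        c18 = calls_at_bait(baits, "b0000", [f"S{i}" for i in range(18)])
        rec = cb.recurrence(c18, baits, cohort_size=180)
        assert rec.table.loc["b0000", "fraction"] == pytest.approx(0.10)
        assert not cb.build_mask(rec, baits, 0.10).flagged_baits
        c19 = calls_at_bait(baits, "b0000", [f"S{i}" for i in range(19)])
        mask = cb.build_mask(cb.recurrence(c19, baits, 180), baits, 0.10)
        assert mask.flagged_baits == {"b0000"}

    def test_duplicated_sample_calls_do_not_inflate_recurrence(self, baits):
        once = calls_at_bait(baits, "b0003", ["S1", "S2"])
        doubled = pd.concat([once, once], ignore_index=True)
        a = cb.recurrence(once, baits, 10).table
        b = cb.recurrence(doubled, baits, 10).table
        pd.testing.assert_frame_equal(a, b)

    def test_del_and_dup_pool_for_recurrence(self, baits):
        dels = calls_at_bait(baits, "b0001", ["S1"], cnv_type="DEL")
        dups = calls_at_bait(baits, "b0001", ["S2"], cnv_type="DUP")
        rec = cb.recurrence(pd.concat([dels, dups], ignore_index=True), baits, 4)
        assert rec.table.loc["b0001", "n_samples_called"] == 2

    def test_cohort_smaller_than_observed_samples_errors(self, baits):
        calls = calls_at_bait(baits, "b0000", ["S1", "S2", "S3"])
        with pytest.raises(ValueError, match="cohort_size"):
            cb.recurrence(calls, baits, 2)

    def test_counts_equal_distinct_sample_oracle(self, baits):
        rng = np.random.default_rng(2)
        frames = []
        for _ in range(300):
            b = f"b{rng.integers(40):04d}"
            frames.append(calls_at_bait(baits, b, [f"S{rng.integers(12)}"]))
        calls = pd.concat(frames, ignore_index=True)
        rec = cb.recurrence(calls, baits, 12)
        expect: dict[str, set] = {}
        for r in calls.itertuples():
            for bt in baits.itertuples():
                if bt.chrom == r.chrom and bt.start < r.end and r.start < bt.end:
                    expect.setdefault(bt.bait_id, set()).add(r.sample)
        for bait_id, row in rec.table.iterrows():
            assert row["n_samples_called"] == len(expect.get(bait_id, set()))

    def test_mask_monotone_in_threshold(self, baits):
        rng = np.random.default_rng(5)
        frames = [
            calls_at_bait(baits, f"b{rng.integers(40):04d}", [f"S{rng.integers(20)}"])
            for _ in range(400)
        ]
        rec = cb.recurrence(pd.concat(frames, ignore_index=True), baits, 20)
        masks = [cb.build_mask(rec, baits, t).flagged_baits for t in (0.05, 0.10, 0.15)]
        assert masks[0] >= masks[1] >= masks[2]

    def test_type_split_mode_counts_only_requested_types(self, baits):
        dels = calls_at_bait(baits, "b0001", ["S1", "S2"], cnv_type="DEL")
        dups = calls_at_bait(baits, "b0001", ["S3"], cnv_type="DUP")
        calls = pd.concat([dels, dups], ignore_index=True)
        only_del = cb.recurrence(calls, baits, 10, cnv_types=("DEL",))
        assert only_del.table.loc["b0001", "n_samples_called"] == 2

    def test_region_mode_flags_all_baits_of_a_recurrent_locus(self, baits):
        # one wide call per sample spanning baits b0000-b0002
        frames = [
            pd.DataFrame(
                {"chrom": ["1"], "start": [0], "end": [550], "type": ["DEL"],
                 "sample": [f"S{i}"], "caller": ["x"]}
            )
            for i in range(3)
        ]
        mask = cb.region_recurrence_mask(
            pd.concat(frames, ignore_index=True), baits, cohort_size=10,
            threshold=0.10,
        )
        assert mask.flagged_baits == {"b0000", "b0001", "b0002"}

    def test_union_mask_is_set_union(self, baits):
        def mk(flagged):
            return cb.ProblematicMask(
                caller_id="x", threshold=0.1, flagged_baits=set(flagged),
                merged_regions=pd.DataFrame(columns=["chrom", "start", "end"]),
                fractions=pd.Series(0.2, index=pd.Index(sorted(flagged))),
            )

        u = cb.union_mask([mk({"b0000", "b0001"}), mk({"b0001", "b0005"})], baits)
        assert u.flagged_baits == {"b0000", "b0001", "b0005"}

    def test_empty_recurrence_empty_mask(self, baits):
        rec = cb.recurrence(pd.DataFrame(columns=["chrom", "start", "end", "type", "sample", "caller"]), baits, 10)
        mask = cb.build_mask(rec, baits, 0.10)
        assert not mask.flagged_baits and mask.merged_regions.empty


class TestRpkm:
    def make_matrix(self, baits, values, samples=("S1", "S2")):
        return pd.DataFrame(
            values, index=pd.Index(baits["bait_id"][: len(values)], name="bait_id"),
            columns=list(samples),
        )

    def test_unit_case(self):
        baits = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [1000], "bait_id": ["b0"]}
        )
        m = pd.DataFrame({"S1": [10]}, index=pd.Index(["b0"], name="bait_id"))
        totals = pd.Series({"S1": 1_000_000})
        out = cb.rpkm(m, totals, baits)
        assert out.loc["b0", "S1"] == pytest.approx(10.0)

    def test_scale_invariance(self, baits):
        rng = np.random.default_rng(1)
        m = self.make_matrix(baits, rng.integers(1, 100, size=(10, 2)))
        totals = pd.Series({"S1": 5_000_000, "S2": 7_000_000})
        a = cb.rpkm(m, totals, baits)
        b = cb.rpkm(m * 2, totals * 2, baits)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_elementwise_formula(self, baits):
        rng = np.random.default_rng(3)
        m = self.make_matrix(baits, rng.integers(0, 500, size=(20, 2)))
        totals = pd.Series({"S1": 2_345_678, "S2": 9_876_543})
        out = cb.rpkm(m, totals, baits)
        lengths = dict(zip(baits["bait_id"], baits["end"] - baits["start"]))
        for bid in m.index:
            for s in m.columns:
                expect = m.loc[bid, s] * 1e9 / (lengths[bid] * totals[s])
                assert out.loc[bid, s] == pytest.approx(expect)

    def test_zero_totals_error_names_sample(self, baits):
        m = self.make_matrix(baits, [[1, 2]])
        with pytest.raises(ValueError, match="S2"):
            cb.rpkm(m, pd.Series({"S1": 100, "S2": 0}), baits)


class TestRpkmCv:
    def test_constant_row_cv_zero(self):
        m = pd.DataFrame({"S1": [5.0], "S2": [5.0], "S3": [5.0]},
                         index=pd.Index(["b0"], name="bait_id"))
        assert cb.rpkm_cv(m).loc["b0"] == 0.0

    def test_hand_computed_two_sample_cv(self):
        # (1, 3): mean 2, sd(n-1) = sqrt(2) -> cv = sqrt(2)/2
        m = pd.DataFrame({"S1": [1.0], "S2": [3.0]},
                         index=pd.Index(["b0"], name="bait_id"))
        assert cb.rpkm_cv(m).loc["b0"] == pytest.approx(np.sqrt(2) / 2)

    def test_zero_mean_row_is_missing_not_zero(self):
        m = pd.DataFrame({"S1": [0.0, 1.0], "S2": [0.0, 2.0]},
                         index=pd.Index(["b0", "b1"], name="bait_id"))
        cv = cb.rpkm_cv(m)
        assert np.isnan(cv.loc["b0"]) and cv.loc["b1"] > 0

    def test_single_sample_rejected(self):
        m = pd.DataFrame({"S1": [1.0]}, index=pd.Index(["b0"], name="bait_id"))
        with pytest.raises(ValueError, match="2 samples"):
            cb.rpkm_cv(m)


class TestGcContent:
    def test_simple_sequences(self):
        fasta = {"1": "ATGC" * 25, "2": "G" * 100}
        assert cb.gc_content("1", 0, 100, fasta) == pytest.approx(0.5)
        assert cb.gc_content("2", 10, 20, fasta) == 1.0

    def test_n_bases_excluded_from_denominator(self):
        fasta = {"1": "GGNNNNAA"}
        assert cb.gc_content("1", 0, 8, fasta) == pytest.approx(0.5)
        assert np.isnan(cb.gc_content("1", 2, 6, fasta))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cb.gc_content("1", 0, 50, {"1": "ACGT"})

    def test_random_sequence_matches_per_base_count(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGTN"), size=10_000))
        fasta = {"1": seq}
        for _ in range(50):
            s = int(rng.integers(0, 9000))
            e = s + int(rng.integers(50, 500))
            window = seq[s:e]
            valid = [b for b in window if b != "N"]
            expect = sum(b in "GC" for b in valid) / len(valid)
            assert cb.gc_content("1", s, e, fasta) == pytest.approx(expect)


class TestAnnotate:
    def test_bait_inside_uniform_track(self, baits):
        track = pd.DataFrame(
            {"chrom": ["1", "2"], "start": [0, 0], "end": [10_000, 10_000],
             "score": [1.0, 1.0]}
        )
        feats = annotate(baits.assign(gc=0.5), track, baits.iloc[:0],
                         pd.Series(0.1, index=baits["bait_id"]))
        assert (feats.table["mappability"] == 1.0).all()

    def test_half_and_half_track_averages_to_half(self):
        baits = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [100], "bait_id": ["b0"], "gc": [0.5]}
        )
        track = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [0, 50], "end": [50, 100],
             "score": [0.0, 1.0]}
        )
        feats = annotate(baits, track, baits.iloc[:0],
                         pd.Series(0.1, index=pd.Index(["b0"])))
        assert feats.table.loc["b0", "mappability"] == pytest.approx(0.5)

    def test_uncovered_bait_is_missing(self, baits):
        track = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [150], "score": [0.8]}
        )
        feats = annotate(baits.assign(gc=0.5), track, baits.iloc[:0],
                         pd.Series(0.1, index=baits["bait_id"]))
        assert feats.table.loc["b0000", "mappability"] == pytest.approx(0.8)
        assert feats.table["mappability"].isna().sum() == len(baits) - 1

    def test_random_tracks_match_per_base_oracle(self, baits):
        rng = np.random.default_rng(4)
        edges = np.sort(rng.choice(np.arange(1, 8000), size=30, replace=False))
        rows, prev = [], 0
        for e in edges.tolist() + [8000]:
            rows.append(("1", prev, e, float(rng.random())))
            prev = e
        track = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        feats = annotate(baits.assign(gc=0.5), track, baits.iloc[:0],
                         pd.Series(0.1, index=baits["bait_id"]))
        per_base = np.full(8000, np.nan)
        for r in track.itertuples():
            per_base[r.start:r.end] = r.score
        for b in baits.itertuples():
            if b.chrom != "1":
                continue
            window = per_base[b.start:b.end]
            got = feats.table.loc[b.bait_id, "mappability"]
            if np.isnan(window).all():
                assert np.isnan(got)
            else:
                assert got == pytest.approx(np.nanmean(window))

    def test_segdup_overlap_flag_and_fraction(self, baits):
        segdups = pd.DataFrame(
            {"chrom": ["1"], "start": [50], "end": [250]}
        )  # half of b0000, quarter of b0001
        track = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10_000], "score": [1.0]})
        feats = annotate(baits.assign(gc=0.5), track, segdups,
                         pd.Series(0.1, index=baits["bait_id"]))
        t = feats.table
        assert bool(t.loc["b0000", "segdup_overlap"]) is True
        assert t.loc["b0000", "segdup_fraction"] == pytest.approx(0.5)
        assert t.loc["b0001", "segdup_fraction"] == pytest.approx(0.5)
        assert not t.loc["b0002", "segdup_overlap"]


class TestCompareFeatures:
    def make_features(self, rng, n, shift=0.0):
        idx = pd.Index([f"b{i:04d}" for i in range(n)], name="bait_id")
        return BaitFeatures(
            table=pd.DataFrame(
                {
                    "mappability": np.clip(rng.normal(0.9 - shift, 0.05, n), 0, 1),
                    "gc": np.clip(rng.normal(0.45, 0.05, n), 0, 1),
                    "rpkm_cv": np.abs(rng.normal(0.2 + shift, 0.05, n)),
                },
                index=idx,
            )
        )

    def make_mask(self, flagged):
        return cb.ProblematicMask(
            caller_id="x", threshold=0.1, flagged_baits=set(flagged),
            merged_regions=pd.DataFrame(columns=["chrom", "start", "end"]),
            fractions=pd.Series(dtype=float),
        )

    def test_null_distribution_gives_large_median_p(self):
        rng = np.random.default_rng(0)
        feats = self.make_features(rng, 600)
        mask = self.make_mask([f"b{i:04d}" for i in range(200)])
        comp = compare_features(feats, mask, n_iter=100, seed=1)
        assert (comp.median_p() > 0.05).all()

    def test_complete_separation_every_iteration_significant(self):
        rng = np.random.default_rng(1)
        idx = pd.Index([f"b{i:04d}" for i in range(150)], name="bait_id")
        table = pd.DataFrame(
            {
                "mappability": np.r_[np.full(50, 0.2), np.full(100, 0.9)]
                + rng.normal(0, 0.01, 150),
                "gc": np.r_[np.full(50, 0.2), np.full(100, 0.6)],
                "rpkm_cv": np.r_[np.full(50, 1.0), np.full(100, 0.1)],
            },
            index=idx,
        )
        mask = self.make_mask([f"b{i:04d}" for i in range(50)])
        comp = compare_features(BaitFeatures(table=table), mask, n_iter=20, seed=2)
        assert (comp.iterations["p"] < 0.001).all()

    def test_artifact_direction_lower_mappability_higher_cv(self):
        rng = np.random.default_rng(3)
        feats = self.make_features(rng, 500, shift=0.0)
        flagged = [f"b{i:04d}" for i in range(100)]
        t = feats.table
        t.loc[t.index.isin(flagged), "mappability"] -= 0.3
        t.loc[t.index.isin(flagged), "rpkm_cv"] += 0.3
        comp = compare_features(feats, self.make_mask(flagged), n_iter=50, seed=4)
        assert comp.flagged_means["mappability"] < comp.comparator_means["mappability"]
        assert comp.flagged_means["rpkm_cv"] > comp.comparator_means["rpkm_cv"]

    def test_empty_mask_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="no problematic regions"):
            compare_features(self.make_features(rng, 50), self.make_mask([]), 10, 0)

    def test_seeded_runs_reproduce_exactly(self):
        rng = np.random.default_rng(6)
        feats = self.make_features(rng, 300)
        mask = self.make_mask([f"b{i:04d}" for i in range(40)])
        a = compare_features(feats, mask, n_iter=30, seed=9)
        b = compare_features(feats, mask, n_iter=30, seed=9)
        pd.testing.assert_frame_equal(a.iterations, b.iterations)
        c = compare_features(feats, mask, n_iter=30, seed=10)
        assert not a.iterations["p"].equals(c.iterations["p"])
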