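"""Dataset construction rules: extraction geometry, negative eligibility,
splits, augmentation bounds, composition summaries."""

import numpy as np
import pytest

import hgtsite as h
from hgtsite.dataset import eligible_negative_intervals


def _ref(bases, rid="r"):
    return h.DnaSequence(rid, bases)


def _random_ref(n, seed, rid="r"):
    rng = np.random.default_rng(seed)
    return _ref("".join(rng.choice(list("ACGT"), size=n)), rid)


class TestExtractPositive:
    def test_window_arithmetic(self):
        ref = _random_ref(200, 0)
        sample = h.extract_positive(ref, h.InsertionSite("r", 60))
        assert sample.window_start == 10
        assert sample.sequence.bases == ref.bases[10:110]
        assert sample.label == 1 and sample.origin == "positive"

    @pytest.mark.parametrize("position", [49, 151, 0, 199])
    def test_boundary_sites_are_skipped(self, position, caplog):
        ref = _random_ref(200, 1)
        assert h.extract_positive(ref, h.InsertionSite("r", position)) is None

    def test_position_50_is_the_first_extractable(self):
        ref = _random_ref(200, 2)
        sample = h.extract_positive(ref, h.InsertionSite("r", 50))
        assert sample.window_start == 0

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError):
            h.extract_positive(_random_ref(200, 3), h.InsertionSite("r", 60), window=99)


class TestSampleNegatives:
    def test_centers_respect_min_distance(self):
        ref = _random_ref(200_000, 4)
        sites = [h.InsertionSite("r", 100_000)]
        negs = h.sample_negatives([ref], sites, 200, seed=0)
        centers = np.array([s.window_start + 50 for s in negs])
        assert (np.abs(centers - 100_000) >= 10_000).all()
        assert all(s.label == 0 for s in negs)

    def test_matches_brute_force_eligibility_mask(self):
        ref_len = 30_000
        sites = [h.InsertionSite("r", p) for p in (5_000, 6_000, 22_000)]
        ref = _random_ref(ref_len, 5)
        min_dist = 5_000
        # brute force: every center individually
        positions = np.arange(ref_len)
        mask = (positions >= 50) & (positions <= ref_len - 50)
        for s in sites:
            mask &= np.abs(positions - s.position) >= min_dist
        eligible = set(np.flatnonzero(mask))
        intervals = eligible_negative_intervals(ref_len, [s.position for s in sites], min_dist)
        from_intervals = {c for a, b in intervals for c in range(a, b)}
        assert from_intervals == eligible
        negs = h.sample_negatives([ref], sites, 300, min_dist=min_dist, seed=1)
        assert {s.window_start + 50 for s in negs} <= eligible

    def test_deterministic_and_distinct(self):
        ref = _random_ref(60_000, 6)
        sites = [h.InsertionSite("r", 100)]
        a = h.sample_negatives([ref], sites, 100, seed=9)
        b = h.sample_negatives([ref], sites, 100, seed=9)
        assert [s.window_start for s in a] == [s.window_start for s in b]
        assert len({s.window_start for s in a}) == 100

    def test_insufficient_territory(self):
        ref = _random_ref(5_000, 7)
        with pytest.raises(ValueError, match="centers"):
            h.sample_negatives([ref], [h.InsertionSite("r", 2_500)], 10, min_dist=10_000)


class TestSplit:
    def test_exact_sizes(self):
        samples = h.sample_negatives([_random_ref(300_000, 8)], [], 1000, seed=0)
        split = h.split_dataset(h.SampleSet(samples), seed=3)
        counts = {k: split.split.count(k) for k in ("train", "validation", "test")}
        assert counts == {"train": 800, "validation": 100, "test": 100}

    def test_small_set_rounding(self):
        samples = h.sample_negatives([_random_ref(30_000, 9)], [], 10, seed=0)
        split = h.split_dataset(h.SampleSet(samples), seed=0)
        counts = {k: split.split.count(k) for k in ("train", "validation", "test")}
        assert counts == {"train": 8, "validation": 1, "test": 1}

    def test_deterministic(self):
        samples = h.sample_negatives([_random_ref(50_000, 10)], [], 50, seed=0)
        a = h.split_dataset(h.SampleSet(samples), seed=11)
        b = h.split_dataset(h.SampleSet(samples), seed=11)
        assert a.split == b.split

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            h.split_dataset(h.SampleSet([]))


class TestAugmentation:
    def test_shift_offsets_within_bounds(self):
        ref = _random_ref(400, 11)
        site = h.InsertionSite("r", 200)
        rng = np.random.default_rng(0)
        offsets = set()
        for _ in range(200):
            s = h.augment_shift(ref, site, max_shift=5, seed=rng.integers(2**31))
            delta = s.window_start - 150
            offsets.add(delta)
            assert 1 <= abs(delta) <= 5
            assert s.origin == "augmented-shift" and s.label == 1
            assert s.sequence.bases == ref.bases[s.window_start : s.window_start + 100]
        assert offsets == {d for d in range(-5, 6) if d != 0}

    def test_shift_zero_returns_canonical(self):
        ref = _random_ref(400, 12)
        s = h.augment_shift(ref, h.InsertionSite("r", 200), max_shift=0, seed=0)
        assert s.window_start == 150 and s.origin == "positive"

    def test_substitution_hamming_bounds(self):
        ref = _random_ref(300_000, 13)
        sample = h.sample_negatives([ref], [], 1, seed=0)[0]
        rng = np.random.default_rng(1)
        for _ in range(1_000):
            out = h.augment_substitute(sample, max_changes=10, seed=rng.integers(2**31))
            diff = [
                (a, b) for a, b in zip(sample.sequence.bases, out.sequence.bases) if a != b
            ]
            assert 1 <= len(diff) <= 10
            assert out.label == sample.label

    def test_substitution_never_restores_original_base(self):
        ref = _random_ref(1_000, 14)
        sample = h.sample_negatives([ref], [], 1, seed=0)[0]
        out = h.augment_substitute(sample, max_changes=100, seed=5)
        for a, b in zip(sample.sequence.bases, out.sequence.bases):
            if a != b:
                assert b in set("ACGT") - {a}

    def test_substitution_zero_is_identity(self):
        ref = _random_ref(1_000, 15)
        sample = h.sample_negatives([ref], [], 1, seed=0)[0]
        out = h.augment_substitute(sample, max_changes=0, seed=0)
        assert out.sequence.bases == sample.sequence.bases

    def test_epoch_augmenter_preserves_labels_and_lengths(self, small_sim):
        _, sample_set, refs, _ = small_sim
        augmenter = h.TrainingAugmenter(refs)
        seqs = augmenter.augment_epoch(sample_set.samples, np.random.default_rng(0))
        assert len(seqs) == len(sample_set)
        assert all(len(s) == 100 for s in seqs)


class TestOverlapInvariant:
    def test_no_positive_negative_window_overlap(self, small_sim):
        _, sample_set, _, _ = small_sim
        pos = [(s.ref_id, s.window_start) for s in sample_set if s.label == 1]
        neg = [(s.ref_id, s.window_start) for s in sample_set if s.label == 0]
        for rid_p, p in pos:
            for rid_n, q in neg:
                if rid_p == rid_n:
                    assert p + 100 <= q or q + 100 <= p


class TestCompositionSummary:
    def test_simple_fractions(self):
        summary = h.composition_summary(["A", "A", "B"])
        assert list(summary.table["label"]) == ["A", "B"]
        np.testing.assert_allclose(summary.table["percentage"], [200 / 3, 100 / 3])
        assert summary.table["percentage"].sum() == pytest.approx(100)

    def test_single_label(self):
        summary = h.composition_summary(["only"])
        assert summary.table["percentage"].iloc[0] == 100
        assert summary.std_percent == 0

    def test_uniform_distribution_matches_tally(self):
        rng = np.random.default_rng(0)
        labels = [f"sp{i}" for i in rng.integers(0, 10, size=1000)]
        summary = h.composition_summary(labels)
        tally = {lab: labels.count(lab) for lab in set(labels)}
        for _, row in summary.table.iterrows():
            assert row["count"] == tally[row["label"]]
            assert row["percentage"] == pytest.approx(100 * tally[row["label"]] / 1000)

    def test_missing_labels_excluded(self):
        sites = [
            h.InsertionSite("r", 1, species="a"),
            h.InsertionSite("r", 2, species=None),
            h.InsertionSite("r", 3, species="b"),
        ]
        summary = h.composition_summary(sites, rank="species")
        assert summary.n_missing == 1
        assert set(summary.table["label"]) == {"a", "b"}


class TestSerialization:
    def test_sample_set_round_trip(self, small_sim, tmp_path):
        _, sample_set, _, _ = small_sim
        split = h.split_dataset(sample_set, seed=0)
        path = tmp_path / "set.tsv.gz"
        split.to_tsv(path)
        back = h.SampleSet.from_tsv(path)
        assert back.sequences() == split.sequences()
        assert back.split == split.split
        np.testing.assert_array_equal(back.labels(), split.labels())

    def test_sites_round_trip(self, tmp_path):
        sites = [h.InsertionSite("r1", 5, "sp", "g"), h.InsertionSite("r2", 7)]
        path = tmp_path / "sites.tsv"
        h.write_sites_tsv(sites, path)
        back = h.read_sites_tsv(path)
        assert back[0] == sites[0]
        assert back[1].species is None
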