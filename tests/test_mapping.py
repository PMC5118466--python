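"""Tag-to-site mapping, multi-map suppression, pooling, wiggle round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inseqtools.mapping import (
    MULTI,
    UNMAPPED,
    SiteCountTrack,
    TagMapper,
    count_sites,
    pool_tracks,
    read_wig,
    write_wig,
)
from inseqtools.reference import (
    ReferenceIndex,
    Replicon,
    reverse_complement,
)

from conftest import random_genome


def fwd_tag(index, ordinal, tag_len=16):
    site = index.sites[ordinal]
    seq = index.replicons[site.replicon_id].sequence
    return seq[site.position : site.position + tag_len]


def rev_tag(index, ordinal, tag_len=16):
    site = index.sites[ordinal]
    seq = index.replicons[site.replicon_id].sequence
    return reverse_complement(seq[site.position - (tag_len - 2) : site.position + 2])


class TestMapTag:
    def test_forward_tag_maps_to_its_site(self, toy_index):
        mapper = TagMapper(toy_index)
        ordinal = toy_index.n_sites // 2
        assert mapper.map_tag(fwd_tag(toy_index, ordinal)) == ordinal

    def test_reverse_tag_maps_to_same_canonical_site(self, toy_index):
        """Both orientations of a TA site resolve to the forward-strand
        position: insertion counting is orientation-blind."""
        mapper = TagMapper(toy_index)
        ordinal = toy_index.n_sites // 2
        assert mapper.map_tag(rev_tag(toy_index, ordinal)) == ordinal

    def test_repeat_tag_suppressed_as_multi(self, rng):
        block = random_genome(rng, 120)
        seq = random_genome(rng, 80) + block + random_genome(rng, 80) + block
        idx = ReferenceIndex([Replicon("r", seq, "chromosome")], [])
        mapper = TagMapper(idx)
        # an interior site of the first copy
        inner = [
            o for o, s in enumerate(idx.sites)
            if 80 + 14 <= s.position <= 80 + 120 - 16
        ]
        assert inner, "repeat block must contain interior TA sites"
        assert mapper.map_tag(fwd_tag(idx, inner[0])) == MULTI

    def test_foreign_tag_unmapped(self, toy_index):
        assert TagMapper(toy_index).map_tag("TA" + "C" * 14) == UNMAPPED

    def test_short_tag_must_be_unique_at_its_own_length(self, toy_index):
        mapper = TagMapper(toy_index)
        ordinal = toy_index.n_sites // 2
        t15 = fwd_tag(toy_index, ordinal)[:15]
        hit = mapper.map_tag(t15)
        assert hit in (ordinal, MULTI)  # unique at 15 bp or suppressed

    def test_long_tag_compared_over_first_tag_len_bases(self, toy_index):
        mapper = TagMapper(toy_index)
        ordinal = toy_index.n_sites // 2
        long_tag = fwd_tag(toy_index, ordinal) + "ACGTACGT"
        assert mapper.map_tag(long_tag) == ordinal

    def test_non_ta_tag_rejected(self, toy_index):
        with pytest.raises(ValueError):
            TagMapper(toy_index).map_tag("CCGGCCGGCCGGCCGG")


class TestCountSites:
    def test_three_tags_one_site(self, toy_index):
        ordinal = 3
        track = count_sites([fwd_tag(toy_index, ordinal)] * 3, toy_index)
        assert track.counts[ordinal] == 3
        assert track.counts.sum() == 3 == track.reads_mapped

    def test_totals_partition_accepted_tags(self, toy_index):
        tags = (
            [fwd_tag(toy_index, 1)] * 4
            + ["TA" + "G" * 14] * 2  # unmapped
        )
        track = count_sites(tags, toy_index)
        assert track.reads_mapped + track.reads_multi + track.reads_unmapped == len(tags)

    def test_empty_stream_all_zero(self, toy_index):
        track = count_sites([], toy_index)
        assert track.counts.sum() == 0
        assert (track.reads_mapped, track.reads_multi, track.reads_unmapped) == (0, 0, 0)


class TestPoolTracks:
    def test_zero_track_is_identity(self, toy_index, rng):
        t = SiteCountTrack("c", rng.integers(0, 9, toy_index.n_sites))
        z = SiteCountTrack.zeros(toy_index)
        assert np.array_equal(pool_tracks([t, z]).counts, t.counts)

    def test_commutative(self, toy_index, rng):
        a = SiteCountTrack("a", rng.integers(0, 9, toy_index.n_sites))
        b = SiteCountTrack("b", rng.integers(0, 9, toy_index.n_sites))
        assert np.array_equal(pool_tracks([a, b]).counts, pool_tracks([b, a]).counts)

    def test_index_mismatch_fatal(self, toy_index):
        a = SiteCountTrack("a", np.zeros(toy_index.n_sites, dtype=int))
        b = SiteCountTrack("b", np.zeros(toy_index.n_sites + 1, dtype=int))
        with pytest.raises(ValueError):
            pool_tracks([a, b])

    def test_pooled_replicates_match_triple_depth_in_expectation(self, default_sim):
        """Mean pooled neutral-site count over 20 seeds matches a single run
        at triple depth, within 3 standard errors of the seed spread."""
        from inseqtools.simulate import simulate_selection, site_fitness

        config, index, truth = default_sim
        neutral = site_fitness(index, truth, "VMM") == 1.0
        _, expected15 = simulate_selection(index, truth, "VMM", depth=15, seed=0)
        means = []
        for seed in range(20):
            reps = [
                simulate_selection(index, truth, "VMM", depth=5, seed=1000 + 3 * seed + r)[0]
                for r in range(3)
            ]
            pooled = pool_tracks([SiteCountTrack("r", c) for c in reps])
            means.append(pooled.counts[neutral].mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        exp = expected15[neutral].mean()
        assert abs(np.mean(means) - exp) <= max(3 * se, 1e-9)


class TestWiggle:
    def test_one_based_conversion(self, tmp_path, rng):
        seq = "C" * 41 + "TA" + "C" * 40
        idx = ReferenceIndex([Replicon("r", seq, "chromosome")], [])
        track = SiteCountTrack.zeros(idx)
        track.counts[idx.site_lookup[("r", 41)]] = 7
        path = tmp_path / "t.wig"
        write_wig(track, idx, path)
        lines = path.read_text().splitlines()
        assert lines == ["variableStep chrom=r", "42 7"]

    def test_all_zero_track_header_only(self, toy_index, tmp_path):
        path = tmp_path / "z.wig"
        write_wig(SiteCountTrack.zeros(toy_index), toy_index, path)
        assert path.read_text() == "variableStep chrom=chrom\n"

    @pytest.mark.parametrize("seed", [0, 1, 17, 2**31 - 1])
    def test_roundtrip_identity_random_tracks(self, seed, toy_index, tmp_path):
        rng = np.random.default_rng(seed)
        track = SiteCountTrack("c", rng.poisson(3, toy_index.n_sites))
        path = tmp_path / f"rt{seed}.wig"
        write_wig(track, toy_index, path)
        back = read_wig(path, toy_index)
        assert np.array_equal(back.counts, track.counts)

    def test_non_ta_position_fatal(self, tmp_path):
        idx = ReferenceIndex([Replicon("r", "CCTACC", "chromosome")], [])
        path = tmp_path / "bad.wig"
        path.write_text("variableStep chrom=r\n1 5\n")  # position 1 is a C
        with pytest.raises(ValueError, match="not a TA site"):
            read_wig(path, idx)
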