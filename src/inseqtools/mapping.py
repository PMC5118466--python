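"""Tag-to-site mapping with multi-map suppression, and wiggle tracks.

Accepted junction tags are matched exactly against the precomputed site
tags of both orientations; a tag matching exactly one genomic locus is
assigned to its TA site, a tag matching more than one is discarded (the
behaviour of bowtie's suppress-multiple-alignments mode, which leaves
repeated regions unassayed).  Per-site counts for one condition form a
:class:`SiteCountTrack`, serialisable as a variableStep wiggle file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reference import ReferenceIndex
from .trimming import TagRead

MULTI = "multi"
UNMAPPED = "unmapped"

__all__ = [
    "SiteCountTrack",
    "TagMapper",
    "map_tag",
    "count_sites",
    "pool_tracks",
    "write_wig",
    "read_wig",
]


@dataclass
class SiteCountTrack:
    """Dense per-TA-site read counts for one condition.

    ``sum(counts) == reads_mapped``; counts are aligned to the reference's
    global site ordinals.
    """

    condition: str
    counts: np.ndarray
    reads_mapped: int = 0
    reads_multi: int = 0
    reads_unmapped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative site counts")

    @classmethod
    def zeros(cls, index: ReferenceIndex, condition: str = "") -> "SiteCountTrack":
        return cls(condition, np.zeros(index.n_sites, dtype=np.int64))


class TagMapper:
    """Exact-match lookup from a junction tag to a unique TA site ordinal.

    Tags longer than the indexed ``tag_len`` are compared over their first
    ``tag_len`` bases; shorter accepted tags are compared over their own
    length and must still be unique at that length, else multi.  Lookup
    tables per query length are built lazily.
    """

    def __init__(self, index: ReferenceIndex, tag_len: int = 16):
        self.index = index
        self.tag_len = tag_len
        self._tables: dict[int, dict[str, int | str]] = {}

    def _table(self, length: int) -> dict[str, int | str]:
        table = self._tables.get(length)
        if table is not None:
            return table
        table = {}
        for ordinal, (fwd, rev) in enumerate(self.index.site_tags(self.tag_len)):
            for tag in (fwd, rev):
                if tag is None:
                    continue
                key = tag[:length]
                prev = table.get(key)
                if prev is None:
                    table[key] = ordinal
                elif prev != ordinal or (fwd and rev and fwd[:length] == rev[:length]):
                    table[key] = MULTI
        # A palindromic site whose two orientations collapse to one key still
        # represents two alignments; handled above by the fwd==rev clause.
        self._tables[length] = table
        return table

    def map_tag(self, tag: str) -> int | str:
        """Return the unique site ordinal, ``"multi"`` or ``"unmapped"``."""
        if not tag.startswith("TA"):
            raise ValueError("tag must start with TA")
        length = min(len(tag), self.tag_len)
        hit = self._table(length).get(tag[:length])
        if hit is None:
            return UNMAPPED
        return hit


def map_tag(tag: str, index: ReferenceIndex, tag_len: int = 16) -> int | str:
    """Convenience wrapper; for many tags build one :class:`TagMapper`."""
    return TagMapper(index, tag_len).map_tag(tag)


def count_sites(
    tags: Iterable[TagRead | str],
    index: ReferenceIndex,
    tag_len: int = 16,
    condition: str = "",
) -> SiteCountTrack:
    """Accumulate uniquely mapped tags into a per-site count track.

    Totals partition the accepted tags:
    ``reads_mapped + reads_multi + reads_unmapped == len(tags)``.
    """
    mapper = TagMapper(index, tag_len)
    track = SiteCountTrack.zeros(index, condition)
    for t in tags:
        tag = t.tag if isinstance(t, TagRead) else t
        hit = mapper.map_tag(tag)
        if hit == MULTI:
            track.reads_multi += 1
        elif hit == UNMAPPED:
            track.reads_unmapped += 1
        else:
            track.counts[hit] += 1
            track.reads_mapped += 1
    return track


def pool_tracks(tracks: Sequence[SiteCountTrack], condition: str | None = None) -> SiteCountTrack:
    """Element-wise sum of replicate tracks on an identical index."""
    if not tracks:
        raise ValueError("no tracks to pool")
    n = len(tracks[0].counts)
    if any(len(t.counts) != n for t in tracks):
        raise ValueError("track length mismatch: tracks built on different indexes")
    return SiteCountTrack(
        condition if condition is not None else tracks[0].condition,
        sum((t.counts for t in tracks), np.zeros(n, dtype=np.int64)),
        reads_mapped=sum(t.reads_mapped for t in tracks),
        reads_multi=sum(t.reads_multi for t in tracks),
        reads_unmapped=sum(t.reads_unmapped for t in tracks),
    )


def write_wig(track: SiteCountTrack, index: ReferenceIndex, path: str | Path) -> None:
    """variableStep wiggle: one block per replicon, 1-based T positions,
    zero-count sites omitted.  Headers are written even for empty blocks."""
    with open(path, "w") as fh:
        for rep_id, sl in index.replicon_slices.items():
            fh.write(f"variableStep chrom={rep_id}\n")
            for ordinal in range(sl.start, sl.stop):
                c = int(track.counts[ordinal])
                if c:
                    fh.write(f"{index.sites[ordinal].position + 1} {c}\n")


def read_wig(path: str | Path, index: ReferenceIndex, condition: str = "") -> SiteCountTrack:
    """Inverse of :func:`write_wig`.  A position that is not a TA site of the
    index is fatal — it means the track and index do not match."""
    track = SiteCountTrack.zeros(index, condition)
    rep_id = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("variableStep"):
                rep_id = dict(
                    kv.split("=", 1) for kv in line.split()[1:]
                )["chrom"]
                if rep_id not in index.replicons:
                    raise ValueError(f"wig replicon {rep_id!r} not in index")
                continue
            if rep_id is None:
                raise ValueError("wig data line before any variableStep header")
            pos_str, count_str = line.split()
            pos = int(pos_str) - 1
            ordinal = index.site_lookup.get((rep_id, pos))
            if ordinal is None:
                raise ValueError(
                    f"wig position {pos + 1} on {rep_id!r} is not a TA site"
                )
            track.counts[ordinal] = int(count_str)
    track.reads_mapped = int(track.counts.sum())
    return track


def write_counts_tsv(track: SiteCountTrack, index: ReferenceIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("replicon\tposition\tcount\n")
        for site, c in zip(index.sites, track.counts):
            fh.write(f"{site.replicon_id}\t{site.position}\t{int(c)}\n")
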