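"""Reference genome model for mariner transposon insertion sequencing.

The mariner (himar1) transposon inserts exclusively at TA dinucleotides, so
the universe of assayable positions is the ordered list of TA sites per
replicon.  This module builds an indexed model of a (multi-replicon) genome:
replicons, gene models, TA sites, gene<->site assignment, and per-site
*assayability* — whether a junction tag anchored at the site maps uniquely,
the automated analogue of suppressing multi-mapping alignments and of manual
curation of duplicated sequence.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "Replicon",
    "TaSite",
    "GeneModel",
    "ReferenceIndex",
    "enumerate_ta_sites",
    "load_reference",
    "site_assayability",
    "flag_duplicated_genes",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REPLICON_KINDS = ("chromosome", "plasmid")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def enumerate_ta_sites(sequence: str) -> list[int]:
    """0-based positions p with ``sequence[p:p+2] == "TA"``, ascending.

    TA cannot overlap itself, so a plain scan suffices; the count is
    strand-symmetric because TA is its own reverse complement.
    """
    positions: list[int] = []
    p = sequence.find("TA")
    while p != -1:
        positions.append(p)
        p = sequence.find("TA", p + 2)
    return positions


@dataclass(frozen=True)
class Replicon:
    id: str
    sequence: str
    kind: str  # chromosome | plasmid — declared, never inferred from size

    def __post_init__(self) -> None:
        if self.kind not in REPLICON_KINDS:
            raise ValueError(
                f"unknown replicon kind {self.kind!r} for {self.id!r}; "
                f"expected one of {REPLICON_KINDS}"
            )
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"replicon {self.id!r}: non-ACGTN characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TaSite:
    replicon_id: str
    position: int  # 0-based position of the T on the forward strand
    ordinal: int  # rank within the replicon, by position
    assayable: bool = True


@dataclass
class GeneModel:
    locus: str
    replicon_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    product: str = ""
    riley_key: str = ""
    sites: list[int] = field(default_factory=list)  # global site ordinals
    duplicated: bool = False

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def has_ta(self) -> bool:
        return self.n_sites > 0


class ReferenceIndex:
    """Replicons, gene models and the genome-wide ordered TA-site list.

    Site ordinals are global: sites are ordered by (replicon input order,
    position).  ``site_lookup`` maps (replicon_id, position) to the global
    ordinal; per-replicon slices are available through ``replicon_slices``.
    """

    def __init__(self, replicons: Sequence[Replicon], genes: Sequence[GeneModel]):
        self.replicons: dict[str, Replicon] = {r.id: r for r in replicons}
        if len(self.replicons) != len(replicons):
            raise ValueError("duplicate replicon ids")
        self.genes: dict[str, GeneModel] = {}

        self.sites: list[TaSite] = []
        self.replicon_slices: dict[str, slice] = {}
        self.site_lookup: dict[tuple[str, int], int] = {}
        self._positions: dict[str, list[int]] = {}
        for rep in replicons:
            start = len(self.sites)
            positions = enumerate_ta_sites(rep.sequence)
            self._positions[rep.id] = positions
            for k, p in enumerate(positions):
                self.sites.append(TaSite(rep.id, p, ordinal=k))
                self.site_lookup[(rep.id, p)] = start + k
            self.replicon_slices[rep.id] = slice(start, len(self.sites))

        for gene in genes:
            self._add_gene(gene)

        self._tag_len: int | None = None
        self._site_tags: list[tuple[str | None, str | None]] | None = None
        self._tag_counts: Counter[str] | None = None

    # ------------------------------------------------------------------ genes
    def _add_gene(self, gene: GeneModel) -> None:
        rep = self.replicons.get(gene.replicon_id)
        if rep is None:
            raise ValueError(
                f"gene {gene.locus!r}: replicon {gene.replicon_id!r} not in FASTA"
            )
        if gene.end <= gene.start:
            raise ValueError(
                f"gene {gene.locus!r}: malformed coordinates "
                f"start={gene.start} end={gene.end}"
            )
        if gene.start < 0 or gene.end > rep.length:
            raise ValueError(
                f"gene {gene.locus!r}: span [{gene.start},{gene.end}) exceeds "
                f"replicon {rep.id!r} length {rep.length}"
            )
        if gene.locus in self.genes:
            raise ValueError(f"duplicate locus {gene.locus!r}")
        # A TA site belongs to the gene only if both T and A fall inside the
        # span; gene strand is ignored (mariner disrupts either orientation).
        positions = self._positions[gene.replicon_id]
        offset = self.replicon_slices[gene.replicon_id].start
        lo = bisect.bisect_left(positions, gene.start)
        hi = bisect.bisect_right(positions, gene.end - 2, lo=lo)
        gene.sites = [offset + k for k in range(lo, hi)]
        self.genes[gene.locus] = gene

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def replicon_kind(self, locus: str) -> str:
        return self.replicons[self.genes[locus].replicon_id].kind

    # ------------------------------------------------------------------- tags
    def site_tags(self, tag_len: int = 16) -> list[tuple[str | None, str | None]]:
        """Per-site (forward, reverse) junction tags of length ``tag_len``.

        The forward tag is the TA plus the next ``tag_len - 2`` bases; the
        reverse tag is the TA plus the preceding ``tag_len - 2`` bases,
        reverse-complemented (so both start with "TA").  An orientation too
        close to the replicon end, or containing N, is None.
        """
        if self._site_tags is not None and self._tag_len == tag_len:
            return self._site_tags
        tags: list[tuple[str | None, str | None]] = []
        for site in self.sites:
            seq = self.replicons[site.replicon_id].sequence
            p = site.position
            fwd: str | None = None
            rev: str | None = None
            if p + tag_len <= len(seq):
                fwd = seq[p : p + tag_len]
                if "N" in fwd:
                    fwd = None
            if p - (tag_len - 2) >= 0:
                rev = reverse_complement(seq[p - (tag_len - 2) : p + 2])
                if "N" in rev:
                    rev = None
            tags.append((fwd, rev))
        self._tag_len = tag_len
        self._site_tags = tags
        self._tag_counts = Counter(
            t for pair in tags for t in pair if t is not None
        )
        return tags

    def tag_counts(self, tag_len: int = 16) -> Counter[str]:
        self.site_tags(tag_len)
        assert self._tag_counts is not None
        return self._tag_counts


def site_assayability(index: ReferenceIndex, tag_len: int = 16) -> list[bool]:
    """Mark each TA site assayable iff at least one of its two junction tags
    occurs exactly once among all site tags genome-wide (both orientations).

    Sites inside exact sequence duplications lose both orientations and
    become unassayable, mirroring the penalty bowtie's multi-alignment
    suppression imposes on repeated regions.
    """
    if tag_len < 15:
        raise ValueError("tag_len must be >= 15")
    tags = index.site_tags(tag_len)
    counts = index.tag_counts(tag_len)
    flags: list[bool] = []
    for site, (fwd, rev) in zip(index.sites, tags):
        ok = any(t is not None and counts[t] == 1 for t in (fwd, rev))
        site.assayable = ok
        flags.append(ok)
    return flags


def flag_duplicated_genes(
    index: ReferenceIndex, min_assayable_frac: float = 0.5
) -> list[str]:
    """Flag genes whose assayable-site fraction falls below the threshold.

    Duplicated genes are reported but never assigned a growth phenotype
    downstream.  Requires :func:`site_assayability` to have run.  Returns the
    flagged loci.
    """
    flagged = []
    for gene in index.genes.values():
        if gene.n_sites == 0:
            gene.duplicated = False
            continue
        frac = sum(index.sites[o].assayable for o in gene.sites) / gene.n_sites
        gene.duplicated = frac < min_assayable_frac
        if gene.duplicated:
            flagged.append(gene.locus)
    return flagged


# ---------------------------------------------------------------------- input

def _parse_gff3(path: Path) -> Iterable[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    seen: set[str] = set()
    for ftype in ("gene", "CDS"):
        for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
            locus = (
                feat.attributes.get("locus_tag", [None])[0]
                or feat.attributes.get("ID", [None])[0]
                or feat.id
            )
            if locus in seen:
                continue
            seen.add(locus)
            yield GeneModel(
                locus=locus,
                replicon_id=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based closed -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                product=feat.attributes.get("product", [""])[0],
                riley_key=feat.attributes.get("riley_key", [""])[0],
            )


def _parse_gene_tsv(path: Path) -> Iterable[GeneModel]:
    """7-column TSV: locus, replicon, start, end, strand, product, riley_key.

    Coordinates are 1-based closed, matching GFF convention.
    """
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0].lower() == "locus":
                continue
            locus, replicon, start, end, strand, product, riley = (parts + [""] * 7)[:7]
            yield GeneModel(
                locus=locus,
                replicon_id=replicon,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                product=product,
                riley_key=riley,
            )


def load_reference(
    genome_fasta: str | Path,
    annotation: str | Path,
    replicon_kinds: Mapping[str, str],
) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` from a multi-FASTA and a GFF3/TSV.

    ``replicon_kinds`` maps every replicon id to "chromosome" or "plasmid";
    the kind is declared, never inferred.  Errors (missing replicon, span
    outside bounds, end <= start) are fatal and name the offending locus.
    """
    genome_fasta = Path(genome_fasta)
    annotation = Path(annotation)
    replicons = []
    for rec in SeqIO.parse(str(genome_fasta), "fasta"):
        try:
            kind = replicon_kinds[rec.id]
        except KeyError:
            raise ValueError(f"no replicon kind declared for {rec.id!r}") from None
        replicons.append(Replicon(rec.id, str(rec.seq).upper(), kind))
    if not replicons:
        raise ValueError(f"no FASTA records in {genome_fasta}")

    if annotation.suffix.lower() in {".gff", ".gff3"}:
        genes = list(_parse_gff3(annotation))
    else:
        genes = list(_parse_gene_tsv(annotation))
    return ReferenceIndex(replicons, genes)


def write_site_index(index: ReferenceIndex, path: str | Path) -> None:
    """Site index TSV: replicon, position (0-based), ordinal, assayable."""
    with open(path, "w") as fh:
        fh.write("replicon\tposition\tordinal\tassayable\n")
        for site in index.sites:
            fh.write(
                f"{site.replicon_id}\t{site.position}\t{site.ordinal}\t"
                f"{int(site.assayable)}\n"
            )
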