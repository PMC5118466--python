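"""Synthetic mutant pools: genomes, selection, and raw INSeq reads.

The generator plants a complete ground truth so every pipeline stage can be
checked end to end:

* a multi-replicon genome (one chromosome plus optional plasmids) with a
  known gene layout, planted exact-duplicate gene pairs, and planted genes
  without any TA dinucleotide;
* per-gene true growth states under two conditions, with a controlled
  overlap so the planted core/condition-specific partition is known;
* selection over ``G`` generations of competitive growth: a mutant whose
  insertion sits in a gene of fitness ``w`` changes abundance by
  ``2**(G * (w - 1))`` relative to a neutral mutant (intergenic insertions
  are neutral; insertions in overlapping genes take the minimum fitness);
* reads with the library structure [IR terminus][TA + tag][adapter], with
  optional planted junk reads (no IR / no TA / too short).

All randomness flows from a single seed; reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hmm import ES, GD, GA, NE
from .reference import GeneModel, ReferenceIndex, Replicon, enumerate_ta_sites

__all__ = ["SimConfig", "SimTruth", "simulate_genome", "simulate_selection", "emit_reads"]

_BASES = np.array(list("ACGT"))

# Default fitness per true growth state: essential mutants die (w=0), growth
# defective mutants grow at half rate, growth advantaged slightly faster.
DEFAULT_FITNESS = {ES: 0.0, GD: 0.5, NE: 1.0, GA: 1.1}


@dataclass
class SimConfig:
    n_genes: int = 200
    n_plasmid_genes: int = 20  # carved out of n_genes, placed on the plasmid
    gene_len: tuple[int, int] = (350, 500)
    intergenic_len: int = 60
    es_frac: float = 0.08
    gd_frac: float = 0.03
    ga_frac: float = 0.01
    cfg_frac: float = 0.5  # fraction of impaired genes impaired in BOTH conditions
    dup_frac: float = 0.02  # fraction of genes planted as exact duplicate pairs
    no_ta_frac: float = 0.005
    min_ta_per_gene: int = 5
    generations: int = 16  # selection spans roughly 15-18 generations
    depth: float = 25.0  # mean reads per TA site
    fitness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FITNESS))
    ir_terminus: str = "ACAGGTTGGATGATAAGTCCCCGGTCT"
    adapter: str = "CTGTCTCTTATACACATCT"
    tag_len: int = 16
    junk_no_ir: float = 0.0
    junk_no_ta: float = 0.0
    junk_short: float = 0.0
    condition_labels: tuple[str, str] = ("VMM", "TY")


@dataclass
class SimTruth:
    states: dict[str, dict[str, str]]  # condition -> locus -> true state
    fitness: dict[str, float]
    generations: int
    duplicate_pairs: list[tuple[str, str]]
    no_ta_genes: list[str]

    def partition(self, condition_a: str, condition_b: str, loci) -> dict[str, str]:
        """Planted GI/VGI/TGI/GN label (chromosome naming) per locus."""
        out = {}
        for locus in loci:
            a = self.states[condition_a][locus] in (ES, GD)
            b = self.states[condition_b][locus] in (ES, GD)
            out[locus] = "GI" if a and b else "VGI" if a else "TGI" if b else "GN"
        return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _seq_without_ta(rng: np.random.Generator, n: int) -> str:
    seq = list(_random_seq(rng, n))
    for i in range(len(seq) - 1):
        if seq[i] == "T" and seq[i + 1] == "A":
            seq[i + 1] = "C"
    return "".join(seq)


def _gene_seq(rng: np.random.Generator, n: int, min_ta: int) -> str:
    for _ in range(100):
        seq = _random_seq(rng, n)
        if len(enumerate_ta_sites(seq)) >= min_ta:
            return seq
    raise ValueError(f"cannot place {min_ta} TA sites in a {n} bp gene")


def simulate_genome(
    config: SimConfig, seed: int
) -> tuple[ReferenceIndex, SimTruth]:
    """Deterministically build a genome + truth table for a seed.

    True states are planted by assignment (exact fractions, not sampling):
    the impaired set of each condition has ``es_frac + gd_frac`` of the
    genes, of which ``cfg_frac`` are shared between conditions (the planted
    core functional genome); ``ga_frac`` genes per condition are growth
    advantaged.  Duplicate pairs are exact sequence copies; planted no-TA
    genes contain no TA dinucleotide inside their span.
    """
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    if config.gene_len[0] < 2:
        raise ValueError("genes must be at least 2 bp to hold a TA site")
    rng = np.random.default_rng(seed)
    n = config.n_genes
    loci = [f"SG{i:04d}" for i in range(n)]

    n_dup_pairs = int(round(config.dup_frac * n / 2))
    n_no_ta = int(round(config.no_ta_frac * n))
    special = rng.choice(n, size=2 * n_dup_pairs + n_no_ta, replace=False)
    dup_pairs = [
        (loci[special[2 * i]], loci[special[2 * i + 1]]) for i in range(n_dup_pairs)
    ]
    no_ta = [loci[j] for j in special[2 * n_dup_pairs :]]
    special_set = set(special.tolist())

    # --- true states, planted on the non-special genes
    regular = [i for i in range(n) if i not in special_set]
    rng.shuffle(regular)
    n_imp = int(round((config.es_frac + config.gd_frac) * n))
    n_common = int(round(config.cfg_frac * n_imp))
    n_only = n_imp - n_common
    common = regular[:n_common]
    only_a = regular[n_common : n_common + n_only]
    only_b = regular[n_common + n_only : n_common + 2 * n_only]
    n_ga = int(round(config.ga_frac * n))
    rest = regular[n_common + 2 * n_only :]
    ga_a = rest[:n_ga]
    ga_b = rest[n_ga : 2 * n_ga]

    es_share = config.es_frac / (config.es_frac + config.gd_frac)

    def impaired_states(idx: list[int]) -> dict[int, str]:
        n_es = int(round(es_share * len(idx)))
        return {j: (ES if k < n_es else GD) for k, j in enumerate(idx)}

    la, lb = config.condition_labels
    states: dict[str, dict[str, str]] = {la: {}, lb: {}}
    imp_a = impaired_states(common + only_a)
    imp_b = impaired_states(common + only_b)
    for i in range(n):
        states[la][loci[i]] = imp_a.get(i, GA if i in ga_a else NE)
        states[lb][loci[i]] = imp_b.get(i, GA if i in ga_b else NE)

    # --- sequences
    lengths = rng.integers(config.gene_len[0], config.gene_len[1] + 1, n)
    seqs: list[str] = []
    for i in range(n):
        if loci[i] in no_ta:
            seqs.append(_seq_without_ta(rng, int(lengths[i])))
        else:
            seqs.append(_gene_seq(rng, int(lengths[i]), config.min_ta_per_gene))
    for a, b in dup_pairs:
        ia, ib = loci.index(a), loci.index(b)
        seqs[ib] = seqs[ia]

    # --- layout: plasmid genes are the tail of the locus list
    n_pl = min(config.n_plasmid_genes, n - 1)
    layout = [("sim_chrom", "chromosome", list(range(n - n_pl)))]
    if n_pl:
        layout.append(("sim_plasmid", "plasmid", list(range(n - n_pl, n))))

    replicons: list[Replicon] = []
    genes: list[GeneModel] = []
    products = ("hypothetical protein", "conserved hypothetical protein",
                "ABC transporter permease", "DNA polymerase subunit",
                "ribosomal protein", "two-component response regulator")
    riley_keys = ("0.0.0", "0.0.1", "0.0.2", "1.5.3", "3.5.5", "2.1.1")
    for rep_id, kind, idxs in layout:
        parts = [_random_seq(rng, config.intergenic_len)]
        pos = config.intergenic_len
        for i in idxs:
            start = pos
            gene_seq = seqs[i]
            # keep planted no-TA genes TA-free across the 5' junction
            if loci[i] in no_ta and parts[-1].endswith("T") and gene_seq.startswith("A"):
                parts[-1] = parts[-1][:-1] + "C"
            parts.append(gene_seq)
            pos += len(gene_seq)
            genes.append(
                GeneModel(
                    locus=loci[i],
                    replicon_id=rep_id,
                    start=start,
                    end=pos,
                    strand="+" if rng.integers(0, 2) else "-",
                    product=str(rng.choice(products)),
                    riley_key=str(rng.choice(riley_keys)),
                )
            )
            parts.append(_random_seq(rng, config.intergenic_len))
            pos += config.intergenic_len
        replicons.append(Replicon(rep_id, "".join(parts), kind))

    index = ReferenceIndex(replicons, genes)
    truth = SimTruth(
        states=states,
        fitness=dict(config.fitness),
        generations=config.generations,
        duplicate_pairs=dup_pairs,
        no_ta_genes=no_ta,
    )
    return index, truth


def site_fitness(index: ReferenceIndex, truth: SimTruth, condition: str) -> np.ndarray:
    """Per-site fitness: minimum over overlapping genes; intergenic w = 1."""
    w = np.ones(index.n_sites)
    states = truth.states[condition]
    for locus, gene in index.genes.items():
        gw = truth.fitness[states[locus]]
        for o in gene.sites:
            w[o] = min(w[o], gw)
    return w


def simulate_selection(
    index: ReferenceIndex,
    truth: SimTruth,
    condition: str,
    depth: float,
    seed: int,
    generations: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Competitive growth of a uniform insertion library for G generations.

    Returns (sampled counts, expected counts), both dense over site
    ordinals.  Abundance multiplier per site is ``2**(G * (w - 1))``; reads
    are multinomial over sites with probabilities proportional to abundance
    and total ``round(depth * n_sites)``.
    """
    G = truth.generations if generations is None else generations
    rng = np.random.default_rng(seed)
    mult = np.power(2.0, G * (site_fitness(index, truth, condition) - 1.0))
    probs = mult / mult.sum()
    total = int(round(depth * index.n_sites))
    counts = rng.multinomial(total, probs)
    return counts.astype(np.int64), total * probs


def emit_reads(
    counts: np.ndarray,
    index: ReferenceIndex,
    config: SimConfig,
    seed: int,
    path: str | Path,
) -> int:
    """Write one FASTQ read per counted insertion (plus planted junk reads).

    Each read is IR + (TA + ``tag_len - 2`` genomic bases in a uniformly
    chosen orientation) + adapter.  A site too close to the replicon end in
    the chosen orientation falls back to the other; qualities are constant.
    Returns the number of reads written.
    """
    rng = np.random.default_rng(seed)
    tl = config.tag_len
    reads: list[str] = []
    for ordinal in np.flatnonzero(counts):
        site = index.sites[ordinal]
        seq = index.replicons[site.replicon_id].sequence
        p = site.position
        fwd = seq[p : p + tl] if p + tl <= len(seq) else None
        rev = (
            _revcomp(seq[p - (tl - 2) : p + 2]) if p - (tl - 2) >= 0 else None
        )
        for _ in range(int(counts[ordinal])):
            if fwd is None and rev is None:
                continue  # unreachable on padded simulator genomes
            tag = fwd if (rev is None or (fwd is not None and rng.integers(0, 2))) else rev
            reads.append(config.ir_terminus + tag + config.adapter)

    n_signal = len(reads)
    junk_total_frac = config.junk_no_ir + config.junk_no_ta + config.junk_short
    if junk_total_frac > 0:
        n_total = int(round(n_signal / (1.0 - junk_total_frac)))
        n_junk = n_total - n_signal
        split = rng.multinomial(
            n_junk,
            np.array([config.junk_no_ir, config.junk_no_ta, config.junk_short])
            / junk_total_frac,
        )
        for _ in range(split[0]):  # adapter-only reads: no IR terminus
            reads.append(_random_junk(rng, config.adapter))
        for _ in range(split[1]):  # IR present but tag does not start with TA
            reads.append(config.ir_terminus + "GG" + _random_junk(rng) + config.adapter)
        for _ in range(split[2]):  # IR + TA but tag shorter than 15 bp
            reads.append(config.ir_terminus + "TA" + _random_junk(rng, n=5) + config.adapter)
    order = rng.permutation(len(reads))
    with open(path, "w") as fh:
        for k, idx in enumerate(order):
            r = reads[idx]
            fh.write(f"@read_{k:07d}\n{r}\n+\n{'I' * len(r)}\n")
    return len(reads)


def _revcomp(s: str) -> str:
    from .reference import reverse_complement

    return reverse_complement(s)


def _random_junk(rng: np.random.Generator, prefix: str = "", n: int = 20) -> str:
    # avoid accidental TA at the tag start is handled by callers; body is random
    return prefix + "".join(_BASES[rng.integers(0, 4, n)])


def write_truth_tsv(index: ReferenceIndex, truth: SimTruth, config: SimConfig, path: str | Path) -> None:
    la, lb = config.condition_labels
    dup = {l for pair in truth.duplicate_pairs for l in pair}
    part = truth.partition(la, lb, index.genes)
    with open(path, "w") as fh:
        fh.write(f"locus\tstate_{la.lower()}\tstate_{lb.lower()}\tpartition\tduplicated\tno_ta\n")
        for locus in index.genes:
            fh.write(
                f"{locus}\t{truth.states[la][locus]}\t{truth.states[lb][locus]}\t"
                f"{part[locus]}\t{int(locus in dup)}\t{int(locus in truth.no_ta_genes)}\n"
            )


def write_genome_files(index: ReferenceIndex, fasta: str | Path, gff: str | Path) -> None:
    """FASTA + GFF3 for the simulated genome (1-based closed GFF spans)."""
    with open(fasta, "w") as fh:
        for rep in index.replicons.values():
            fh.write(f">{rep.id}\n")
            for i in range(0, rep.length, 70):
                fh.write(rep.sequence[i : i + 70] + "\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in index.replicons.values():
            fh.write(f"##sequence-region {rep.id} 1 {rep.length}\n")
        for gene in index.genes.values():
            attrs = (
                f"ID={gene.locus};locus_tag={gene.locus};product={gene.product};"
                f"riley_key={gene.riley_key}"
            )
            fh.write(
                f"{gene.replicon_id}\tsim\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
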