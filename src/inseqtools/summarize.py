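"""Per-gene, per-condition summary statistics.

For each gene: N (TA sites), insertion density (fraction of sites with at
least one read), average read depth (mean count over insertion-bearing
sites — zero-count sites do not dilute the mean), and the HMM gene state.
Duplicated genes are reported as ``unassayed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .hmm import NO_SITES
from .mapping import SiteCountTrack
from .reference import GeneModel, ReferenceIndex

UNASSAYED = "unassayed"

__all__ = ["GeneSummary", "summarize_gene", "summarize_condition", "low_density_flags"]


@dataclass(frozen=True)
class GeneSummary:
    locus: str
    condition: str
    n_sites: int
    hit_sites: int
    insertion_density: float
    avg_read_depth: float
    gene_state: str


def summarize_gene(
    gene: GeneModel,
    track: SiteCountTrack,
    gene_state: str,
    condition: str = "",
) -> GeneSummary:
    """Density and depth are kept at full precision; serialisation rounds
    half-up to 2 decimals.  ``density * N == hit_sites`` exactly."""
    counts = [int(track.counts[o]) for o in gene.sites]
    hit = sum(1 for c in counts if c > 0)
    density = hit / gene.n_sites if gene.n_sites else 0.0
    depth = sum(counts) / hit if hit else 0.0
    state = UNASSAYED if gene.duplicated else (gene_state if gene.n_sites else NO_SITES)
    return GeneSummary(gene.locus, condition, gene.n_sites, hit, density, depth, state)


def summarize_condition(
    index: ReferenceIndex,
    track: SiteCountTrack,
    gene_states: Mapping[str, str],
    condition: str = "",
) -> dict[str, GeneSummary]:
    return {
        locus: summarize_gene(gene, track, gene_states.get(locus, NO_SITES), condition)
        for locus, gene in index.genes.items()
    }


def low_density_flags(
    summaries: Mapping[str, GeneSummary],
    index: ReferenceIndex,
    threshold: float = 0.30,
) -> pd.DataFrame:
    """Loci with insertion density strictly below ``threshold``, cross-checked
    against the duplicated flags: a low-density gene explained by sequence
    duplication is not a candidate essential."""
    rows = []
    for locus, s in summaries.items():
        if s.n_sites and s.insertion_density < threshold:
            rows.append(
                {
                    "locus": locus,
                    "insertion_density": s.insertion_density,
                    "explained_by_duplication": index.genes[locus].duplicated,
                }
            )
    return pd.DataFrame(rows, columns=["locus", "insertion_density", "explained_by_duplication"])


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals (Table-style display)."""
    import decimal

    return float(
        decimal.Decimal(repr(x)).quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP)
    )


def write_gene_summaries(
    summaries: Mapping[str, GeneSummary],
    index: ReferenceIndex,
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "locus\tN\tinsertion_density\tavg_read_depth\tgene_state\triley_key\tannotation\n"
        )
        for locus, s in summaries.items():
            gene = index.genes[locus]
            fh.write(
                f"{locus}\t{s.n_sites}\t{_round2(s.insertion_density)}\t"
                f"{_round2(s.avg_read_depth)}\t{s.gene_state}\t{gene.riley_key}\t"
                f"{gene.product}\n"
            )
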