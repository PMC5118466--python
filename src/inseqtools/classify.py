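"""Two-condition comparison: core functional genome and condition-specific
growth-impaired partitions.

Per-site states pool into growth impaired (GI = ES or GD) and growth neutral
(GN = NE or GA).  Combining two conditions (canonically VMM, a minimal
mannitol medium, and TY, a rich medium) partitions chromosomal genes into

* GI  — impaired in both conditions: the core functional genome (CFG),
* VGI — impaired on the first (minimal) condition only,
* TGI — impaired on the second (rich) condition only,
* GN  — impaired in neither,

with P-prefixed analogues (PGI/PVGI/PTGI/PGN) for plasmid-borne genes.
Genes without TA sites and genes with duplicated sequence are discounted
from all phenotype counts but listed with their exclusion reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .hmm import ES, GD, GA, NE, NO_SITES
from .reference import ReferenceIndex
from .summarize import GeneSummary, UNASSAYED

IMPAIRED_STATES = {ES, GD}
VALID_STATES = {ES, GD, NE, GA}
PHENOTYPES = ("GI", "VGI", "TGI", "GN", "PGI", "PVGI", "PTGI", "PGN", UNASSAYED, NO_SITES)

__all__ = [
    "classify_gene_pair",
    "build_comparison_table",
    "riley_distribution",
    "hypothetical_report",
    "load_hypothetical_table",
]


def classify_gene_pair(replicon_kind: str, state_a: str, state_b: str) -> str:
    """Pure function (replicon kind, state under A, state under B) -> phenotype.

    Condition A is the minimal-medium condition (VMM in the canonical setup),
    condition B the rich one (TY).  ``unassayed``/``no_sites`` short-circuit.
    """
    if UNASSAYED in (state_a, state_b):
        return UNASSAYED
    if NO_SITES in (state_a, state_b):
        return NO_SITES
    for s in (state_a, state_b):
        if s not in VALID_STATES:
            raise ValueError(f"unknown gene state {s!r}")
    impaired_a = state_a in IMPAIRED_STATES
    impaired_b = state_b in IMPAIRED_STATES
    if impaired_a and impaired_b:
        label = "GI"
    elif impaired_a:
        label = "VGI"
    elif impaired_b:
        label = "TGI"
    else:
        label = "GN"
    if replicon_kind == "plasmid":
        return "P" + label
    if replicon_kind == "chromosome":
        return label
    raise ValueError(f"unknown replicon kind {replicon_kind!r}")


@dataclass
class ComparisonResult:
    table: pd.DataFrame
    phenotype_counts: dict[str, int]
    venn: dict[str, int]  # chromosomal genes: both / a_only / b_only


def build_comparison_table(
    summaries_a: Mapping[str, GeneSummary],
    summaries_b: Mapping[str, GeneSummary],
    index: ReferenceIndex,
    labels: tuple[str, str] = ("VMM", "TY"),
) -> ComparisonResult:
    """One record per locus with the final phenotype, plus partition counts
    and the chromosomal Venn triple (impaired both / A only / B only).

    Fatal if the two conditions do not cover the same locus universe.
    """
    only_a = sorted(set(summaries_a) - set(summaries_b))
    only_b = sorted(set(summaries_b) - set(summaries_a))
    if only_a or only_b:
        raise ValueError(
            f"locus universes differ: only in {labels[0]}: {only_a[:5]}..., "
            f"only in {labels[1]}: {only_b[:5]}..."
        )
    la, lb = labels
    rows = []
    for locus in summaries_a:
        sa, sb = summaries_a[locus], summaries_b[locus]
        gene = index.genes[locus]
        kind = index.replicon_kind(locus)
        phenotype = classify_gene_pair(kind, sa.gene_state, sb.gene_state)
        rows.append(
            {
                "locus": locus,
                "replicon": gene.replicon_id,
                "replicon_kind": kind,
                "n_sites": sa.n_sites,
                f"state_{la.lower()}": sa.gene_state,
                f"state_{lb.lower()}": sb.gene_state,
                f"density_{la.lower()}": sa.insertion_density,
                f"density_{lb.lower()}": sb.insertion_density,
                f"depth_{la.lower()}": sa.avg_read_depth,
                f"depth_{lb.lower()}": sb.avg_read_depth,
                "phenotype": phenotype,
                "riley_key": gene.riley_key,
                "product": gene.product,
            }
        )
    table = pd.DataFrame(rows)
    counts = {p: int((table["phenotype"] == p).sum()) for p in PHENOTYPES}
    chrom = table[table["replicon_kind"] == "chromosome"]
    venn = {
        "both_impaired": int((chrom["phenotype"] == "GI").sum()),
        f"{la.lower()}_only": int((chrom["phenotype"] == "VGI").sum()),
        f"{lb.lower()}_only": int((chrom["phenotype"] == "TGI").sum()),
    }
    return ComparisonResult(table, counts, venn)


def riley_distribution(table: pd.DataFrame, phenotype: str) -> pd.DataFrame:
    """Riley functional class -> (count, fraction) within one phenotype
    category; fractions sum to 1.  Missing keys fall in "unannotated"."""
    sub = table[table["phenotype"] == phenotype]
    if sub.empty:
        return pd.DataFrame(columns=["riley_key", "count", "fraction"])
    keys = sub["riley_key"].replace("", "unannotated").fillna("unannotated")
    counts = keys.value_counts()
    return pd.DataFrame(
        {
            "riley_key": counts.index,
            "count": counts.values,
            "fraction": counts.values / counts.values.sum(),
        }
    ).reset_index(drop=True)


# Report sections, in the order the five impaired groups are conventionally
# listed: core, minimal-only, rich-only, plasmid core, plasmid conditional.
REPORT_SECTIONS = (
    ("core_functional_genome", ("GI",)),
    ("condition_a_impaired", ("VGI",)),
    ("condition_b_impaired", ("TGI",)),
    ("plasmid_impaired", ("PGI",)),
    ("plasmid_condition_impaired", ("PVGI", "PTGI")),
)


def hypothetical_report(
    table: pd.DataFrame,
    patterns: Sequence[str] = ("hypothetical",),
    duplicated: Mapping[str, bool] | None = None,
) -> dict[str, pd.DataFrame]:
    """Growth-impaired genes whose product matches the patterns (substring,
    case-insensitive), grouped into the five impaired sections plus a
    separate section for duplicated (unassayed) genes."""
    prod = table["product"].fillna("").str.lower()
    is_hypo = False
    for pat in patterns:
        is_hypo = is_hypo | prod.str.contains(pat.lower(), regex=False)
    hypo = table[is_hypo]
    if duplicated is None:
        duplicated = {}
    dup_mask = hypo["locus"].map(lambda l: bool(duplicated.get(l, False))) | (
        hypo["phenotype"] == UNASSAYED
    )
    report: dict[str, pd.DataFrame] = {}
    assayed = hypo[~dup_mask]
    for section, phenos in REPORT_SECTIONS:
        report[section] = assayed[assayed["phenotype"].isin(phenos)].reset_index(drop=True)
    impaired = {p for _, ps in REPORT_SECTIONS for p in ps}
    report["duplicated"] = hypo[
        dup_mask & hypo["phenotype"].isin(impaired | {UNASSAYED, "PGN", "GN"})
    ].reset_index(drop=True)
    return report


def load_hypothetical_table() -> pd.DataFrame:
    """Curated table of growth-impaired hypothetical proteins from the
    R. leguminosarum bv. viciae 3841 INSeq screens (VMM vs TY), as published;
    the ``duplications`` column is non-empty for genes excluded for sequence
    duplication."""
    from importlib.resources import files

    path = files("inseqtools.data").joinpath("rlv3841_hypothetical_gi.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["duplications"] = df["duplications"].replace({pd.NA: ""}).fillna("")
    for col in ("n", "density_vmm", "depth_vmm", "density_ty", "depth_ty"):
        df[col] = pd.to_numeric(df[col])
    return df


def write_comparison_outputs(result: ComparisonResult, outdir: str | Path, labels=("VMM", "TY")) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
    pd.Series(result.venn).rename("genes").to_csv(outdir / "venn_counts.tsv", sep="\t")
    for pheno in ("GI", "VGI", "TGI", "PGI", "PVGI", "PTGI"):
        dist = riley_distribution(result.table, pheno)
        if not dist.empty:
            dist.to_csv(outdir / f"riley_{pheno}.tsv", sep="\t", index=False)
    report = hypothetical_report(result.table)
    for section, df in report.items():
        df.to_csv(outdir / f"hypothetical_{section}.tsv", sep="\t", index=False)
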