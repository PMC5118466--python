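"""End-to-end pipeline: index -> trim -> map -> call -> summarize -> compare.

Configuration is a TOML file (see :class:`PipelineConfig`); every stage
consumes the previous stage's declared file formats, so intermediates can be
deleted and re-derived with identical downstream results.  A run report
records input checksums, per-stage counts, the package version and the seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .classify import build_comparison_table, write_comparison_outputs
from .hmm import HmmConfig, assign_all_gene_states, estimate_emissions, viterbi_states
from .mapping import count_sites, read_wig, write_wig
from .reference import (
    flag_duplicated_genes,
    load_reference,
    site_assayability,
    write_site_index,
)
from .simulate import (
    SimConfig,
    emit_reads,
    simulate_genome,
    simulate_selection,
    write_genome_files,
    write_truth_tsv,
)
from .summarize import summarize_condition, write_gene_summaries
from .trimming import process_fastq, write_status_counts, write_tag_fasta

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: Path
    genome: Path | None = None
    annotation: Path | None = None
    replicon_kinds: dict[str, str] = field(default_factory=dict)
    reads: dict[str, list[Path]] = field(default_factory=dict)  # condition -> fastqs
    condition_labels: tuple[str, str] = ("VMM", "TY")
    ir_terminus: str = ""
    adapter: str = ""
    tag_len: int = 16
    min_len: int = 15
    ir_mismatches: int = 0
    epsilon: float = 1e-3
    m_es: float = 0.05
    min_assayable_frac: float = 0.5
    seed: int = 0
    simulate: SimConfig | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw: dict[str, Any] = tomllib.load(fh)
        sim = None
        if "simulate" in raw:
            sim = SimConfig(**raw.pop("simulate"))
        base = Path(path).parent
        cfg = cls(outdir=base / raw.pop("outdir", "inseq_out"), simulate=sim)
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config field {key!r}")
            if key in ("genome", "annotation"):
                value = base / value
            elif key == "reads":
                value = {c: [base / p for p in ps] for c, ps in value.items()}
            elif key == "condition_labels":
                value = tuple(value)
            setattr(cfg, key, value)
        if cfg.simulate is not None:
            cfg.simulate.condition_labels = cfg.condition_labels
            if cfg.ir_terminus:
                cfg.simulate.ir_terminus = cfg.ir_terminus
            if cfg.adapter:
                cfg.simulate.adapter = cfg.adapter
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            for name, p in (("genome", self.genome), ("annotation", self.annotation)):
                if p is None or not Path(p).exists():
                    raise ValueError(f"config field {name!r}: missing path {p}")
            for cond, paths in self.reads.items():
                for p in paths:
                    if not Path(p).exists():
                        raise ValueError(f"config field 'reads.{cond}': missing path {p}")
            if not self.ir_terminus or not self.adapter:
                raise ValueError("config fields 'ir_terminus'/'adapter' are required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the run report.

    On failure a FAILED marker file is left in the output directory next to
    whatever partial outputs were produced.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"version": __version__, "seed": config.seed, "stages": {}}
    try:
        return _run(config, out, report)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run(config: PipelineConfig, out: Path, report: dict[str, Any]) -> dict[str, Any]:
    la, lb = config.condition_labels

    if config.simulate is not None:
        _log("simulate", f"genome with {config.simulate.n_genes} genes, seed {config.seed}")
        sim = config.simulate
        sim_index, truth = simulate_genome(sim, config.seed)
        config.genome = out / "sim_genome.fasta"
        config.annotation = out / "sim_genes.gff3"
        write_genome_files(sim_index, config.genome, config.annotation)
        write_truth_tsv(sim_index, truth, sim, out / "sim_truth.tsv")
        config.replicon_kinds = {r.id: r.kind for r in sim_index.replicons.values()}
        config.ir_terminus = sim.ir_terminus
        config.adapter = sim.adapter
        config.reads = {}
        for k, cond in enumerate(config.condition_labels):
            counts, _ = simulate_selection(
                sim_index, truth, cond, sim.depth, seed=config.seed + 1 + k
            )
            fq = out / f"sim_reads_{cond.lower()}.fastq"
            n = emit_reads(counts, sim_index, sim, seed=config.seed + 101 + k, path=fq)
            _log("simulate", f"{cond}: {n} reads")
            config.reads[cond] = [fq]

    config.validate()
    report["inputs"] = {
        str(p): _sha256(Path(p))
        for p in [config.genome, config.annotation]
        + [p for ps in config.reads.values() for p in ps]
    }

    _log("index", f"loading {config.genome}")
    index = load_reference(config.genome, config.annotation, config.replicon_kinds)
    site_assayability(index, config.tag_len)
    duplicated = flag_duplicated_genes(index, config.min_assayable_frac)
    write_site_index(index, out / "site_index.tsv")
    report["stages"]["index"] = {
        "replicons": len(index.replicons),
        "genes": len(index.genes),
        "ta_sites": index.n_sites,
        "duplicated_genes": len(duplicated),
        "no_ta_genes": sum(1 for g in index.genes.values() if not g.has_ta),
    }
    _log("index", f"{index.n_sites} TA sites, {len(index.genes)} genes")

    hmm_cfg = HmmConfig(epsilon=config.epsilon, m_es=config.m_es)
    summaries = {}
    for cond in config.condition_labels:
        tags_all = []
        status_totals: dict[str, int] = {}
        for fq in config.reads[cond]:
            tags, counts = process_fastq(
                fq, config.ir_terminus, config.adapter, config.min_len, config.ir_mismatches
            )
            tags_all.extend(tags)
            for k, v in counts.items():
                status_totals[k] = status_totals.get(k, 0) + v
        write_tag_fasta(tags_all, out / f"tags_{cond.lower()}.fasta")
        from collections import Counter

        write_status_counts(Counter(status_totals), out / f"trim_counts_{cond.lower()}.tsv")
        _log("trim", f"{cond}: accepted {status_totals.get('accepted', 0)}")

        mapped = count_sites(tags_all, index, config.tag_len, condition=cond)
        write_wig(mapped, index, out / f"counts_{cond.lower()}.wig")
        _log("map", f"{cond}: mapped {mapped.reads_mapped}, multi {mapped.reads_multi}, "
                    f"unmapped {mapped.reads_unmapped}")

        # decode from the serialized wig: downstream sees only declared formats
        track = read_wig(out / f"counts_{cond.lower()}.wig", index, condition=cond)
        model = estimate_emissions(track, hmm_cfg)
        states = viterbi_states(track, index, model, hmm_cfg)
        gene_states = assign_all_gene_states(index, states)
        summaries[cond] = summarize_condition(index, track, gene_states, cond)
        write_gene_summaries(summaries[cond], index, out / f"genes_{cond.lower()}.tsv")
        report["stages"][f"condition_{cond}"] = {
            "trim": status_totals,
            "mapped": mapped.reads_mapped,
            "multi": mapped.reads_multi,
            "unmapped": mapped.reads_unmapped,
            "mu": model.mu,
        }
        _log("call", f"{cond}: mu={model.mu:.2f}")

    result = build_comparison_table(
        summaries[la], summaries[lb], index, labels=(la, lb)
    )
    write_comparison_outputs(result, out, labels=(la, lb))
    report["stages"]["compare"] = {
        "phenotype_counts": result.phenotype_counts,
        "venn": result.venn,
    }
    _log("compare", f"phenotypes: { {k: v for k, v in result.phenotype_counts.items() if v} }")

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
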