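"""Trim raw INSeq reads to junction tags and map them to TA sites.

Reads have the structure [IR terminus][TA + genomic tag][adapter]; trimming
keeps 5'-TA tags of >= 15 bp, mapping assigns each tag to its unique TA site
and discards multi-mapping tags (repeated sequence stays unassayed).
"""

import tempfile
from pathlib import Path

from inseqtools import SimConfig, count_sites, process_fastq, simulate_genome, simulate_selection
from inseqtools.reference import site_assayability
from inseqtools.simulate import emit_reads

config = SimConfig(junk_no_ta=0.05)  # plant 5% reads without the 5'-TA
index, truth = simulate_genome(config, seed=1)
site_assayability(index, config.tag_len)

counts, _ = simulate_selection(index, truth, "VMM", depth=10, seed=2)
with tempfile.TemporaryDirectory() as tmp:
    fq = Path(tmp) / "reads.fastq"
    emit_reads(counts, index, config, seed=3, path=fq)
    tags, status = process_fastq(fq, config.ir_terminus, config.adapter)

print("trim statuses:", dict(status))
track = count_sites(tags, index, config.tag_len, condition="VMM")
print(f"mapped {track.reads_mapped}, multi-mapped (discarded) {track.reads_multi}, "
      f"unmapped {track.reads_unmapped}")
# multi-mapped reads come from the planted duplicate gene pairs; everything
# else returns to exactly the site it was emitted from
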