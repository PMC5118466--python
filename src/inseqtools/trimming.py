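"""Raw-read trimming: recover genomic junction tags from INSeq reads.

An INSeq read has the structure [transposon IR terminus][TA + genomic
tag][sequencing adapter].  A read is accepted when the IR terminus is found,
the clipped tag starts with the TA of the insertion site, and the tag is at
least ``min_len`` (default 15) bases long.  Every read yields a
:class:`TagRead` whose status records the first failed check.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

ACCEPTED = "accepted"
NO_IR = "no_ir"
NO_TA = "no_ta"
TOO_SHORT = "too_short"
STATUSES = (ACCEPTED, NO_IR, NO_TA, TOO_SHORT)

__all__ = ["TagRead", "extract_tag", "process_fastq", "STATUSES"]


@dataclass(frozen=True)
class TagRead:
    read_id: str
    tag: str
    status: str


def _find_with_mismatches(read: str, pattern: str, max_mm: int) -> int:
    """Index of the first occurrence of ``pattern`` allowing up to ``max_mm``
    substitutions, or -1.  Exact matching takes the fast path."""
    if max_mm == 0:
        return read.find(pattern)
    n, m = len(read), len(pattern)
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(read[i : i + m], pattern):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return i
    return -1


def extract_tag(
    read: str,
    ir_terminus: str,
    adapter: str,
    min_len: int = 15,
    ir_mismatches: int = 0,
    read_id: str = "",
) -> TagRead:
    """Clip a read at the end of the IR element and at the adapter start,
    then apply the 5'-TA and length filters, in that order.

    Checks run in the order no_ir, no_ta, too_short and the status records
    the first failure.  If the adapter does not occur the tag runs to the
    read end.
    """
    if not ir_terminus or not adapter:
        raise ValueError("ir_terminus and adapter must be non-empty")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    read = read.upper()
    hit = _find_with_mismatches(read, ir_terminus, ir_mismatches)
    if hit == -1:
        return TagRead(read_id, "", NO_IR)
    tag = read[hit + len(ir_terminus) :]
    cut = tag.find(adapter)
    if cut != -1:
        tag = tag[:cut]
    if not tag.startswith("TA"):
        return TagRead(read_id, tag, NO_TA)
    if len(tag) < min_len:
        return TagRead(read_id, tag, TOO_SHORT)
    return TagRead(read_id, tag, ACCEPTED)


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(handle: IO[str]) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence); fatal on a malformed record, naming it."""
    record = 0
    while True:
        header = handle.readline()
        if not header:
            return
        record += 1
        seq = handle.readline().rstrip("\n")
        plus = handle.readline()
        qual = handle.readline().rstrip("\n")
        if not header.startswith("@") or not plus.startswith("+") or not qual:
            raise ValueError(f"malformed FASTQ record {record}")
        if len(qual) != len(seq):
            raise ValueError(f"malformed FASTQ record {record}: quality length")
        yield header[1:].split()[0], seq


def process_fastq(
    reads: str | Path | Iterable[tuple[str, str]],
    ir_terminus: str,
    adapter: str,
    min_len: int = 15,
    ir_mismatches: int = 0,
) -> tuple[list[TagRead], Counter[str]]:
    """Trim a FASTQ file (optionally gzip) or an iterable of (id, sequence).

    Returns the accepted tags (original read ids preserved) and per-status
    counts; the counts partition the input.
    """
    if isinstance(reads, (str, Path)):
        with _open_maybe_gzip(reads) as fh:
            return process_fastq(
                list(_iter_fastq(fh)), ir_terminus, adapter, min_len, ir_mismatches
            )
    counts: Counter[str] = Counter({s: 0 for s in STATUSES})
    accepted: list[TagRead] = []
    for read_id, seq in reads:
        tr = extract_tag(seq, ir_terminus, adapter, min_len, ir_mismatches, read_id)
        counts[tr.status] += 1
        if tr.status == ACCEPTED:
            accepted.append(tr)
    return accepted, counts


def write_tag_fasta(tags: Iterable[TagRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f">{t.read_id}\n{t.tag}\n")


def write_status_counts(counts: Counter[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(STATUSES) + "\n")
        fh.write("\t".join(str(counts[s]) for s in STATUSES) + "\n")
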