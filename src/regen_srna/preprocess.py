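"""Raw-read QC filtering, adapter trimming and collapsing.

Five filter rules are applied to each raw read, in a fixed order so that
every rejected read is attributed to exactly one rule:

1. quality: more than 4 bases with Phred < 10 (``q10``) or more than 6
   bases with Phred < 13 (``q13``);
2. ``homopolymer``: a single nucleotide makes up >= 90% of the insert;
3. ``adapter5`` (5' adapter contamination) / ``no_adapter3`` (3' adapter
   absent);
4. ``no_insert``: nothing left after trimming the 3' adapter;
5. ``too_short``: trimmed insert shorter than 18 nt.

The 3' adapter is trimmed before the length check; quality rules see the
full raw read.  Kept reads are collapsed to unique insert sequences with
counts (``seq{i}_x{count}``), the unit of all downstream statistics.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from .synthgen import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5, QC_RULES


class RawRead(NamedTuple):
    read_id: str
    sequence: str
    quality: str  # Phred+33


class ProcessedRead(NamedTuple):
    """A QC-passed, adapter-trimmed, collapsed unique sequence."""
    read_id: str
    sequence: str
    count: int


class MalformedReadError(ValueError):
    pass


@dataclass
class FilterParams:
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str | None = DEFAULT_ADAPTER5
    max_below_q10: int = 4
    max_below_q13: int = 6
    homopolymer_fraction: float = 0.9
    min_length: int = 18
    adapter_match_len: int = 8


@dataclass
class FilterReport:
    input_count: int = 0
    kept_count: int = 0
    rejected: dict[str, int] = field(default_factory=lambda: {r: 0 for r in QC_RULES})

    def balanced(self) -> bool:
        return self.kept_count + sum(self.rejected.values()) == self.input_count

    def to_json(self) -> str:
        return json.dumps({"input_count": self.input_count,
                           "kept_count": self.kept_count,
                           "rejected": self.rejected}, indent=2)


def _find_adapter3(seq: str, adapter: str, k: int) -> int:
    """Leftmost start of a >=k-base prefix match of the 3' adapter, or -1."""
    return seq.find(adapter[:k])


def _failing_rule(read: RawRead, p: FilterParams) -> tuple[str | None, str]:
    """Return (first failing rule or None, trimmed insert)."""
    if len(read.sequence) != len(read.quality):
        raise MalformedReadError(
            f"read {read.read_id}: sequence and quality lengths differ")
    phred = [ord(c) - 33 for c in read.quality]
    if any(q < 0 for q in phred):
        raise MalformedReadError(f"read {read.read_id}: quality not Phred+33")

    if sum(q < 10 for q in phred) > p.max_below_q10:
        return "q10", ""
    if sum(q < 13 for q in phred) > p.max_below_q13:
        return "q13", ""

    pos = _find_adapter3(read.sequence, p.adapter3, p.adapter_match_len)
    insert = read.sequence[:pos] if pos >= 0 else read.sequence

    if insert and max(insert.count(b) for b in set(insert)) >= p.homopolymer_fraction * len(insert):
        return "homopolymer", insert
    if p.adapter5 and read.sequence.startswith(p.adapter5[:p.adapter_match_len]):
        return "adapter5", insert
    if pos < 0:
        return "no_adapter3", insert
    if not insert:
        return "no_insert", insert
    if len(insert) < p.min_length:
        return "too_short", insert
    return None, insert


def filter_reads(reads: Iterable[RawRead],
                 params: FilterParams | None = None) -> tuple[list[ProcessedRead], FilterReport]:
    """Apply the five filter rules; collapse survivors to unique sequences.

    Returns collapsed reads ordered by decreasing count (ties by first
    appearance) and a :class:`FilterReport` whose counters balance exactly.
    """
    p = params or FilterParams()
    report = FilterReport()
    counts: dict[str, int] = {}
    order: dict[str, int] = {}
    for read in reads:
        report.input_count += 1
        rule, insert = _failing_rule(read, p)
        if rule is not None:
            report.rejected[rule] += 1
            continue
        report.kept_count += 1
        if insert not in counts:
            order[insert] = len(order)
            counts[insert] = 0
        counts[insert] += 1
    ranked = sorted(counts, key=lambda s: (-counts[s], order[s]))
    kept = [ProcessedRead(f"seq{i + 1}_x{counts[s]}", s, counts[s])
            for i, s in enumerate(ranked)]
    return kept, report


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_fastq(path) -> Iterator[RawRead]:
    """Stream a (possibly gzipped) FASTQ file."""
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield RawRead(header.strip().lstrip("@").split()[0], seq, qual)


def write_collapsed_fasta(path, kept: Iterable[ProcessedRead]) -> None:
    with open(path, "w") as fh:
        for r in kept:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def read_collapsed_fasta(path) -> list[ProcessedRead]:
    out = []
    with open(path) as fh:
        name, chunks = None, []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out.append(_collapsed(name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
        if name is not None:
            out.append(_collapsed(name, "".join(chunks)))
    return out


def _collapsed(name: str, seq: str) -> ProcessedRead:
    count = int(name.rsplit("_x", 1)[1]) if "_x" in name else 1
    return ProcessedRead(name, seq, count)
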