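"""Ungapped read-to-genome mapping with best-hit filtering.

Reads are placed on both strands of the genome allowing up to three
substitutions (``N`` counts as a mismatch at its position).  The mapper
uses an exact k-mer seed index with full verification: a read of length
L aligned with at most m mismatches must contain at least one exact
seed among m+1 disjoint chunks of length L // (m+1) (pigeonhole), so
enumerating seed hits and verifying candidates yields every qualifying
placement.  Correctness is checked against an exhaustive sliding-window
Hamming oracle in the test suite.

Best-hit filtering keeps, per read, only hits with the minimal total
mismatch count, then discards hits with more than one internal mismatch
or more than two 3'-terminal mismatches.  Mismatches in the last two
read positions (read orientation) are treated as putative non-template
3' additions; all other positions are "internal".
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import encode, revcomp
from .preprocess import ProcessedRead

HIT_COLUMNS = ["read_id", "contig", "start", "end", "strand",
               "mm_internal", "mm_tail3", "mm_total"]


class GenomeIndex:
    """Per-contig 2-bit encoded genome with lazily built k-mer indexes."""

    def __init__(self, genome: Mapping[str, str]):
        self.names = list(genome)
        self.codes = {c: encode(genome[c]) for c in self.names}
        self._kidx: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    def _index(self, contig: str, k: int) -> tuple[np.ndarray, np.ndarray]:
        key = (contig, k)
        if key not in self._kidx:
            codes = self.codes[contig].astype(np.int64)
            n = len(codes) - k + 1
            if n <= 0:
                self._kidx[key] = (np.empty(0, np.int64), np.empty(0, np.int64))
                return self._kidx[key]
            kmers = np.zeros(n, dtype=np.int64)
            bad = np.zeros(n, dtype=bool)
            for j in range(k):
                col = codes[j:j + n]
                kmers = kmers * 4 + np.where(col > 3, 0, col)
                bad |= col > 3
            kmers[bad] = -1
            order = np.argsort(kmers, kind="stable")
            self._kidx[key] = (kmers[order], order.astype(np.int64))
        return self._kidx[key]

    def seed_starts(self, contig: str, kmer_code: int, k: int, offset: int) -> np.ndarray:
        """Alignment start positions implied by exact hits of one seed."""
        sorted_kmers, order = self._index(contig, k)
        lo = np.searchsorted(sorted_kmers, kmer_code, side="left")
        hi = np.searchsorted(sorted_kmers, kmer_code, side="right")
        return order[lo:hi] - offset


def _verify(codes: np.ndarray, qcodes: np.ndarray, starts: np.ndarray,
            max_mm: int, minus: bool) -> list[tuple[int, int, int]]:
    """Check candidate starts; return (start, internal, tail3) per kept hit."""
    L = len(qcodes)
    starts = np.unique(starts)
    starts = starts[(starts >= 0) & (starts + L <= len(codes))]
    if len(starts) == 0:
        return []
    window = codes[starts[:, None] + np.arange(L)[None, :]]
    mism = window != qcodes[None, :]
    total = mism.sum(axis=1)
    keep = total <= max_mm
    out = []
    for row, s, t in zip(mism[keep], starts[keep], total[keep]):
        # query is in genome orientation; for minus-strand hits the read's
        # two 3'-most positions sit at the left end of the genomic window
        tail = int(row[:2].sum()) if minus else int(row[-2:].sum())
        out.append((int(s), int(t) - tail, tail))
    return out


def map_reads(reads: Sequence[ProcessedRead | tuple], genome: Mapping[str, str],
              max_mismatch: int = 3) -> pd.DataFrame:
    """Map reads to both genome strands, reporting every qualifying placement.

    ``reads`` may be :class:`ProcessedRead` tuples or ``(read_id, seq)``
    pairs.  Returns a hit table with one row per placement, mismatch counts
    split into internal vs 3'-tail (last two read positions).
    """
    index = GenomeIndex(genome)
    rows: list[tuple] = []
    for read in reads:
        rid, seq = read[0], read[1]
        L = len(seq)
        for strand in "+-":
            q = seq if strand == "+" else revcomp(seq)
            qcodes = encode(q)
            k = max(L // (max_mismatch + 1), 1)
            n_seeds = min(max_mismatch + 1, L // k)
            for contig in index.names:
                cand: list[np.ndarray] = []
                for i in range(n_seeds):
                    chunk = qcodes[i * k:(i + 1) * k]
                    if (chunk > 3).any():
                        continue
                    code = 0
                    for b in chunk:
                        code = code * 4 + int(b)
                    cand.append(index.seed_starts(contig, code, k, i * k))
                if not cand:
                    continue
                starts = np.concatenate(cand)
                for s, internal, tail in _verify(index.codes[contig], qcodes,
                                                starts, max_mismatch,
                                                strand == "-"):
                    rows.append((rid, contig, s, s + L, strand,
                                 internal, tail, internal + tail))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def besthit_filter(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep per-read minimal-mismatch hits passing the internal/tail rules.

    Step 1: per read, keep only hits with the minimal total mismatch count.
    Step 2: discard hits with more than 1 internal mismatch or more than 2
    3'-tail mismatches.  Reads losing all hits become unmapped (absent from
    the output).  Pure per-read operation; independent of row order.
    """
    if hits.empty:
        return hits.copy()
    best = hits["mm_total"] == hits.groupby("read_id")["mm_total"].transform("min")
    out = hits[best & (hits["mm_internal"] <= 1) & (hits["mm_tail3"] <= 2)]
    return out.reset_index(drop=True)


def write_hits_tsv(path, hits: pd.DataFrame) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
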