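"""De novo miRNA locus discovery and homology-based naming.

Aligned reads (all timepoints pooled) are clustered into loci (gap <=
200 nt).  A locus is accepted as a miRNA gene when (a) at least 80% of
its read mass sits on one strand, (b) the dominant read length is
20-24 nt, (c) a star partner exists whose genomic position forms a
duplex with the mature arm showing the canonical 2-nt 3' overhang under
a heuristic base-pairing check (Watson-Crick plus G:U), and (d) the
paired fraction over the stem reaches 0.6.  The pairing check is a
maximal-complementarity heuristic, not thermodynamic folding.

Names are transferred from known hairpins by best local alignment with
a Karlin-Altschul E-value (blastn-like +2/-3 scoring, ungapped lambda
solved numerically, K ~ 0.41); loci with no hit below the E-value
threshold (1e-6) are reported as novel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from ._seq import revcomp

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


@dataclass
class MiRNALocus:
    contig: str
    start: int
    end: int
    strand: str
    mature_start: int
    mature_end: int
    star_start: int
    star_end: int
    pairing_score: float      # fraction of stem positions paired
    strand_bias: float
    read_support: float
    hairpin_seq: str
    name: str = "novel"


def _pair_fraction(arm5: str, arm3: str, overhang: int = 2) -> float:
    """Heuristic duplex pairing with a 2-nt 3' overhang on each arm.

    Position i of the 5' arm is tested against position len(arm3)-1-overhang-i
    of the 3' arm (WC or G:U); the score is the paired fraction of the
    5' arm length.
    """
    n = len(arm5)
    paired = 0
    for i in range(n - overhang):
        j = len(arm3) - 1 - overhang - i
        if 0 <= j < len(arm3) and (arm5[i], arm3[j]) in _PAIRS:
            paired += 1
    return paired / n if n else 0.0


def _duplex_check(genome: Mapping[str, str], contig: str, strand: str,
                  a: tuple[int, int], b: tuple[int, int],
                  min_pair_fraction: float) -> float | None:
    """Pairing score of two candidate arms, or None if below threshold."""
    left, right = (a, b) if a[0] <= b[0] else (b, a)
    lseq = genome[contig][left[0]:left[1]]
    rseq = genome[contig][right[0]:right[1]]
    if strand == "+":
        arm5, arm3 = lseq, rseq
    else:
        arm5, arm3 = revcomp(rseq), revcomp(lseq)
    score = _pair_fraction(arm5, arm3)
    return score if score >= min_pair_fraction else None


def find_mirna_loci(hits: pd.DataFrame, reads: Mapping, genome: Mapping[str, str],
                    max_gap: int = 200, min_reads: float = 10.0,
                    min_strand_bias: float = 0.8,
                    dominant_length: tuple[int, int] = (20, 24),
                    min_pair_fraction: float = 0.6,
                    min_star_reads: float = 2.0,
                    max_arm_distance: int = 150) -> list[MiRNALocus]:
    """Cluster aligned reads into loci and apply the hairpin criteria.

    ``hits`` should come from pooled libraries mapped at <= 2 mismatches;
    ``reads`` maps read_id to an object with ``count`` and ``sequence``.
    Output is deterministic and independent of read input order.
    """
    if hits.empty:
        return []
    df = hits.copy()
    df["count"] = [reads[r].count for r in df["read_id"]]
    df = df.sort_values(["contig", "start", "end", "strand"], kind="stable")
    loci: list[MiRNALocus] = []
    for contig, grp in df.groupby("contig", sort=True):
        block: list = []
        block_end = -1
        for hit in grp.itertuples(index=False):
            if block and hit.start > block_end + max_gap:
                locus = _evaluate_block(block, contig, genome,
                                        min_reads, min_strand_bias,
                                        dominant_length, min_pair_fraction,
                                        min_star_reads, max_arm_distance)
                if locus:
                    loci.append(locus)
                block = []
                block_end = -1
            block.append(hit)
            block_end = max(block_end, hit.end)
        if block:
            locus = _evaluate_block(block, contig, genome, min_reads,
                                    min_strand_bias, dominant_length,
                                    min_pair_fraction, min_star_reads,
                                    max_arm_distance)
            if locus:
                loci.append(locus)
    return loci


def _evaluate_block(block: Sequence, contig: str, genome: Mapping[str, str],
                    min_reads: float, min_strand_bias: float,
                    dominant_length: tuple[int, int],
                    min_pair_fraction: float, min_star_reads: float,
                    max_arm_distance: int) -> MiRNALocus | None:
    total = sum(h.count for h in block)
    if total < min_reads:
        return None
    plus = sum(h.count for h in block if h.strand == "+")
    bias = max(plus, total - plus) / total
    if bias < min_strand_bias:
        return None
    strand = "+" if plus >= total - plus else "-"
    major = [h for h in block if h.strand == strand]
    # dominant read length (weighted mode, deterministic tie-break on length)
    by_len: dict[int, float] = {}
    for h in major:
        by_len[h.end - h.start] = by_len.get(h.end - h.start, 0) + h.count
    dom_len = min(sorted(by_len), key=lambda l: (-by_len[l], l))
    if not dominant_length[0] <= dom_len <= dominant_length[1]:
        return None
    # candidate arms: 5'-position groups on the major strand
    by_pos: dict[tuple[int, int], float] = {}
    for h in major:
        key = (h.start, h.end)
        by_pos[key] = by_pos.get(key, 0) + h.count
    ranked = sorted(by_pos, key=lambda k: (-by_pos[k], k))
    mature = ranked[0]
    for cand in ranked[1:]:
        if by_pos[cand] < min_star_reads:
            continue
        gap = max(cand[0] - mature[1], mature[0] - cand[1])
        if gap > max_arm_distance:  # arms must sit within hairpin range
            continue
        if cand[1] <= mature[0] or cand[0] >= mature[1]:  # disjoint
            score = _duplex_check(genome, contig, strand, mature, cand,
                                  min_pair_fraction)
            if score is not None:
                start = min(mature[0], cand[0])
                end = max(mature[1], cand[1])
                seq = genome[contig][start:end]
                if strand == "-":
                    seq = revcomp(seq)
                return MiRNALocus(contig, start, end, strand,
                                  mature[0], mature[1], cand[0], cand[1],
                                  score, bias, total, seq)
    return None


# ---------------------------------------------------------------------------
# homology naming
# ---------------------------------------------------------------------------

def _ungapped_lambda(match: float = 2.0, mismatch: float = -3.0,
                     p: float = 0.25) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for a uniform background."""
    from scipy.optimize import brentq

    def g(lam):
        return (4 * p * math.exp(lam * match)
                + 12 * p * math.exp(lam * mismatch)) * p - 1

    return float(brentq(g, 1e-6, 5.0))


_LAMBDA = _ungapped_lambda()
_K = 0.41  # standard ungapped approximation for nucleotide scoring


def evalue(score: float, query_len: int, db_len: int) -> float:
    """Karlin-Altschul E-value, E = K m n exp(-lambda S)."""
    return _K * query_len * db_len * math.exp(-_LAMBDA * score)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def assign_names(loci: Sequence[MiRNALocus], known_hairpins: Mapping[str, str],
                 max_evalue: float = 1e-6) -> pd.DataFrame:
    """Name each locus from its best known-hairpin alignment, else novel-k.

    Both orientations of the locus hairpin are searched.  Returns a table
    (locus_id, name, evalue, score) and sets ``locus.name`` in place.
    """
    aligner = _aligner()
    db_len = sum(len(s) for s in known_hairpins.values())
    rows = []
    novel = 0
    for i, locus in enumerate(loci, 1):
        best_name, best_score = None, -math.inf
        for name, hp in known_hairpins.items():
            for query in (locus.hairpin_seq, revcomp(locus.hairpin_seq)):
                s = aligner.score(query, hp)
                if s > best_score:
                    best_name, best_score = name, s
        e = (evalue(best_score, len(locus.hairpin_seq), db_len)
             if best_name is not None else math.inf)
        if best_name is not None and e < max_evalue:
            locus.name = best_name
        else:
            novel += 1
            locus.name = f"novel-{novel}"
        rows.append((f"locus-{i}", locus.name,
                     None if math.isinf(e) else e, best_score))
    return pd.DataFrame(rows, columns=["locus_id", "name", "evalue", "score"])
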