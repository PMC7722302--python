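"""piRNA diagnostics: 1U bias, ping-pong signature, cluster prediction.

Candidate piRNAs are mapped reads of 24-35 nt whose annotation cascade
label is ``none`` or ``repeat`` (intergenic and repeat-derived reads).
The ping-pong signature is quantified as a Z-score profile over 5'-end
overlaps of opposite-strand read pairs: for each overlap o in 1..30 the
pair mass is the sum over 5'-position pairs of the product of read
counts, and Z(o) standardises that mass against all other overlaps.
Clusters are called with a sliding-window density scan (1 kb windows,
100 nt step) over hit-count-normalised candidate read mass, requiring a
1U majority or a length concentration within [24, pimax]; qualifying
windows are merged, trimmed to the supporting read span, and loci
shorter than 1 kb are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MAX_OVERLAP = 30
CANDIDATE_COLUMNS = ["read_id", "contig", "strand", "five_end", "start", "end",
                     "length", "count", "n_hits", "first_base"]


@dataclass
class PingPongProfile:
    mass: np.ndarray          # index 0 unused; mass[o] for o in 1..MAX_OVERLAP
    z: np.ndarray
    undefined_background: bool

    def z10(self) -> float:
        return float(self.z[10])

    def peak_overlap(self) -> int:
        return int(np.argmax(self.z[1:]) + 1)


@dataclass
class PiRNACluster:
    contig: str
    start: int
    end: int
    mass: float               # 1/hit-count weighted read mass
    u1_fraction: float
    size_fraction_in_range: float

    @property
    def length(self) -> int:
        return self.end - self.start


def candidate_table(hits: pd.DataFrame, classified: pd.DataFrame,
                    reads: Mapping | None = None,
                    min_len: int = 24, max_len: int = 35,
                    allowed_major: Sequence[str] = ("none", "repeat")) -> pd.DataFrame:
    """Build the candidate-hit table for all piRNA diagnostics.

    One row per genomic placement of each candidate read, carrying the 5'
    end coordinate, read length, collapsed read count, the read's total
    genomic hit count (for 1/n multi-mapper weighting) and its first base.
    """
    if hits.empty:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    lab = classified["major"].reindex(hits["read_id"]).fillna("none")
    sel = hits[lab.isin(allowed_major).to_numpy()].copy()
    sel["length"] = sel["end"] - sel["start"]
    sel = sel[(sel["length"] >= min_len) & (sel["length"] <= max_len)]
    if sel.empty:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    sel["five_end"] = np.where(sel["strand"] == "+", sel["start"], sel["end"] - 1)
    if reads is None:
        sel["count"] = 1
        sel["first_base"] = "N"
    else:
        sel["count"] = [reads[r].count for r in sel["read_id"]]
        sel["first_base"] = [reads[r].sequence[0] for r in sel["read_id"]]
    sel["n_hits"] = sel.groupby("read_id")["read_id"].transform("size")
    return sel[CANDIDATE_COLUMNS].reset_index(drop=True)


def select_candidates(classified: pd.DataFrame, lengths: Mapping[str, int],
                      min_len: int = 24, max_len: int = 35) -> list[str]:
    """Read ids of candidate piRNAs (24-35 nt, unannotated or repeat)."""
    return [rid for rid, major in classified["major"].items()
            if major in ("none", "repeat") and min_len <= lengths[rid] <= max_len]


def u1_fraction(cand: pd.DataFrame) -> float:
    """Read-count-weighted share of candidate reads with a 5' uridine (T)."""
    per_read = cand.drop_duplicates("read_id")
    total = per_read["count"].sum()
    if total == 0:
        return 0.0
    return float(per_read.loc[per_read["first_base"] == "T", "count"].sum() / total)


def _strand_masses(cand: pd.DataFrame):
    """Per contig: {pos: mass} for plus and minus 5' ends."""
    out = {}
    for contig, grp in cand.groupby("contig"):
        plus = grp[grp["strand"] == "+"].groupby("five_end")["count"].sum().to_dict()
        minus = grp[grp["strand"] == "-"].groupby("five_end")["count"].sum().to_dict()
        out[contig] = (plus, minus)
    return out


def pingpong_profile(cand: pd.DataFrame,
                     max_overlap: int = MAX_OVERLAP) -> PingPongProfile:
    """Pair-mass and Z-score per 5' overlap of opposite-strand read pairs.

    A plus-strand 5' end at p and a minus-strand 5' end at p + o - 1
    overlap by exactly o nt; the pair mass is the product of the read
    counts at the two positions.  Z(o) standardises mass[o] against the
    mean and sample standard deviation of all other overlaps.
    """
    mass = np.zeros(max_overlap + 1)
    for plus, minus in _strand_masses(cand).values():
        for p, mp in plus.items():
            for o in range(1, max_overlap + 1):
                mm = minus.get(p + o - 1)
                if mm:
                    mass[o] += mp * mm
    nonzero = int((mass[1:] > 0).sum())
    z = np.zeros_like(mass)
    undefined = nonzero < 2
    if not undefined:
        for o in range(1, max_overlap + 1):
            others = np.delete(mass[1:], o - 1)
            sd = others.std(ddof=1)
            if sd > 0:
                z[o] = (mass[o] - others.mean()) / sd
    return PingPongProfile(mass, z, undefined)


def pingpong_matrix(cand: pd.DataFrame, lo: int = 18, hi: int = 40) -> pd.DataFrame:
    """Length x length pair-mass matrix for exact 10-nt 5' overlaps.

    Each pair contributes its mass to both (len_a, len_b) and
    (len_b, len_a), so the matrix is symmetric and each row marginal is
    the pair mass in which reads of that length participate.
    """
    idx = list(range(lo, hi + 1))
    mat = pd.DataFrame(0.0, index=idx, columns=idx)
    for contig, grp in cand.groupby("contig"):
        plus = grp[grp["strand"] == "+"]
        minus = grp[grp["strand"] == "-"]
        mtab: dict[int, list[tuple[int, int]]] = {}
        for r in minus.itertuples(index=False):
            mtab.setdefault(r.five_end, []).append((r.length, r.count))
        for r in plus.itertuples(index=False):
            for lb, cb in mtab.get(r.five_end + 9, ()):
                if lo <= r.length <= hi and lo <= lb <= hi:
                    m = r.count * cb
                    mat.loc[r.length, lb] += m
                    mat.loc[lb, r.length] += m
    return mat


def predict_clusters(cand: pd.DataFrame, genome: Mapping[str, str],
                     pimax: int = 35, window: int = 1000, step: int = 100,
                     min_mass: float = 10.0, min_u1: float = 0.5,
                     min_size_fraction: float = 0.75, min_min_len: int = 24,
                     min_cluster_length: int = 1000) -> list[PiRNACluster]:
    """Sliding-window piRNA cluster prediction.

    Reads are weighted 1 / (genomic hit count).  A window qualifies when
    its mass reaches ``min_mass`` and either its 1U fraction reaches
    ``min_u1`` or the fraction of its read mass with length in
    [``min_min_len``, ``pimax``] reaches ``min_size_fraction``.
    Overlapping or adjacent qualifying windows are merged, the merged
    interval is trimmed to the span of its supporting reads, and loci
    shorter than ``min_cluster_length`` are dropped.  Deterministic and
    independent of read input order.
    """
    clusters: list[PiRNACluster] = []
    if cand.empty:
        return clusters
    cand = cand.assign(w=cand["count"] / cand["n_hits"],
                       is_t=(cand["first_base"] == "T"),
                       in_range=(cand["length"] >= min_min_len)
                       & (cand["length"] <= pimax))
    for contig in sorted(cand["contig"].unique()):
        grp = cand[cand["contig"] == contig]
        glen = len(genome[contig])
        nbins = glen // step + 1
        mass = np.zeros(nbins)
        t_mass = np.zeros(nbins)
        r_mass = np.zeros(nbins)
        bins = (grp["five_end"] // step).to_numpy()
        np.add.at(mass, bins, grp["w"].to_numpy())
        np.add.at(t_mass, bins, (grp["w"] * grp["is_t"]).to_numpy())
        np.add.at(r_mass, bins, (grp["w"] * grp["in_range"]).to_numpy())
        per = window // step
        kernel = np.ones(per)
        wmass = np.convolve(mass, kernel)[per - 1:nbins + per - 1]
        wt = np.convolve(t_mass, kernel)[per - 1:nbins + per - 1]
        wr = np.convolve(r_mass, kernel)[per - 1:nbins + per - 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            ok = (wmass >= min_mass) & ((wt / wmass >= min_u1)
                                        | (wr / wmass >= min_size_fraction))
        # window i covers [i*step, i*step + window)
        merged: list[list[int]] = []
        for i in np.flatnonzero(ok):
            s, e = int(i) * step, int(i) * step + window
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            inside = grp[(grp["five_end"] >= s) & (grp["five_end"] < e)]
            if inside.empty:
                continue
            cs, ce = int(inside["start"].min()), int(inside["end"].max())
            if ce - cs < min_cluster_length:
                continue
            m = inside["w"].sum()
            clusters.append(PiRNACluster(
                contig, cs, ce, float(m),
                float((inside["w"] * inside["is_t"]).sum() / m),
                float((inside["w"] * inside["in_range"]).sum() / m)))
    return clusters


def merge_clusters(*cluster_lists: Sequence[PiRNACluster]) -> pd.DataFrame:
    """Union of cluster intervals across libraries (sweep-line merge).

    Overlapping or book-ended intervals from any input list coalesce into
    one locus.  Idempotent and commutative.
    """
    ivs = sorted((c.contig, c.start, c.end)
                 for lst in cluster_lists for c in lst)
    rows: list[tuple[str, int, int]] = []
    for contig, s, e in ivs:
        if rows and rows[-1][0] == contig and s <= rows[-1][2]:
            rows[-1] = (contig, rows[-1][1], max(rows[-1][2], e))
        else:
            rows.append((contig, s, e))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def cluster_share(cand: pd.DataFrame, clusters: pd.DataFrame | Sequence[PiRNACluster],
                  genome: Mapping[str, str]) -> tuple[float, float]:
    """(fraction of piRNA mass inside clusters, genome fraction covered)."""
    if not isinstance(clusters, pd.DataFrame):
        clusters = merge_clusters(clusters)
    genome_len = sum(len(s) for s in genome.values())
    covered = int((clusters["end"] - clusters["start"]).sum()) if len(clusters) else 0
    if cand.empty:
        return 0.0, covered / genome_len if genome_len else 0.0
    w = (cand["count"] / cand["n_hits"]).to_numpy()
    total = w.sum()
    inside = np.zeros(len(cand), dtype=bool)
    for row in clusters.itertuples(index=False):
        inside |= ((cand["contig"] == row.contig)
                   & (cand["five_end"] >= row.start)
                   & (cand["five_end"] < row.end)).to_numpy()
    share = float(w[inside].sum() / total) if total > 0 else 0.0
    return share, covered / genome_len if genome_len else 0.0


def clusters_to_bed(path, clusters: Sequence[PiRNACluster]) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters, 1):
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\tcluster-{i}\t"
                     f"{c.mass:.1f}\t+\n")
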