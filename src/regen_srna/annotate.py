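"""Hierarchical small-RNA classification against reference feature sets.

Each mapped read receives exactly one class label, the highest class in
the fixed precedence cascade miRNA > tRNA > rRNA > mRNA > repeat > none
that any of its retained hits overlaps (a hit counts as overlapping a
feature when at least 50% of the read lies inside it).  tRNA-derived
reads are sub-typed by their 5'/3' terminus (tRF-5p shares the mature
tRNA 5' end within +-1 nt), and repeat-derived reads by hit strand
versus the annotated repeat orientation (sense / antisense / unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .preprocess import ProcessedRead
from .synthgen import Feature

MAJOR_CLASSES = ("miRNA", "tRF", "rRF", "mRNA", "repeat", "none")
_PRECEDENCE = {"mirna_hairpin": 0, "trna": 1, "rrna": 2, "mrna": 3, "repeat": 4}
_MAJOR_OF = {"mirna_hairpin": "miRNA", "trna": "tRF", "rrna": "rRF",
             "mrna": "mRNA", "repeat": "repeat"}
LENGTH_RANGE = range(18, 41)


class ReferenceValidationError(ValueError):
    pass


@dataclass
class ReferenceSet:
    """Genomic reference features used by the classification cascade."""

    features: list[Feature]
    trees: dict[str, IntervalTree] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.trees = {}
        for f in self.features:
            if f.fclass not in _PRECEDENCE:
                continue
            if f.start < 0 or f.end <= f.start:
                raise ReferenceValidationError(
                    f"feature {f.feature_id}: invalid interval {f.start}-{f.end}")
            self.trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)

    @classmethod
    def from_truth(cls, features: Sequence[Feature],
                   genome: Mapping[str, str] | None = None) -> "ReferenceSet":
        """Build from a synthetic truth annotation (piRNA clusters excluded).

        If ``genome`` is given, intervals are validated against contig sizes.
        """
        refs = [f for f in features if f.fclass in _PRECEDENCE]
        if genome is not None:
            for f in refs:
                if f.contig not in genome or f.end > len(genome[f.contig]):
                    raise ReferenceValidationError(
                        f"feature {f.feature_id} lies off contig {f.contig}")
        return cls(refs)

    def overlapping(self, contig: str, start: int, end: int):
        tree = self.trees.get(contig)
        return [iv.data for iv in tree.overlap(start, end)] if tree else []


def _trna_termini(feat: Feature) -> tuple[int, int]:
    """Genome coordinates of the mature 5' and 3' terminal bases."""
    if feat.strand == "+":
        return feat.start, feat.end - 1
    return feat.end - 1, feat.start


def type_trf(hit_start: int, hit_end: int, hit_strand: str, trna: Feature,
             tolerance: int = 1) -> str:
    """Sub-type a tRNA-derived read by its terminus match (+-1 nt)."""
    five, three = _trna_termini(trna)
    read5 = hit_start if hit_strand == "+" else hit_end - 1
    read3 = hit_end - 1 if hit_strand == "+" else hit_start
    if abs(read5 - five) <= tolerance:
        return "tRF-5p"
    if abs(read3 - three) <= tolerance:
        return "tRF-3p"
    return "tRF-other"


def classify_reads(hits: pd.DataFrame, refs: ReferenceSet,
                   min_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Assign one class label per mapped read.

    Returns a frame indexed by ``read_id`` with columns ``major``, ``sub``
    (tRF or repeat sub-type, else empty) and ``feature_id`` of the winning
    feature.  ``hits`` must already be best-hit filtered.
    """
    rows = {}
    for rid, grp in hits.groupby("read_id", sort=False):
        best = None  # ((precedence, -overlap, feature_id), feature, hit_row)
        for hit in grp.itertuples(index=False):
            L = hit.end - hit.start
            for feat in refs.overlapping(hit.contig, hit.start, hit.end):
                ov = min(hit.end, feat.end) - max(hit.start, feat.start)
                if ov < min_overlap_fraction * L:
                    continue
                key = (_PRECEDENCE[feat.fclass], -ov, feat.feature_id)
                if best is None or key < best[0]:
                    best = (key, feat, hit)
        if best is None:
            rows[rid] = ("none", "", "")
            continue
        _, feat, hit = best
        sub = ""
        if feat.fclass == "trna":
            sub = type_trf(hit.start, hit.end, hit.strand, feat)
        elif feat.fclass == "repeat":
            orient = feat.meta.get("orientation", feat.strand)
            if orient == "?":
                sub = "unknown"
            else:
                sub = "sense" if hit.strand == orient else "antisense"
        rows[rid] = (_MAJOR_OF[feat.fclass], sub, feat.feature_id)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["major", "sub", "feature_id"])
    out.index.name = "read_id"
    return out


def _counts(read_ids, reads: Mapping[str, ProcessedRead] | None):
    if reads is None:
        return pd.Series(1, index=read_ids)
    return pd.Series({rid: reads[rid].count for rid in read_ids})


def class_fractions(classified: pd.DataFrame,
                    reads: Mapping[str, ProcessedRead] | None = None) -> pd.Series:
    """Per-class share of mapped reads (read-count weighted); sums to 1."""
    w = _counts(classified.index, reads)
    shares = w.groupby(classified["major"]).sum()
    shares = shares.reindex(MAJOR_CLASSES, fill_value=0).astype(float)
    total = shares.sum()
    return shares / total if total > 0 else shares


def length_profile(classified: pd.DataFrame, lengths: Mapping[str, int],
                   reads: Mapping[str, ProcessedRead] | None = None) -> pd.DataFrame:
    """Class x read-length (18-40 nt) count matrix; rows sum to class totals."""
    w = _counts(classified.index, reads)
    mat = pd.DataFrame(0.0, index=list(MAJOR_CLASSES), columns=list(LENGTH_RANGE))
    for rid, major in classified["major"].items():
        ln = lengths[rid]
        if ln in mat.columns:
            mat.loc[major, ln] += w[rid]
    return mat


def repeat_orientation_counts(classified: pd.DataFrame,
                              reads: Mapping[str, ProcessedRead] | None = None
                              ) -> tuple[pd.Series, pd.DataFrame]:
    """Read counts by strand-vs-repeat orientation, overall and per family.

    Reads from exact repeat copies are orientation-consistent across all
    their placements, so each read contributes once via its label.
    """
    rep = classified[classified["major"] == "repeat"]
    w = _counts(rep.index, reads)
    overall = pd.Series(0.0, index=["sense", "antisense", "unknown"])
    per_family: dict[str, pd.Series] = {}
    for rid, row in rep.iterrows():
        fam = row["feature_id"].split(".")[0]
        overall[row["sub"]] += w[rid]
        per_family.setdefault(
            fam, pd.Series(0.0, index=overall.index))[row["sub"]] += w[rid]
    fam_df = pd.DataFrame(per_family).T if per_family else pd.DataFrame(
        columns=overall.index)
    return overall, fam_df
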