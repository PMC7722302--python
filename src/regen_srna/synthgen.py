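"""Synthetic genomes and small-RNA libraries with truth labels.

The generator plants the genomic features the analysis assumes — miRNA
hairpins with a paired mature/star duplex, tRNAs with defined mature
termini, rRNAs, mRNAs carrying 3' UTRs, multi-copy repeat families with
recorded orientation, and intergenic piRNA clusters — and then emits
multi-timepoint FASTQ libraries whose reads carry the statistical
structure the downstream modules detect: a miRNA length peak near 22 nt,
5'-dominant tRNA fragments, piRNA pools with a tunable 5'-uridine (1U)
fraction and a tunable fraction of ping-pong pairs (opposite-strand
reads whose 5' ends overlap by exactly 10 nt), sense/antisense repeat
imbalance, and per-rule QC artifacts.  Every read is recorded in a truth
table, so class composition, 1U rate, ping-pong enrichment and QC
rejections are all recoverable quantities, not assumptions.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import random_seq, revcomp

MIRNA_ARM_LEN = 21
MIRNA_LOOP_LEN = 12
HAIRPIN_LEN = 2 * MIRNA_ARM_LEN + MIRNA_LOOP_LEN
TRNA_LEN = 72
RRNA_LEN = 150
QC_RULES = ("q10", "q13", "homopolymer", "adapter5", "no_adapter3", "no_insert", "too_short")

# Illumina TruSeq small-RNA adapters; any ACGT strings work, these are the
# sequences real libraries of this kind carry.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


class SizingError(ValueError):
    """Requested features do not fit in the requested contigs."""


class ConfigError(ValueError):
    """Library specification inconsistent with the genome truth set."""


@dataclass(frozen=True)
class Feature:
    """A planted genomic feature (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    strand: str
    fclass: str  # mirna_hairpin | trna | rrna | mrna | repeat | pirna_cluster
    feature_id: str
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the toy genome and its planted truth annotation."""

    contig_count: int = 2
    contig_length: int = 100_000
    mirna_hairpin_count: int = 10
    trna_count: int = 6
    rrna_count: int = 2
    mrna_count: int = 8
    mrna_length: int = 800
    utr3_length: int = 200
    repeat_family_count: int = 3
    repeat_copy_number: int = 4
    repeat_length: int = 200
    repeat_unknown_orientation_rate: float = 0.2
    pirna_cluster_count: int = 3
    pirna_cluster_length: int = 5_000
    rng_seed: int = 0

    def validate(self) -> None:
        counts = (
            self.contig_count, self.contig_length, self.mirna_hairpin_count,
            self.trna_count, self.rrna_count, self.mrna_count,
            self.repeat_family_count, self.repeat_copy_number,
            self.pirna_cluster_count,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all genome-spec counts must be >= 0")


def _default_class_mix() -> dict[str, float]:
    # Shares of mapped reads as observed in planarian regeneration libraries:
    # ~41-45% unannotated/intergenic (piRNA pool), 20-23% repeat, 12-14% tRF,
    # 9-16% miRNA, small rRF and mRNA contributions.
    return {"mirna": 0.12, "trf": 0.13, "rrf": 0.04, "mrna": 0.06,
            "repeat": 0.21, "pirna": 0.44}


def _default_length_profile() -> dict[str, dict[int, float]]:
    uniform = {ln: 1 / 18 for ln in range(18, 36)}
    return {
        "mirna": {21: 0.25, 22: 0.50, 23: 0.25},
        "trf": {30: 0.15, 31: 0.20, 32: 0.30, 33: 0.25, 34: 0.10},
        "rrf": dict(uniform),
        "mrna": dict(uniform),
        "repeat": {ln: 1 / 8 for ln in range(28, 36)},
        # piRNA lengths uniform over 30-34 nt, matching the observed 30-34 nt
        # ping-pong length square.
        "pirna": {ln: 1 / 5 for ln in range(30, 35)},
    }


def _default_artifact_rates() -> dict[str, float]:
    return {rule: 0.004 for rule in QC_RULES}


@dataclass
class LibrarySpec:
    """Parameters of one simulated small-RNA library (one timepoint)."""

    total_reads: int = 50_000
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    u1_fraction: float = 0.775
    pingpong_fraction: float = 0.3
    pingpong_a10_bias: float = 0.0
    antisense_repeat_fold: float = 2.4
    trf5_fraction: float = 0.8
    mirna_star_fraction: float = 0.1
    length_profile: dict[str, dict[int, float]] = field(default_factory=_default_length_profile)
    artifact_rates: dict[str, float] = field(default_factory=_default_artifact_rates)
    feature_weights: dict[str, dict[str, float]] | None = None
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        for name in ("u1_fraction", "pingpong_fraction", "pingpong_a10_bias",
                     "trf5_fraction", "mirna_star_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for cls, dist in self.length_profile.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"length distribution for {cls!r} must sum to 1")
        for rule in self.artifact_rates:
            if rule not in QC_RULES:
                raise ValueError(f"unknown artifact rule {rule!r}")


@dataclass(frozen=True)
class ReadRecord:
    """One raw FASTQ read plus its truth label."""

    read_id: str
    sequence: str
    quality: str
    truth_class: str      # mirna|trf|rrf|mrna|repeat|pirna|artifact
    feature_id: str
    contig: str = ""
    start: int = -1       # genomic interval of the (untrimmed) insert
    end: int = -1
    strand: str = "."
    insert: str = ""      # the clean insert the QC stage should recover


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _place_intervals(rng: np.random.Generator, contig_length: int,
                     occupied: list[tuple[int, int]], lengths: Sequence[int],
                     margin: int = 25) -> list[tuple[int, int]]:
    """Sample non-overlapping intervals (plus a safety margin) on one contig."""
    placed = []
    taken = list(occupied)
    for ln in lengths:
        if ln + 2 * margin >= contig_length:
            raise SizingError(
                f"feature of length {ln} cannot fit in contig of length {contig_length}")
        for attempt in range(400):
            s = int(rng.integers(margin, contig_length - ln - margin))
            e = s + ln
            if all(e + margin <= ts or s >= te + margin for ts, te in taken):
                taken.append((s, e))
                placed.append((s, e))
                break
        else:
            need = sum(lengths) + 2 * margin * len(lengths)
            raise SizingError(
                f"could not place all features: ~{need} bp of features requested "
                f"on a {contig_length} bp contig; increase contig_length or "
                "reduce feature counts")
    return placed


def build_genome(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], list[Feature]]:
    """Build contig sequences and the truth feature annotation.

    Deterministic for a fixed ``spec.rng_seed``.  Returns ``(genome,
    features)`` where ``genome`` maps contig name to sequence and every
    planted feature appears exactly once in ``features``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    contigs = [f"contig{i + 1}" for i in range(spec.contig_count)]
    seqs = {c: list(random_seq(rng, spec.contig_length)) for c in contigs}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    features: list[Feature] = []

    def host_contig(i: int) -> str:
        if not contigs:
            raise SizingError("cannot place features on a genome with 0 contigs")
        return contigs[i % len(contigs)]

    def plant(contig: str, seq: str, fclass: str, fid: str, strand: str,
              meta: dict | None = None, margin: int = 25) -> Feature:
        (s, e), = _place_intervals(rng, spec.contig_length, occupied[contig],
                                   [len(seq)], margin=margin)
        occupied[contig].append((s, e))
        genomic = seq if strand == "+" else revcomp(seq)
        seqs[contig][s:e] = list(genomic)
        feat = Feature(contig, s, e, strand, fclass, fid, meta or {})
        features.append(feat)
        return feat

    # miRNA hairpins: 5' arm A, loop, 3' arm pairing A with 2-nt 3' overhangs
    for i in range(spec.mirna_hairpin_count):
        arm = random_seq(rng, MIRNA_ARM_LEN)
        loop = random_seq(rng, MIRNA_LOOP_LEN)
        arm3 = revcomp(arm[: MIRNA_ARM_LEN - 2]) + random_seq(rng, 2)
        hairpin = arm + loop + arm3
        strand = "+" if rng.random() < 0.5 else "-"
        meta = {
            # transcript-coordinate offsets of the arms within the hairpin
            "arm5_t": (0, MIRNA_ARM_LEN),
            "arm3_t": (MIRNA_ARM_LEN + MIRNA_LOOP_LEN, HAIRPIN_LEN),
            "mature_arm": "arm5",
            "hairpin_seq": hairpin,
        }
        plant(host_contig(i), hairpin, "mirna_hairpin", f"mir-{i + 1}", strand, meta)

    for i in range(spec.trna_count):
        strand = "+" if rng.random() < 0.5 else "-"
        plant(host_contig(i), random_seq(rng, TRNA_LEN), "trna", f"trna-{i + 1}", strand)

    for i in range(spec.rrna_count):
        strand = "+" if rng.random() < 0.5 else "-"
        plant(host_contig(i), random_seq(rng, RRNA_LEN), "rrna", f"rrna-{i + 1}", strand)

    for i in range(spec.mrna_count):
        strand = "+" if rng.random() < 0.5 else "-"
        utr = min(spec.utr3_length, spec.mrna_length)
        meta = {"utr3_t": (spec.mrna_length - utr, spec.mrna_length)}
        plant(host_contig(i), random_seq(rng, spec.mrna_length), "mrna",
              f"mrna-{i + 1}", strand, meta)

    for i in range(spec.repeat_family_count):
        consensus = random_seq(rng, spec.repeat_length)
        known = rng.random() >= spec.repeat_unknown_orientation_rate
        for j in range(spec.repeat_copy_number):
            strand = "+" if rng.random() < 0.5 else "-"
            meta = {"family": f"repfam-{i + 1}",
                    "orientation": strand if known else "?"}
            plant(host_contig(i + j), consensus, "repeat",
                  f"repfam-{i + 1}.c{j + 1}", strand, meta)

    for i in range(spec.pirna_cluster_count):
        # clusters are plain intergenic sequence; only the interval matters.
        # A window-scale margin keeps distinct clusters resolvable by
        # kb-window density scans, as real intergenic clusters are.
        plant(host_contig(i), random_seq(rng, spec.pirna_cluster_length),
              "pirna_cluster", f"cluster-{i + 1}", "+", margin=2000)

    genome = {c: "".join(seqs[c]) for c in contigs}
    return genome, features


def transcript_seq(genome: Mapping[str, str], feat: Feature) -> str:
    """Feature sequence in transcript (5'->3') orientation."""
    s = genome[feat.contig][feat.start:feat.end]
    return s if feat.strand == "+" else revcomp(s)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _choose(rng: np.random.Generator, items: Sequence, weights=None):
    if weights is None:
        return items[int(rng.integers(len(items)))]
    w = np.asarray(weights, dtype=float)
    return items[int(rng.choice(len(items), p=w / w.sum()))]


def _sample_length(rng: np.random.Generator, dist: Mapping[int, float]) -> int:
    lens = sorted(dist)
    p = np.array([dist[l] for l in lens], dtype=float)
    return int(rng.choice(lens, p=p / p.sum()))


class _Emitter:
    """Stateful read emitter for one library."""

    def __init__(self, genome: Mapping[str, str], features: Sequence[Feature],
                 lib: LibrarySpec, rng: np.random.Generator):
        self.genome = genome
        self.lib = lib
        self.rng = rng
        self.by_class: dict[str, list[Feature]] = {}
        for f in features:
            self.by_class.setdefault(f.fclass, []).append(f)
        self.reads: list[ReadRecord] = []
        self._n = 0

    # -- helpers ----------------------------------------------------------
    def _clean_insert_ok(self, insert: str) -> bool:
        """True if a clean insert will pass every QC rule untouched."""
        if len(insert) < 18:
            return False
        if self.lib.adapter3[:8] in insert:
            return False
        if insert.startswith(self.lib.adapter5[:8]):
            return False
        counts = max(insert.count(b) for b in "ACGT")
        if counts >= 0.9 * len(insert):
            return False
        return True

    def _weights(self, cls: str, feats: Sequence[Feature]):
        fw = (self.lib.feature_weights or {}).get(cls)
        if fw is None:
            return None
        return [fw.get(f.feature_id, 1.0) for f in feats]

    def _emit(self, insert: str, truth_class: str, feature_id: str,
              contig: str = "", start: int = -1, end: int = -1, strand: str = ".",
              with_adapter3: bool = True, prefix: str = "",
              low_q: tuple[int, int, int] | None = None) -> None:
        """Append one raw read; ``low_q`` = (n_bases, phred, ...) marker."""
        self._n += 1
        rid = f"read{self._n}"
        raw = prefix + insert + (self.lib.adapter3 if with_adapter3 else "")
        qual = ["?" for _ in raw]  # Phred+33, Q30 throughout
        if low_q is not None:
            n_bad, phred = low_q
            pos = self.rng.choice(len(raw), size=min(n_bad, len(raw)), replace=False)
            for p in pos:
                qual[int(p)] = chr(33 + phred)
        self.reads.append(ReadRecord(rid, raw, "".join(qual), truth_class,
                                     feature_id, contig, start, end, strand, insert))

    def _emit_genomic(self, feat: Feature, t_start: int, length: int,
                      truth_class: str, read_strand: str | None = None) -> bool:
        """Emit a read at transcript offset ``t_start`` of ``feat``.

        ``read_strand`` overrides the feature strand (repeat antisense).
        Returns False if the insert would not survive QC cleanly.
        """
        if t_start < 0 or t_start + length > feat.length:
            return False
        if feat.strand == "+":
            g0 = feat.start + t_start
        else:
            g0 = feat.end - t_start - length
        g1 = g0 + length
        strand = read_strand if read_strand is not None else feat.strand
        s = self.genome[feat.contig][g0:g1]
        insert = s if strand == "+" else revcomp(s)
        if not self._clean_insert_ok(insert):
            return False
        self._emit(insert, truth_class, feat.feature_id, feat.contig, g0, g1, strand)
        return True

    def _retry(self, fn, tries: int = 60) -> None:
        for _ in range(tries):
            if fn():
                return
        raise RuntimeError("failed to place a clean read after many attempts")

    # -- per-class emitters -----------------------------------------------
    def emit_mirna(self) -> None:
        feats = self.by_class["mirna_hairpin"]
        feat = _choose(self.rng, feats, self._weights("mirna", feats))
        dist = self.lib.length_profile["mirna"]

        def attempt() -> bool:
            length = _sample_length(self.rng, dist)
            if self.rng.random() < self.lib.mirna_star_fraction:
                a0, a1 = feat.meta["arm3_t"]
                length = min(length, a1 - a0)
                return self._emit_genomic(feat, a0, length, "mirna")
            a0, _ = feat.meta["arm5_t"]
            return self._emit_genomic(feat, a0, length, "mirna")

        self._retry(attempt)

    def emit_trf(self) -> None:
        feats = self.by_class["trna"]
        feat = _choose(self.rng, feats, self._weights("trf", feats))
        dist = self.lib.length_profile["trf"]

        def attempt() -> bool:
            length = min(_sample_length(self.rng, dist), feat.length)
            r = self.rng.random()
            if r < self.lib.trf5_fraction:
                t0 = 0
            elif r < self.lib.trf5_fraction + (1 - self.lib.trf5_fraction) / 2:
                t0 = feat.length - length
            else:
                hi = feat.length - length - 2
                if hi < 2:
                    return False
                t0 = int(self.rng.integers(2, hi + 1))
            return self._emit_genomic(feat, t0, length, "trf")

        self._retry(attempt)

    def _emit_uniform(self, cls: str, fclass: str) -> None:
        feats = self.by_class[fclass]
        feat = _choose(self.rng, feats, self._weights(cls, feats))
        dist = self.lib.length_profile[cls]

        def attempt() -> bool:
            length = min(_sample_length(self.rng, dist), feat.length)
            t0 = int(self.rng.integers(0, feat.length - length + 1))
            return self._emit_genomic(feat, t0, length, cls)

        self._retry(attempt)

    def emit_repeat(self) -> None:
        feats = self.by_class["repeat"]
        feat = _choose(self.rng, feats, self._weights("repeat", feats))
        dist = self.lib.length_profile["repeat"]
        fold = self.lib.antisense_repeat_fold
        antisense = self.rng.random() < fold / (1.0 + fold)

        def attempt() -> bool:
            length = min(_sample_length(self.rng, dist), feat.length)
            t0 = int(self.rng.integers(0, feat.length - length + 1))
            strand = feat.strand
            if antisense:
                strand = "-" if strand == "+" else "+"
            return self._emit_genomic(feat, t0, length, "repeat", read_strand=strand)

        self._retry(attempt)

    def _pirna_single(self, feat: Feature) -> bool:
        length = _sample_length(self.rng, self.lib.length_profile["pirna"])
        strand = "+" if self.rng.random() < 0.5 else "-"
        want_u1 = self.rng.random() < self.lib.u1_fraction
        contig_seq = self.genome[feat.contig]
        lo, hi = feat.start, feat.end - length
        if hi <= lo:
            return False
        start0 = int(self.rng.integers(lo, hi))
        for off in range(hi - lo):
            g0 = lo + (start0 - lo + off) % (hi - lo)
            first = contig_seq[g0] if strand == "+" else revcomp(contig_seq[g0 + length - 1])
            if (first == "T") == want_u1:
                insert = (contig_seq[g0:g0 + length] if strand == "+"
                          else revcomp(contig_seq[g0:g0 + length]))
                if self._clean_insert_ok(insert):
                    self._emit(insert, "pirna", feat.feature_id, feat.contig,
                               g0, g0 + length, strand)
                    return True
        return False

    def _pirna_pair(self, feat: Feature) -> bool:
        """Opposite-strand pair whose 5' ends overlap by exactly 10 nt."""
        la = _sample_length(self.rng, self.lib.length_profile["pirna"])
        lb = _sample_length(self.rng, self.lib.length_profile["pirna"])
        contig_seq = self.genome[feat.contig]
        want_u1_plus = self.rng.random() < self.lib.u1_fraction
        want_u1_minus = self.rng.random() < self.lib.u1_fraction
        # plus-strand member 5' end at p; minus-strand member 5' end at p+9
        lo = feat.start + lb  # keep minus member inside the cluster
        hi = feat.end - la
        if hi <= lo:
            return False
        start0 = int(self.rng.integers(lo, hi))
        for off in range(hi - lo):
            p = lo + (start0 - lo + off) % (hi - lo)
            if (contig_seq[p] == "T") != want_u1_plus:
                continue
            minus_first = revcomp(contig_seq[p + 9])
            if (minus_first == "T") != want_u1_minus:
                continue
            if self.lib.pingpong_a10_bias and self.rng.random() < self.lib.pingpong_a10_bias:
                # position 10 of the plus member should read A
                if contig_seq[p + 9] != "A":
                    continue
            ins_plus = contig_seq[p:p + la]
            ins_minus = revcomp(contig_seq[p + 9 - lb + 1:p + 10])
            if self._clean_insert_ok(ins_plus) and self._clean_insert_ok(ins_minus):
                self._emit(ins_plus, "pirna", feat.feature_id, feat.contig,
                           p, p + la, "+")
                self._emit(ins_minus, "pirna", feat.feature_id, feat.contig,
                           p + 9 - lb + 1, p + 10, "-")
                return True
        return False

    def emit_pirna(self, budget: int) -> int:
        """Emit piRNA reads; pairs consume 2 of the remaining ``budget``."""
        feats = self.by_class["pirna_cluster"]
        feat = _choose(self.rng, feats, self._weights("pirna", feats))
        if budget >= 2 and self.rng.random() < self.lib.pingpong_fraction:
            self._retry(lambda: self._pirna_pair(feat))
            return 2
        self._retry(lambda: self._pirna_single(feat))
        return 1

    # -- QC artifacts ------------------------------------------------------
    def emit_artifact(self, rule: str) -> None:
        rng = self.rng

        def random_clean(n: int) -> str:
            while True:
                s = random_seq(rng, n)
                if (self.lib.adapter3[:8] not in s
                        and not s.startswith(self.lib.adapter5[:8])
                        and max(s.count(b) for b in "ACGT") < 0.9 * len(s)):
                    return s

        if rule == "q10":
            self._emit(random_clean(25), "artifact", rule, low_q=(5, 9))
        elif rule == "q13":
            self._emit(random_clean(25), "artifact", rule, low_q=(7, 12))
        elif rule == "homopolymer":
            self._emit("A" * 25, "artifact", rule)
        elif rule == "adapter5":
            self._emit(random_clean(25), "artifact", rule, prefix=self.lib.adapter5)
        elif rule == "no_adapter3":
            self._emit(random_clean(25), "artifact", rule, with_adapter3=False)
        elif rule == "no_insert":
            self._emit("", "artifact", rule)
        elif rule == "too_short":
            self._emit(random_clean(int(rng.integers(15, 18))), "artifact", rule)
        else:  # pragma: no cover
            raise ValueError(f"unknown QC rule {rule!r}")


def simulate_library(genome: Mapping[str, str], features: Sequence[Feature],
                     lib: LibrarySpec) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one FASTQ library plus its per-read truth table.

    Returns ``(reads, truth)``; ``truth`` has one row per read with columns
    ``read_id, class, feature_id, contig, start, end, strand``.
    """
    lib.validate()
    rng = np.random.default_rng(lib.rng_seed)
    by_class: dict[str, list[Feature]] = {}
    for f in features:
        by_class.setdefault(f.fclass, []).append(f)
    needs = {"mirna": "mirna_hairpin", "trf": "trna", "rrf": "rrna",
             "mrna": "mrna", "repeat": "repeat", "pirna": "pirna_cluster"}
    for cls, share in lib.class_mix.items():
        if cls not in needs:
            raise ConfigError(f"unknown read class {cls!r}")
        if share > 0 and not by_class.get(needs[cls]):
            raise ConfigError(
                f"class_mix assigns {share} to {cls!r} but the truth set has no "
                f"{needs[cls]!r} features")

    art_total = sum(lib.artifact_rates.values())
    if art_total > 1.0:
        raise ConfigError("artifact rates sum to more than 1")
    # exact read-level multinomial allocation: piRNA ping-pong pairs are
    # emitted inside the piRNA budget, so class counts stay binomial
    outcomes = list(QC_RULES) + sorted(lib.class_mix)
    probs = np.array([lib.artifact_rates.get(r, 0.0) for r in QC_RULES]
                     + [(1 - art_total) * lib.class_mix[c] for c in sorted(lib.class_mix)])
    if probs.sum() <= 0:
        alloc = np.zeros(len(outcomes), dtype=int)
    else:
        alloc = rng.multinomial(lib.total_reads, probs / probs.sum())

    em = _Emitter(genome, features, lib, rng)
    for pick, n in zip(outcomes, alloc):
        if pick in QC_RULES:
            for _ in range(n):
                em.emit_artifact(pick)
        elif pick == "mirna":
            for _ in range(n):
                em.emit_mirna()
        elif pick == "trf":
            for _ in range(n):
                em.emit_trf()
        elif pick == "rrf":
            for _ in range(n):
                em._emit_uniform("rrf", "rrna")
        elif pick == "mrna":
            for _ in range(n):
                em._emit_uniform("mrna", "mrna")
        elif pick == "repeat":
            for _ in range(n):
                em.emit_repeat()
        else:
            remaining = n
            while remaining > 0:
                remaining -= em.emit_pirna(remaining)

    truth = pd.DataFrame(
        [(r.read_id, r.truth_class, r.feature_id, r.contig, r.start, r.end, r.strand)
         for r in em.reads],
        columns=["read_id", "class", "feature_id", "contig", "start", "end", "strand"],
    )
    return em.reads, truth


# ---------------------------------------------------------------------------
# phenotype-table simulation (knockdown experiments)
# ---------------------------------------------------------------------------

def simulate_phenotypes(n_animals: int, condition: str, rng: np.random.Generator,
                        mean_area: float = 1000.0, area_cv: float = 0.2,
                        rel_distance_mean: float = 0.5, rel_distance_sd: float = 0.05,
                        head_diameter: float = 500.0,
                        p_no_pr: float = 0.0, p_cyclopia: float = 0.0,
                        p_lesion: float = 0.0, p_no_white: float = 0.0) -> pd.DataFrame:
    """Simulate per-animal photoreceptor measurements for one treatment arm.

    Areas are Gaussian around ``mean_area`` (floored at 10% of the mean);
    the eye-to-eye distance is ``rel_distance`` x ``head_diameter``.
    """
    rows = []
    for i in range(n_animals):
        r = rng.random()
        lesion = r < p_lesion
        no_pr = not lesion and r < p_lesion + p_no_pr
        cyclopia = not lesion and not no_pr and r < p_lesion + p_no_pr + p_cyclopia
        pr_count = 0 if no_pr else (1 if cyclopia else 2)
        la = ra = dist = np.nan
        if pr_count >= 1:
            la = max(float(rng.normal(mean_area, area_cv * mean_area)), 0.1 * mean_area)
        if pr_count == 2:
            ra = max(float(rng.normal(mean_area, area_cv * mean_area)), 0.1 * mean_area)
            dist = float(rng.normal(rel_distance_mean, rel_distance_sd)) * head_diameter
        rows.append({
            "animal_id": f"{condition}-{i + 1}",
            "condition": condition,
            "pr_count": pr_count,
            "area_left": la,
            "area_right": ra,
            "pr_distance": dist,
            "head_diameter": head_diameter,
            "white_region_present": pr_count == 2 and rng.random() >= p_no_white,
            "lesion_or_lysed": lesion,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_genome_fasta(path, genome: Mapping[str, str]) -> None:
    write_fasta(path, genome.items())


def write_truth_bed(path, features: Sequence[Feature]) -> None:
    """Truth annotation as BED6; name column is ``class:feature_id``."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.fclass}:{f.feature_id}"
                     f"\t0\t{f.strand}\n")


def write_reads_fastq(path, reads: Sequence[ReadRecord]) -> None:
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth_tsv(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_reference_fastas(outdir, genome: Mapping[str, str],
                           features: Sequence[Feature]) -> None:
    """Per-class FASTA references (hairpins, mature tRNAs, rRNA, mRNA+UTR)."""
    import os
    groups = {"mirna_hairpin": [], "trna": [], "rrna": [], "mrna": [], "utr3": []}
    for f in features:
        if f.fclass in ("mirna_hairpin", "trna", "rrna", "mrna"):
            groups[f.fclass].append((f.feature_id, transcript_seq(genome, f)))
        if f.fclass == "mrna":
            u0, u1 = f.meta["utr3_t"]
            groups["utr3"].append((f.feature_id, transcript_seq(genome, f)[u0:u1]))
    names = {"mirna_hairpin": "hairpins.fa", "trna": "trna.fa", "rrna": "rrna.fa",
             "mrna": "mrna.fa", "utr3": "utr3.fa"}
    for key, fname in names.items():
        write_fasta(os.path.join(outdir, fname), groups[key])
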