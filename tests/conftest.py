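import numpy as np
import pytest

from regen_srna import align, annotate, preprocess
from regen_srna.synthgen import (
    LibrarySpec,
    SyntheticGenomeSpec,
    build_genome,
    simulate_library,
)


@pytest.fixture(scope="session")
def toy_genome():
    """Default synthetic genome plus truth features (seed 11)."""
    return build_genome(SyntheticGenomeSpec(rng_seed=11))


@pytest.fixture(scope="session")
def small_run(toy_genome):
    """A 6000-read library pushed through QC, mapping and classification.

    Shared by module tests that need a realistic joint state; statistical
    assertions at tighter tolerances use their own larger runs.
    """
    genome, features = toy_genome
    lib = LibrarySpec(total_reads=6000, rng_seed=7)
    reads, truth = simulate_library(genome, features, lib)
    raw = [preprocess.RawRead(r.read_id, r.sequence, r.quality) for r in reads]
    kept, report = preprocess.filter_reads(raw)
    hits = align.besthit_filter(align.map_reads(kept, genome))
    refs = annotate.ReferenceSet.from_truth(features, genome)
    classified = annotate.classify_reads(hits, refs)
    return {
        "genome": genome,
        "features": features,
        "lib": lib,
        "reads": reads,
        "truth": truth,
        "kept": kept,
        "report": report,
        "hits": hits,
        "refs": refs,
        "classified": classified,
        "by_id": {r.read_id: r for r in kept},
    }


def truth_class_by_sequence(reads, truth):
    """Map collapsed insert sequence -> set of planted truth classes."""
    lookup = truth.set_index("read_id")["class"].to_dict()
    out = {}
    for r in reads:
        out.setdefault(r.insert, set()).add(lookup[r.read_id])
    return out


def naive_map(reads, genome, max_mismatch=3):
    """Exhaustive sliding-window Hamming-distance mapping oracle."""
    from regen_srna._seq import revcomp

    rows = []
    for rid, seq in reads:
        L = len(seq)
        for contig, g in genome.items():
            for strand in "+-":
                q = seq if strand == "+" else revcomp(seq)
                for s in range(len(g) - L + 1):
                    window = g[s:s + L]
                    mm = [i for i in range(L)
                          if window[i] != q[i] or q[i] not in "ACGT"]
                    if len(mm) > max_mismatch:
                        continue
                    if strand == "+":
                        tail = sum(1 for i in mm if i >= L - 2)
                    else:
                        tail = sum(1 for i in mm if i < 2)
                    rows.append((rid, contig, s, s + L, strand,
                                 len(mm) - tail, tail, len(mm)))
    return rows


def naive_besthit(rows):
    """Reference implementation of the best-hit rules on oracle rows."""
    by_read = {}
    for row in rows:
        by_read.setdefault(row[0], []).append(row)
    out = []
    for rid, hits in by_read.items():
        best = min(h[7] for h in hits)
        out.extend(h for h in hits
                   if h[7] == best and h[5] <= 1 and h[6] <= 2)
    return out


def naive_pingpong(hit_rows, max_overlap=30):
    """All-pairs ping-pong mass oracle.

    ``hit_rows``: (contig, strand, five_end, count).  Every plus/minus
    5'-position pair within each contig contributes count_a * count_b to
    its exact overlap.
    """
    mass = np.zeros(max_overlap + 1)
    plus = [h for h in hit_rows if h[1] == "+"]
    minus = [h for h in hit_rows if h[1] == "-"]
    for ca, _, pa, na in plus:
        for cb, _, pb, nb in minus:
            if ca != cb:
                continue
            o = pb - pa + 1
            if 1 <= o <= max_overlap:
                mass[o] += na * nb
    return mass


def naive_average_linkage_cophenetic(dist):
    """O(n^3) average-linkage agglomeration -> cophenetic distance matrix.

    ``dist``: square distance matrix.  Returns the matrix of merge
    heights at which each pair of leaves first joins one cluster.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        members_i, members_j = clusters.pop(i), clusters.pop(j)
        for a in members_i:
            for b in members_j:
                coph[a, b] = coph[b, a] = h
        merged = members_i + members_j
        new_d = {}
        for (a, b), v in d.items():
            if a in (i, j) or b in (i, j):
                continue
            new_d[(a, b)] = v
        for k, members_k in clusters.items():
            # average linkage: mean pairwise distance between members
            v = np.mean([dist[a, b] for a in merged for b in members_k])
            new_d[(min(k, next_id), max(k, next_id))] = v
        clusters[next_id] = merged
        d = new_d
        next_id += 1
    return coph
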