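"""piRNA diagnostics: 1U, ping-pong signature, cluster calling."""

import numpy as np
import pandas as pd
import pytest

from conftest import naive_pingpong
from regen_srna import align, annotate, pirna, preprocess
from regen_srna.synthgen import (
    LibrarySpec,
    SyntheticGenomeSpec,
    build_genome,
    simulate_library,
)

CAND = pirna.CANDIDATE_COLUMNS


def cand_df(rows):
    """rows: (read_id, contig, strand, five_end, length, count, first_base)."""
    recs = []
    for rid, contig, strand, fe, ln, ct, fb in rows:
        start = fe if strand == "+" else fe - ln + 1
        recs.append((rid, contig, strand, fe, start, start + ln, ln, ct, 1, fb))
    return pd.DataFrame(recs, columns=CAND)


def pirna_only_candidates(n_reads, seed, **lib_kwargs):
    """Simulate a piRNA-only library and return its candidate table."""
    spec = SyntheticGenomeSpec(contig_count=1, contig_length=60_000,
                               mirna_hairpin_count=1, trna_count=1, rrna_count=1,
                               mrna_count=1, repeat_family_count=1,
                               pirna_cluster_count=2, pirna_cluster_length=5000,
                               rng_seed=4)
    genome, features = build_genome(spec)
    lib = LibrarySpec(total_reads=n_reads, rng_seed=seed, artifact_rates={},
                      class_mix={"pirna": 1.0}, **lib_kwargs)
    reads, truth = simulate_library(genome, features, lib)
    lookup = truth.set_index("read_id")
    recs = []
    for r in reads:
        row = lookup.loc[r.read_id]
        fe = row["start"] if row["strand"] == "+" else row["end"] - 1
        recs.append((r.read_id, row["contig"], row["strand"], fe,
                     row["start"], row["end"], len(r.insert), 1, 1, r.insert[0]))
    return pd.DataFrame(recs, columns=CAND), genome, features


# ---------------------------------------------------------------------------
# candidate selection & 1U
# ---------------------------------------------------------------------------

def test_select_candidates_rules():
    classified = pd.DataFrame(
        {"major": ["miRNA", "none", "none", "repeat", "none"],
         "sub": [""] * 5, "feature_id": [""] * 5},
        index=["m22", "p32", "short", "rep30", "long36"])
    lengths = {"m22": 22, "p32": 32, "short": 20, "rep30": 30, "long36": 36}
    sel = pirna.select_candidates(classified, lengths)
    assert sel == ["p32", "rep30"]


def test_u1_fraction_all_t():
    cand = cand_df([("r1", "c1", "+", 10, 30, 3, "T"),
                    ("r2", "c1", "-", 90, 31, 2, "T")])
    assert pirna.u1_fraction(cand) == 1.0


def test_u1_fraction_weighted():
    cand = cand_df([("r1", "c1", "+", 10, 30, 3, "T"),
                    ("r2", "c1", "+", 50, 30, 1, "A")])
    assert pirna.u1_fraction(cand) == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# ping-pong profile
# ---------------------------------------------------------------------------

def test_single_strand_data_flagged_zero():
    cand = cand_df([(f"r{i}", "c1", "+", 10 * i, 30, 1, "T") for i in range(5)])
    prof = pirna.pingpong_profile(cand)
    assert prof.undefined_background
    assert prof.mass[1:].sum() == 0 and np.all(prof.z == 0)


def test_constructed_six_read_case_matches_bruteforce():
    rows = [("a", "c1", "+", 10, 30, 2, "T"),
            ("b", "c1", "-", 19, 31, 3, "T"),   # overlap 10 with a
            ("c", "c1", "+", 40, 32, 1, "T"),
            ("d", "c1", "-", 44, 30, 2, "A"),   # overlap 5 with c
            ("e", "c1", "+", 60, 30, 1, "T"),
            ("f", "c1", "-", 69, 30, 4, "T")]   # overlap 10 with e
    cand = cand_df(rows)
    prof = pirna.pingpong_profile(cand)
    oracle = naive_pingpong([(r[1], r[2], r[3], r[5]) for r in rows])
    assert np.array_equal(prof.mass, oracle)
    assert prof.mass[10] == 2 * 3 + 1 * 4 and prof.mass[5] == 2


def test_random_hits_match_bruteforce_oracle():
    rng = np.random.default_rng(12)
    rows = [(f"r{i}", f"c{rng.integers(2)}", "+-"[rng.integers(2)],
             int(rng.integers(0, 400)), int(rng.integers(24, 36)),
             int(rng.integers(1, 5)), "TACG"[rng.integers(4)])
            for i in range(800)]
    cand = cand_df(rows)
    prof = pirna.pingpong_profile(cand)
    oracle = naive_pingpong([(r[1], r[2], r[3], r[5]) for r in rows])
    assert np.allclose(prof.mass, oracle)


def test_planted_pingpong_peaks_at_ten():
    cand, _, _ = pirna_only_candidates(600, seed=3, pingpong_fraction=0.3)
    prof = pirna.pingpong_profile(cand)
    assert prof.peak_overlap() == 10
    assert prof.z10() > 3.3


# ---------------------------------------------------------------------------
# ping-pong matrix
# ---------------------------------------------------------------------------

def test_matrix_zero_without_ten_overlaps():
    cand = cand_df([("a", "c1", "+", 10, 30, 1, "T"),
                    ("b", "c1", "-", 15, 30, 1, "T")])
    mat = pirna.pingpong_matrix(cand)
    assert mat.to_numpy().sum() == 0


def test_matrix_planted_pair_lengths_dominate():
    rows = [("a", "c1", "+", 10, 31, 2, "T"), ("b", "c1", "-", 19, 32, 3, "T")]
    mat = pirna.pingpong_matrix(cand_df(rows))
    assert mat.loc[31, 32] == 6 and mat.loc[32, 31] == 6
    assert mat.to_numpy().sum() == 12


def test_matrix_symmetry_on_simulated_pool():
    cand, _, _ = pirna_only_candidates(400, seed=5, pingpong_fraction=0.5)
    mat = pirna.pingpong_matrix(cand)
    assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
    # mass concentrated in the planted 30-34 nt square
    total = mat.to_numpy().sum()
    inside = mat.loc[30:34, 30:34].to_numpy().sum()
    assert total > 0 and inside / total > 0.99


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def test_featureless_contig_yields_no_clusters():
    rng = np.random.default_rng(2)
    genome = {"c1": "".join(rng.choice(list("ACGT"), 20000))}
    rows = [(f"r{i}", "c1", "+", int(rng.integers(0, 19000)), 30, 1, "T")
            for i in range(30)]  # sparse: under min_mass everywhere
    assert pirna.predict_clusters(cand_df(rows), genome) == []


def test_planted_clusters_recovered_with_high_jaccard():
    cand, genome, features = pirna_only_candidates(1200, seed=8)
    clusters = pirna.predict_clusters(cand, genome)
    truth = [f for f in features if f.fclass == "pirna_cluster"]
    assert len(clusters) == len(truth)
    for t in truth:
        jac = max(_jaccard((c.start, c.end), (t.start, t.end))
                  for c in clusters if c.contig == t.contig)
        assert jac >= 0.9


def _jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union


def test_cluster_prediction_order_invariant():
    cand, genome, _ = pirna_only_candidates(800, seed=9)
    shuffled = cand.sample(frac=1.0, random_state=0).reset_index(drop=True)
    c1 = pirna.predict_clusters(cand, genome)
    c2 = pirna.predict_clusters(shuffled, genome)
    assert [(c.contig, c.start, c.end) for c in c1] == \
           [(c.contig, c.start, c.end) for c in c2]


def sweepline_union(intervals):
    out = []
    for c, s, e in sorted(intervals):
        if out and out[-1][0] == c and s <= out[-1][2]:
            out[-1][2] = max(out[-1][2], e)
        else:
            out.append([c, s, e])
    return [tuple(x) for x in out]


def test_merge_clusters_matches_sweepline_oracle():
    rng = np.random.default_rng(6)
    lists = []
    for _ in range(3):
        lists.append([pirna.PiRNACluster(f"c{rng.integers(2)}",
                                         int(s := rng.integers(0, 5000)),
                                         int(s + rng.integers(500, 2000)),
                                         10.0, 0.8, 0.9)
                      for _ in range(6)])
    merged = pirna.merge_clusters(*lists)
    expected = sweepline_union([(c.contig, c.start, c.end)
                                for lst in lists for c in lst])
    assert list(map(tuple, merged.itertuples(index=False))) == expected


def test_merge_identity_disjoint_and_idempotent():
    a = [pirna.PiRNACluster("c1", 100, 200, 1, 1, 1)]
    b = [pirna.PiRNACluster("c1", 500, 700, 1, 1, 1)]
    ab = pirna.merge_clusters(a, b)
    assert list(map(tuple, ab.itertuples(index=False))) == [
        ("c1", 100, 200), ("c1", 500, 700)]
    again = pirna.merge_clusters(a, b, a, b)
    assert ab.equals(again)
    ba = pirna.merge_clusters(b, a)
    assert ab.equals(ba)


def test_cluster_share_trivial_cases():
    genome = {"c1": "A" * 10_000}
    empty = pd.DataFrame(columns=CAND)
    assert pirna.cluster_share(empty, pd.DataFrame(columns=["contig", "start", "end"]),
                               genome) == (0.0, 0.0)
    cand = cand_df([("r1", "c1", "+", 150, 30, 1, "T"),
                    ("r2", "c1", "+", 160, 30, 1, "T")])
    clusters = pd.DataFrame([("c1", 100, 200)], columns=["contig", "start", "end"])
    share, cov = pirna.cluster_share(cand, clusters, genome)
    assert share == 1.0 and cov == pytest.approx(0.01)
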