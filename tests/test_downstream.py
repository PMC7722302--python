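"""Target scanning, GO enrichment, phenotype scoring, PR statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from regen_srna._seq import revcomp
from regen_srna.downstream import (
    ControlSummary,
    chi_square_2x2,
    classify_phenotype,
    go_enrichment,
    phenotype_summary,
    pooled_t,
    pr_stats,
    regen_target_comparison,
    scan_targets,
)
from regen_srna.synthgen import simulate_phenotypes
from regen_srna._seq import random_seq

MIRNA = "TGGAATGTAAAGAAGTATGTAT"  # 22 nt


def test_full_complement_utr_reports_site():
    utr = "ACGT" * 5 + revcomp(MIRNA) + "ACGT" * 5
    sites = scan_targets({"m1": MIRNA}, {"g1": utr})
    assert len(sites) == 1
    row = sites.iloc[0]
    assert row["seed_type"] == "7mer"
    assert row["score"] >= 140
    assert 0 <= row["start"] < row["end"] <= len(utr)


def test_no_seed_no_site():
    rng = np.random.default_rng(0)
    utr = "A" * 500  # cannot complement the seed
    assert scan_targets({"m1": MIRNA}, {"g1": utr}).empty


def test_seed_match_rate_matches_closed_form():
    """Random 1-kb UTR vs random 22-mers: E[seed matches] ~ L * 4^-7."""
    rng = np.random.default_rng(1)
    n_trials, utr_len = 500, 1000
    count = 0
    for i in range(n_trials):
        m = random_seq(rng, 22)
        utr = random_seq(rng, utr_len)
        sites = scan_targets({"m": m}, {"u": utr}, min_score=None,
                             gu_tolerance=0)
        count += len(sites)
    positions = utr_len - 6
    expect = n_trials * positions * 0.25 ** 7
    sd = math.sqrt(n_trials * positions * 0.25 ** 7)  # Poisson-scale error
    assert abs(count - expect) <= 3 * sd


def test_planted_seed_sites_full_recall():
    rng = np.random.default_rng(2)
    mirnas = {f"m{i}": random_seq(rng, 22) for i in range(4)}
    utrs = {}
    planted = []
    for i, (mid, m) in enumerate(mirnas.items()):
        site = revcomp(m)
        utr = random_seq(rng, 300) + site + random_seq(rng, 300)
        utrs[f"g{i}"] = utr
        planted.append((mid, f"g{i}"))
    sites = scan_targets(mirnas, utrs)
    found = set(zip(sites["mirna_id"], sites["mrna_id"]))
    assert set(planted) <= found


def test_chi_square_symmetric_table_zero():
    chi2, p = chi_square_2x2(10, 10, 10, 10)
    assert chi2 == 0.0 and p == 1.0


def test_chi_square_matches_closed_form():
    a, b, c, d = 30, 70, 10, 190
    chi2, p = chi_square_2x2(a, b, c, d)
    n = a + b + c + d
    expected = np.outer([a + b, c + d], [a + c, b + d]) / n
    obs = np.array([[a, b], [c, d]])
    oracle = ((obs - expected) ** 2 / expected).sum()
    assert chi2 == pytest.approx(oracle, abs=1e-9)


def test_go_enrichment_detects_planted_term():
    rng = np.random.default_rng(3)
    targets = [f"t{i}" for i in range(60)]
    background = [f"b{i}" for i in range(600)]
    gene_terms = {}
    for g in targets:
        terms = ["GO:planted"] if rng.random() < 0.5 else []
        terms += ["GO:noise"] if rng.random() < 0.2 else []
        gene_terms[g] = terms
    for g in background:
        terms = ["GO:planted"] if rng.random() < 0.05 else []
        terms += ["GO:noise"] if rng.random() < 0.2 else []
        gene_terms[g] = terms
    res = go_enrichment(targets, background, gene_terms).set_index("term")
    assert bool(res.loc["GO:planted", "significant"])
    assert not bool(res.loc["GO:noise", "significant"])


def test_go_enrichment_small_expected_excluded():
    gene_terms = {"t1": ["GO:rare"], "b1": [], "b2": [], "b3": []}
    res = go_enrichment(["t1"], ["b1", "b2", "b3"], gene_terms)
    row = res.set_index("term").loc["GO:rare"]
    assert not row["tested"] and not row["significant"]


def test_bonferroni_monotone_in_terms_tested():
    """Adding tested terms never turns a non-significant term significant."""
    gene_terms = {f"t{i}": ["GO:a"] if i < 12 else [] for i in range(40)}
    gene_terms.update({f"b{i}": ["GO:a"] if i < 10 else [] for i in range(200)})
    few = go_enrichment(gene_terms.keys() - {f"b{i}" for i in range(200)},
                        [f"b{i}" for i in range(200)], gene_terms)
    with_extra = dict(gene_terms)
    for i in range(40):
        with_extra[f"t{i}"] = with_extra[f"t{i}"] + ["GO:pad1", "GO:pad2"]
    for i in range(200):
        with_extra[f"b{i}"] = with_extra[f"b{i}"] + ["GO:pad1", "GO:pad2"]
    more = go_enrichment([f"t{i}" for i in range(40)],
                         [f"b{i}" for i in range(200)], with_extra)
    p_few = few.set_index("term").loc["GO:a"]
    p_more = more.set_index("term").loc["GO:a"]
    assert bool(p_more["significant"]) <= bool(p_few["significant"])


def test_regen_comparison_trivial_cases():
    empty = pd.DataFrame(columns=["mirna_id", "mrna_id", "start", "end",
                                  "seed_type", "score"])
    res = regen_target_comparison(empty, ["m1"], ["m2"], ["wnt1"])
    assert res["verdict"] == "not-testable"
    rows = [("m1", "wnt1"), ("m1", "other"), ("m2", "wnt1"), ("m2", "other")]
    sites = pd.DataFrame([(a, b, 0, 7, "7mer", 150) for a, b in rows],
                         columns=empty.columns)
    res = regen_target_comparison(sites, ["m1"], ["m2"], ["wnt1"])
    assert res["chi_square"] == 0.0 and res["verdict"] == "not-enriched"


def test_regen_comparison_detects_planted_enrichment():
    rows = [("m1", "wnt1")] * 30 + [("m1", "other")] * 70
    rows += [("m2", "wnt1")] * 10 + [("m2", "other")] * 190
    sites = pd.DataFrame([(a, b, 0, 7, "7mer", 150) for a, b in rows],
                         columns=["mirna_id", "mrna_id", "start", "end",
                                  "seed_type", "score"])
    res = regen_target_comparison(sites, ["m1"], ["m2"], ["wnt1"])
    assert res["verdict"] == "enriched"


# ---------------------------------------------------------------------------
# phenotype scoring
# ---------------------------------------------------------------------------

CTRL = ControlSummary(mean_rel_distance=0.5)


def record(pr_count=2, a_l=100.0, a_r=100.0, dist=250.0, head=500.0,
           white=True, lesion=False):
    return {"pr_count": pr_count, "area_left": a_l, "area_right": a_r,
            "pr_distance": dist, "head_diameter": head,
            "white_region_present": white, "lesion_or_lysed": lesion}


@pytest.mark.parametrize("rec,expected", [
    (record(), "regular-paired"),
    (record(a_l=100, a_r=140), "irregular-paired"),   # 40% of the larger area
    (record(a_l=100, a_r=125), "regular-paired"),     # 20% difference is fine
    (record(dist=340), "irregular-paired"),           # rel distance +36%
    (record(white=False), "irregular-paired"),
    (record(pr_count=1), "cyclopia"),
    (record(pr_count=0), "no-PR"),
    (record(lesion=True), "lesion/lysed"),
    (record(pr_count=0, lesion=True), "lesion/lysed"),  # lesion dominates
])
def test_classify_phenotype_rules(rec, expected):
    assert classify_phenotype(rec, CTRL) == expected


def test_classify_phenotype_scale_invariant():
    rec = record(a_l=110, a_r=95, dist=260)
    scaled = record(a_l=1100, a_r=950, dist=2600, head=5000)
    assert classify_phenotype(rec, CTRL) == classify_phenotype(scaled, CTRL)


def test_phenotype_summary_fractions():
    rng = np.random.default_rng(5)
    ctrl_df = simulate_phenotypes(30, "scrambled", rng)
    summary = ControlSummary.from_records(ctrl_df)
    kd = simulate_phenotypes(30, "kd", rng, p_no_pr=0.3, p_cyclopia=0.2,
                             p_lesion=0.1)
    frac = phenotype_summary(kd, summary)
    assert frac.sum() == pytest.approx(1.0)
    assert frac["no-PR"] > 0 and frac["cyclopia"] > 0


# ---------------------------------------------------------------------------
# PR statistics
# ---------------------------------------------------------------------------

def test_identical_samples_t_zero_ratio_one():
    rng = np.random.default_rng(6)
    arm = simulate_phenotypes(20, "x", rng)
    res = pr_stats(arm, arm)
    assert res["t"] == 0.0 and res["relative_area"] == 1.0
    assert res["distance_variance_ratio"] == pytest.approx(1.0)


def test_pooled_t_matches_textbook_formula():
    x = np.array([3.1, 2.8, 3.5, 3.0, 2.9])
    y = np.array([2.1, 2.4, 2.0, 2.6, 2.2])
    t, p = pooled_t(x, y)
    nx, ny = 5, 5
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    oracle = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    assert t == pytest.approx(oracle, abs=1e-9)
    from scipy import stats
    res = stats.ttest_ind(x, y, equal_var=True)
    assert t == pytest.approx(float(res.statistic), abs=1e-9)
    assert p == pytest.approx(float(res.pvalue), abs=1e-12)


def test_simulated_knockdown_detected():
    rng = np.random.default_rng(7)
    ctrl = simulate_phenotypes(30, "scrambled", rng, mean_area=1000)
    kd = simulate_phenotypes(30, "kd", rng, mean_area=600)
    res = pr_stats(kd, ctrl)
    assert 0.52 <= res["relative_area"] <= 0.66
    assert res["p"] < 1e-4 and res["t"] < 0


def test_pr_stats_requires_two_animals():
    rng = np.random.default_rng(8)
    one = simulate_phenotypes(1, "x", rng)
    many = simulate_phenotypes(10, "y", rng)
    with pytest.raises(ValueError):
        pr_stats(one, many)
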