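"""miRNA target scanning, GO enrichment, knockdown phenotype statistics.

Target prediction is a documented seed-plus-score approximation: a site
requires a perfect Watson-Crick match of miRNA positions 2-8 (7-mer
seed; optionally one G:U tolerated) on the 3' UTR, and the full
miRNA:UTR duplex is then scored ungapped at +5 per WC pair, +2 per G:U,
-3 per mismatch, with seed positions weighted 4-fold; sites keep a
default score threshold of 140 (a perfect unsupplemented seed).

GO enrichment uses per-term 2x2 chi-square tests (no continuity
correction, terms with any expected cell below 5 excluded) under strict
Bonferroni correction.  Knockdown phenotypes are scored with the 33%
irregularity rules and compared with a pooled-variance two-sample
t-test (two-tailed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import is_gu, is_wc, revcomp

SITE_COLUMNS = ["mirna_id", "mrna_id", "start", "end", "seed_type", "score"]
PHENOTYPE_CATEGORIES = ("regular-paired", "irregular-paired", "cyclopia",
                        "no-PR", "lesion/lysed")


# ---------------------------------------------------------------------------
# target scanning
# ---------------------------------------------------------------------------

def _pair_score(m: str, t: str) -> int:
    """Duplex position score: the target base pairs the miRNA base."""
    if is_wc(m, t):
        return 5
    if is_gu(m, t):
        return 2
    return -3


def _seed_ok(mirna: str, utr: str, s: int, gu_tolerance: int) -> str | None:
    """Check the 7-mer seed (miRNA pos 2-8) against UTR positions [s, s+7)."""
    gu = 0
    for k in range(1, 8):
        t = utr[s + 7 - k]
        if is_wc(mirna[k], t):
            continue
        if is_gu(mirna[k], t) and gu < gu_tolerance:
            gu += 1
            continue
        return None
    return "7mer" if gu == 0 else "7mer-GU"


def _duplex_score(mirna: str, utr: str, s: int) -> int:
    """Ungapped duplex score anchored at the seed site, seed weighted x4."""
    score = 0
    for k in range(len(mirna)):
        t_idx = s + 7 - k
        if 0 <= t_idx < len(utr):
            w = 4 if 1 <= k <= 7 else 1
            score += w * _pair_score(mirna[k], utr[t_idx])
    return score


def scan_targets(mirnas: Mapping[str, str], utrs: Mapping[str, str],
                 min_score: float | None = 140.0,
                 gu_tolerance: int = 1) -> pd.DataFrame:
    """Report seed-anchored target sites of each miRNA on each 3' UTR.

    ``mirnas`` and ``utrs`` are id -> sequence (5'->3', DNA alphabet).
    With ``min_score=None`` every seed match is reported, which makes the
    expected hit count on random sequence follow the closed-form 4^-7
    rate for ``gu_tolerance=0``.
    """
    rows = []
    for mid, mseq in mirnas.items():
        if len(mseq) < 8:
            continue
        for gid, useq in utrs.items():
            for s in range(len(useq) - 6):
                seed_type = _seed_ok(mseq, useq, s, gu_tolerance)
                if seed_type is None:
                    continue
                score = _duplex_score(mseq, useq, s)
                if min_score is not None and score < min_score:
                    continue
                lo = max(s + 7 - len(mseq) + 1, 0) if len(mseq) > 7 else s
                hi = min(s + 8, len(useq))
                rows.append((mid, gid, lo, hi, seed_type, score))
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def chi_square_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Chi-square statistic and p for a 2x2 table, no continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    if n == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def go_enrichment(target_genes: Iterable[str], background_genes: Iterable[str],
                  gene_terms: Mapping[str, Sequence[str]],
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-term 2x2 chi-square enrichment with strict Bonferroni correction.

    ``background_genes`` is the gene universe; genes also in the target
    set are counted on the target side only.  Terms with any expected
    cell below 5 are excluded from testing (``tested=False``).
    """
    targets = set(target_genes)
    background = set(background_genes) - targets
    terms = sorted({t for g in targets | background
                    for t in gene_terms.get(g, ())})
    rows = []
    for term in terms:
        a = sum(1 for g in targets if term in gene_terms.get(g, ()))
        b = len(targets) - a
        c = sum(1 for g in background if term in gene_terms.get(g, ()))
        d = len(background) - c
        table = np.array([[a, b], [c, d]], dtype=float)
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n if n else table
        tested = n > 0 and (expected >= 5).all()
        chi2, p = chi_square_2x2(a, b, c, d) if tested else (0.0, 1.0)
        rows.append((term, a, b, c, d, chi2, p, tested))
    df = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d",
                                     "chi_square", "p", "tested"])
    n_tested = int(df["tested"].sum())
    df["bonferroni_alpha"] = alpha / n_tested if n_tested else np.nan
    df["significant"] = df["tested"] & (df["p"] < df["bonferroni_alpha"])
    return df


def regen_target_comparison(sites: pd.DataFrame, phenotype_mirnas: Sequence[str],
                            control_mirnas: Sequence[str],
                            regen_genes: Sequence[str]) -> dict:
    """Compare target-site counts on regeneration genes between miRNA sets.

    Builds the 2x2 table (miRNA set x on/off regeneration-associated
    genes) and runs a chi-square test; returns counts, statistic, p, and
    a verdict in {'enriched', 'not-enriched', 'not-testable'}.
    """
    regen = set(regen_genes)

    def split(mirna_set):
        sub = sites[sites["mirna_id"].isin(set(mirna_set))]
        on = int(sub["mrna_id"].isin(regen).sum())
        return on, len(sub) - on

    a, b = split(phenotype_mirnas)
    c, d = split(control_mirnas)
    out = {"phenotype_on_regen": a, "phenotype_elsewhere": b,
           "control_on_regen": c, "control_elsewhere": d}
    if a + b == 0 or c + d == 0 or (a + c) == 0 or (b + d) == 0:
        out.update(chi_square=np.nan, p=np.nan, verdict="not-testable")
        return out
    chi2, p = chi_square_2x2(a, b, c, d)
    phen_rate = a / (a + b)
    ctrl_rate = c / (c + d)
    enriched = p < 0.05 and phen_rate > ctrl_rate
    out.update(chi_square=chi2, p=p,
               verdict="enriched" if enriched else "not-enriched")
    return out


# ---------------------------------------------------------------------------
# knockdown phenotype scoring
# ---------------------------------------------------------------------------

@dataclass
class ControlSummary:
    """Summary of scrambled-control animals used by the 33% rules."""
    mean_rel_distance: float  # mean of (PR distance / head diameter)

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "ControlSummary":
        paired = records[(records["pr_count"] == 2)
                         & ~records["lesion_or_lysed"]]
        rel = paired["pr_distance"] / paired["head_diameter"]
        return cls(float(rel.mean()))


def classify_phenotype(record: Mapping, control: ControlSummary,
                       threshold: float = 1 / 3) -> str:
    """Score one animal into the five phenotype categories.

    Lesion/lysis dominates; 0 photoreceptors is no-PR, 1 is cyclopia.
    Paired PRs are irregular when one surface area exceeds the other by
    more than 33% (difference relative to the smaller area), when the
    relative eye distance deviates from the control mean by more than
    33%, or when the surrounding white region is absent.
    Scale-invariant in all lengths and areas.
    """
    if record["lesion_or_lysed"]:
        return "lesion/lysed"
    if record["pr_count"] == 0:
        return "no-PR"
    if record["pr_count"] == 1:
        return "cyclopia"
    a_l, a_r = record["area_left"], record["area_right"]
    area_dev = abs(a_l - a_r) / min(a_l, a_r)
    rel = record["pr_distance"] / record["head_diameter"]
    dist_dev = (abs(rel - control.mean_rel_distance) / control.mean_rel_distance
                if control.mean_rel_distance > 0 else 0.0)
    if area_dev > threshold or dist_dev > threshold \
            or not record["white_region_present"]:
        return "irregular-paired"
    return "regular-paired"


def phenotype_summary(records: pd.DataFrame, control: ControlSummary) -> pd.Series:
    """Fraction of animals in each phenotype category for one condition."""
    cats = [classify_phenotype(row, control) for _, row in records.iterrows()]
    counts = pd.Series(cats).value_counts()
    return counts.reindex(PHENOTYPE_CATEGORIES, fill_value=0) / len(records)


def pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample pooled-variance t statistic and two-tailed p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
           / (nx + ny - 2))
    if sp2 == 0:
        return 0.0, 1.0
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * stats.t.sf(abs(t), df=nx + ny - 2)
    return float(t), float(p)


def pr_stats(condition: pd.DataFrame, control: pd.DataFrame,
             welch: bool = False) -> dict:
    """PR-size comparison of one knockdown arm against scrambled controls.

    Uses paired-PR, lesion-free animals; the observation is the mean of
    the two PR surface areas per animal.  Reports the relative mean area
    (condition / control), the two-sample t statistic and two-tailed p
    (pooled variance by default, Welch behind the flag), and the
    variance ratio of the relative eye distances (descriptive only).
    """
    def prep(df):
        ok = df[(df["pr_count"] == 2) & ~df["lesion_or_lysed"]]
        areas = (ok["area_left"] + ok["area_right"]) / 2
        rel_d = ok["pr_distance"] / ok["head_diameter"]
        return areas.to_numpy(), rel_d.to_numpy()

    a_cond, d_cond = prep(condition)
    a_ctrl, d_ctrl = prep(control)
    if len(a_cond) < 2 or len(a_ctrl) < 2:
        raise ValueError("need >= 2 paired-PR animals per arm")
    if welch:
        res = stats.ttest_ind(a_cond, a_ctrl, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    else:
        t, p = pooled_t(a_cond, a_ctrl)
    var_ratio = (d_cond.var(ddof=1) / d_ctrl.var(ddof=1)
                 if d_ctrl.var(ddof=1) > 0 else np.nan)
    return {"relative_area": float(a_cond.mean() / a_ctrl.mean()),
            "t": t, "p": p, "distance_variance_ratio": float(var_ratio),
            "n_condition": len(a_cond), "n_control": len(a_ctrl)}
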