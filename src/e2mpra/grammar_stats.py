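"""Statistical battery for the synthetic-enhancer grammar library.

Class 1 (homotypic copy-number series) is tested by Spearman trend of
log2 activity against motif copy number; Class 1 + Class 2 feed a
per-pair synergy regression ``log2Activity ~ countTF1 + countTF2 + k``
where ``k`` is an interaction indicator that is 0 for homotypic elements
and the per-motif copy count for heterotypic pairs; Class 3 (orderings
of four distinct motifs) is tested by one-way ANOVA over the 24
permutations of each motif set, and by hypergeometric positional
enrichment of motifs in the top/bottom ranked sequences.

All p-value families are Benjamini-Hochberg adjusted within assay.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .activity_scoring import bh_adjust
from .library_design import DesignElement, motif_counts

logger = logging.getLogger(__name__)

__all__ = [
    "IdentifiabilityError",
    "homotypic_trend",
    "synergy_regression",
    "order_anova",
    "positional_enrichment",
    "exclude_unobserved_motifs",
    "hypergeom_upper_tail",
    "synergy_network_edges",
]


class IdentifiabilityError(ValueError):
    """The interaction term has no variation in the design subset."""


def _replicate_activities(activities: pd.DataFrame) -> pd.DataFrame:
    return activities[activities["replicate"] != "pooled"]


def _grammar_designs(designs: list[DesignElement], category: str
                     ) -> list[DesignElement]:
    return [d for d in designs if d.library == "grammar"
            and d.category == category]


# --------------------------------------------------------------------------
# Class 1: homotypic trend
# --------------------------------------------------------------------------

def homotypic_trend(activities: pd.DataFrame, designs: list[DesignElement],
                    fdr: float = 0.05) -> pd.DataFrame:
    """Spearman correlation between motif copy number and per-replicate
    log2 activity, per motif and assay (templates contribute separate
    observations)."""
    class1 = _grammar_designs(designs, "1")
    copies = {d.element_id: (next(iter(motif_counts(d))),
                             sum(motif_counts(d).values()))
              for d in class1}
    act = _replicate_activities(activities)
    act = act[act["element_id"].isin(copies)]
    rows = []
    for (assay,), sub in act.groupby(["assay"]):
        motifs = sorted({copies[e][0] for e in sub["element_id"]})
        for motif in motifs:
            obs = sub[[copies[e][0] == motif for e in sub["element_id"]]]
            x = np.array([copies[e][1] for e in obs["element_id"]])
            y = obs["log2_activity"].values
            if len(np.unique(x)) < 2:
                continue
            if np.ptp(y) == 0:
                rows.append({"motif": motif, "assay": assay,
                             "spearman_rho": np.nan, "p": np.nan,
                             "n": len(y)})
                continue
            res = stats.spearmanr(x, y)
            rows.append({"motif": motif, "assay": assay,
                         "spearman_rho": res.statistic, "p": res.pvalue,
                         "n": len(y)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adjusted_p"] = np.nan
        for assay, idx in out.groupby("assay").groups.items():
            out.loc[idx, "adjusted_p"] = bh_adjust(out.loc[idx, "p"])
        out["significant"] = out["adjusted_p"] < fdr
    return out


# --------------------------------------------------------------------------
# Class 1 + 2: synergy regression
# --------------------------------------------------------------------------

def synergy_regression(activities: pd.DataFrame,
                       designs: list[DesignElement],
                       fdr: float = 0.01,
                       k_encoding: str = "copies") -> pd.DataFrame:
    """Per-pair OLS of per-replicate activity on the two motif copy
    numbers plus the interaction term ``k``.

    ``k_encoding='copies'`` sets k to the per-motif copy count of Class 2
    elements (2 under the default 2:2 arrangements); ``'indicator'``
    uses a 0/1 class flag.  The two-sided t-test p-value of the k
    coefficient is BH-adjusted across pairs within each assay.
    """
    if k_encoding not in ("copies", "indicator"):
        raise ValueError(f"unknown k encoding {k_encoding!r}")
    class1 = _grammar_designs(designs, "1")
    class2 = _grammar_designs(designs, "2")
    if not class2:
        raise IdentifiabilityError("no Class 2 elements: k is constant")
    c1_by_motif: dict[str, list[DesignElement]] = defaultdict(list)
    for d in class1:
        c1_by_motif[next(iter(motif_counts(d)))].append(d)
    pairs: dict[tuple[str, str], list[DesignElement]] = defaultdict(list)
    for d in class2:
        pairs[tuple(sorted(motif_counts(d)))].append(d)

    act = _replicate_activities(activities).set_index("element_id")
    rows = []
    for (a, b), els2 in sorted(pairs.items()):
        members = c1_by_motif.get(a, []) + c1_by_motif.get(b, []) + els2
        design_rows = []
        for d in members:
            mc = motif_counts(d)
            if d.category == "1":
                k = 0
            else:
                k = (d.k if d.k is not None else max(mc.values())) \
                    if k_encoding == "copies" else 1
            design_rows.append((d.element_id, mc.get(a, 0), mc.get(b, 0), k))
        dm = pd.DataFrame(design_rows,
                          columns=["element_id", "count1", "count2", "k"]
                          ).set_index("element_id")
        if dm["k"].nunique() < 2:
            raise IdentifiabilityError(f"pair {a}+{b}: k constant")
        for assay, sub in act.groupby("assay"):
            obs = dm.join(sub["log2_activity"], how="inner").dropna()
            if obs["k"].nunique() < 2 or len(obs) < 5:
                continue
            X = sm.add_constant(obs[["count1", "count2", "k"]])
            fit = sm.OLS(obs["log2_activity"], X).fit()
            rows.append({"motif1": a, "motif2": b, "assay": assay,
                         "beta_count1": fit.params["count1"],
                         "beta_count2": fit.params["count2"],
                         "beta_k": fit.params["k"],
                         "p_k": fit.pvalues["k"], "n": len(obs)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adjusted_p_k"] = np.nan
        for assay, idx in out.groupby("assay").groups.items():
            out.loc[idx, "adjusted_p_k"] = bh_adjust(out.loc[idx, "p_k"])
        out["significant"] = out["adjusted_p_k"] < fdr
        out["sign"] = np.sign(out["beta_k"]).astype(int)
    return out


def synergy_network_edges(synergy: pd.DataFrame) -> pd.DataFrame:
    """Significant pairs as network edges (sign, -log10 adjusted p)."""
    sig = synergy[synergy["significant"]].copy()
    sig["weight"] = -np.log10(sig["adjusted_p_k"])
    return sig[["motif1", "motif2", "assay", "sign", "weight"]]


# --------------------------------------------------------------------------
# Class 3: motif-order ANOVA
# --------------------------------------------------------------------------

def order_anova(activities: pd.DataFrame,
                designs: list[DesignElement], fdr: float = 0.01
                ) -> pd.DataFrame:
    """One-way ANOVA of per-replicate activity with the motif permutation
    as the factor, one test per four-motif set and assay."""
    class3 = _grammar_designs(designs, "3")
    perm_of = {d.element_id: tuple(n for n, _, _ in d.arrangement)
               for d in class3}
    act = _replicate_activities(activities)
    act = act[act["element_id"].isin(perm_of)].copy()
    act["perm"] = [perm_of[e] for e in act["element_id"]]
    act["motif_set"] = [tuple(sorted(p)) for p in act["perm"]]
    rows = []
    for (mset, assay), sub in act.groupby(["motif_set", "assay"]):
        groups = [g["log2_activity"].values
                  for _, g in sub.groupby("perm") if len(g) >= 2]
        if len(groups) < 2:
            warnings.warn(f"motif set {'+'.join(mset)} ({assay}): "
                          "degenerate groups, skipped")
            continue
        if np.ptp(np.concatenate(groups)) == 0:
            f_stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p = stats.f_oneway(*groups)
            if np.isnan(f_stat):  # zero within-group variance everywhere
                f_stat, p = 0.0, 1.0
        means = [g.mean() for g in groups]
        rows.append({"motif_set": "+".join(mset), "assay": assay,
                     "F": f_stat, "p": p,
                     "activity_range": max(means) - min(means),
                     "n": int(sub.shape[0])})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adjusted_p"] = np.nan
        for assay, idx in out.groupby("assay").groups.items():
            out.loc[idx, "adjusted_p"] = bh_adjust(out.loc[idx, "p"])
        out["significant"] = out["adjusted_p"] < fdr
    return out


# --------------------------------------------------------------------------
# Class 3: positional enrichment
# --------------------------------------------------------------------------

def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(x - 1, N, K, n))


_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def positional_enrichment(pooled_activities: pd.DataFrame,
                          designs: list[DesignElement],
                          n_select: int = 200) -> pd.DataFrame:
    """Hypergeometric enrichment of each motif at each of the four slots
    among the top/bottom ``n_select`` Class 3 sequences ranked by pooled
    transcriptional activity (slot 1 distal, slot 4 proximal to the
    minimal promoter)."""
    class3 = _grammar_designs(designs, "3")
    perm_of = {d.element_id: tuple(n for n, _, _ in d.arrangement)
               for d in class3}
    act = pooled_activities[
        (pooled_activities["replicate"] == "pooled")
        & (pooled_activities["element_id"].isin(perm_of))].dropna(
            subset=["log2_activity"])
    ranked = act.sort_values(["log2_activity", "element_id"],
                             ascending=[False, True])
    N = len(ranked)
    if N < n_select:
        raise ValueError(f"only {N} ranked elements for n_select={n_select}")
    selections = {"top": ranked.head(n_select)["element_id"],
                  "bottom": ranked.tail(n_select)["element_id"]}
    motifs = sorted({m for p in perm_of.values() for m in p})
    # background occupancy over all ranked sequences
    ranked_perms = [perm_of[e] for e in ranked["element_id"]]
    rows = []
    for tail, selected in selections.items():
        sel_perms = [perm_of[e] for e in selected]
        for motif in motifs:
            for q in range(1, 5):
                K = sum(p[q - 1] == motif for p in ranked_perms)
                x = sum(p[q - 1] == motif for p in sel_perms)
                n = len(sel_perms)
                p = hypergeom_upper_tail(x, N, K, n)
                denom_n = n - x
                denom_rest = (N - K) - (n - x)
                if x == 0:
                    odds = 0.0
                elif denom_n == 0 or denom_rest <= 0 or K == x:
                    odds = np.inf
                else:
                    odds = (x / denom_n) / ((K - x) / denom_rest)
                rows.append({"motif": motif, "position": q, "tail": tail,
                             "x": x, "n": n, "K": K, "N": N,
                             "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = np.nan
    for tail, idx in out.groupby("tail").groups.items():
        out.loc[idx, "adjusted_p"] = bh_adjust(out.loc[idx, "p"])
    def _stars(ap: float) -> str:
        for thr, s in _STAR_THRESHOLDS:
            if ap < thr:
                return s
        return "ns"

    out["stars"] = [_stars(ap) for ap in out["adjusted_p"]]
    return out


# --------------------------------------------------------------------------
# coverage-based motif exclusion
# --------------------------------------------------------------------------

def exclude_unobserved_motifs(designs: list[DesignElement],
                              counts: pd.DataFrame,
                              min_inserted: int = 10
                              ) -> tuple[list[DesignElement], list[str]]:
    """Drop wholesale every grammar motif whose elements are not covered
    in the pooled inserted (gDNA) channel.

    A motif is dropped when the median pooled inserted count over its
    elements falls below ``min_inserted``.  Returns the retained designs
    and the dropped motif names.
    """
    ins = counts[counts["channel"] == "inserted"]
    pooled = ins.groupby("element_id")["count"].sum()
    per_motif: dict[str, list[float]] = defaultdict(list)
    for d in designs:
        if d.library != "grammar" or not d.arrangement:
            continue
        total = float(pooled.get(d.element_id, 0))
        for m in motif_counts(d):
            per_motif[m].append(total)
    dropped = sorted(m for m, v in per_motif.items()
                     if np.median(v) < min_inserted)
    if dropped:
        logger.info("exclude_unobserved_motifs: dropping %s", dropped)
    kept = [d for d in designs
            if not (d.arrangement and set(motif_counts(d)) & set(dropped))]
    return kept, dropped
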