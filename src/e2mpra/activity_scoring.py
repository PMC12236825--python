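"""Normalized activity scores from count tables.

Transcriptional activity is the RNA/DNA barcode-count ratio; epigenetic
activity is the enriched/inserted UMI ratio.  Both are put on a common
scale by counts-per-million (CPM) depth normalization followed by a
scaling factor ``f`` computed as a trimmed mean of M-values (TMM) over
designated negative-control elements, so that the expected log2 activity
of the controls is zero in every sample.  Replicates are pooled by
summing raw counts per channel and re-normalizing, which damps the UMI
shot noise that dominates per-replicate epigenetic ratios.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .read_counting import (CHANNEL_ATAC, CHANNEL_DNA, CHANNEL_H3K27AC,
                            CHANNEL_INSERTED, CHANNEL_RNA)

logger = logging.getLogger(__name__)

__all__ = [
    "ASSAY_OF_CHANNEL",
    "cpm_normalize",
    "tmm_factor",
    "epigenetic_activity",
    "mpra_activity",
    "category_tests",
    "replicate_qc",
    "bh_adjust",
]

#: enriched channel -> assay label
ASSAY_OF_CHANNEL = {CHANNEL_ATAC: "ATAC", CHANNEL_H3K27AC: "H3K27ac"}

ACTIVITY_COLUMNS = ["element_id", "assay", "replicate", "log2_activity",
                    "support"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def cpm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``cpm`` column: count x 1e6 / total of its (replicate, channel)."""
    totals = table.groupby(["replicate", "channel"])["count"].transform("sum")
    zero = totals == 0
    if zero.any():
        bad = table.loc[zero, ["replicate", "channel"]].drop_duplicates()
        raise ValueError(f"zero channel total for {bad.values.tolist()}")
    out = table.copy()
    out["cpm"] = out["count"] * 1e6 / totals
    return out


def tmm_factor(enriched_ctrl, inserted_ctrl,
               trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """TMM scaling factor from negative-control CPM values.

    M_i = log2(enriched_i / inserted_i) and A_i = 0.5 log2(enriched_i *
    inserted_i) over controls with both values positive.  The lowest and
    highest ``trim_m`` fraction by M and ``trim_a`` fraction by A are
    discarded and f = 2**mean(M) of the survivors (unweighted).
    Dividing all enriched values by f re-centres the trimmed mean of
    control M-values at zero.
    """
    e = np.asarray(enriched_ctrl, dtype=float)
    i = np.asarray(inserted_ctrl, dtype=float)
    ok = (e > 0) & (i > 0)
    e, i = e[ok], i[ok]
    n = len(e)
    if n < 3:
        raise ValueError(f"TMM needs >=3 usable controls, got {n}")
    m = np.log2(e / i)
    a = 0.5 * np.log2(e * i)

    def _keep(values: np.ndarray, trim: float) -> np.ndarray:
        k = int(np.floor(n * trim))
        order = np.argsort(values, kind="stable")
        keep = np.zeros(n, dtype=bool)
        keep[order[k:n - k if k else n]] = True
        return keep

    keep = _keep(m, trim_m) & _keep(a, trim_a)
    if not keep.any():  # pathological trims; fall back to M-trim only
        keep = _keep(m, trim_m)
    return float(2 ** m[keep].mean())


def _ratio_log2(enriched_cpm, inserted_cpm, enriched_raw, inserted_raw,
                f: float, depth_e: float, depth_i: float) -> np.ndarray:
    """log2((enriched/f)/inserted) on the CPM scale, with +0.5 raw
    pseudocount on both channels where enriched == 0 but inserted > 0."""
    e = np.asarray(enriched_cpm, dtype=float).copy()
    i = np.asarray(inserted_cpm, dtype=float).copy()
    zero_e = (np.asarray(enriched_raw) == 0) & (np.asarray(inserted_raw) > 0)
    e[zero_e] = 0.5 * 1e6 / depth_e
    i[zero_e] = (np.asarray(inserted_raw)[zero_e] + 0.5) * 1e6 / depth_i
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2((e / f) / i)


def _pool_counts(table: pd.DataFrame) -> pd.DataFrame:
    pooled = (table.groupby(["element_id", "channel"], as_index=False)
              .agg(count=("count", "sum")))
    pooled["replicate"] = "pooled"
    return pooled


def epigenetic_activity(table: pd.DataFrame, controls,
                        channel: str, pool: bool = True,
                        min_inserted: int = 10,
                        trim_m: float = 0.30, trim_a: float = 0.05,
                        ) -> pd.DataFrame:
    """Per-replicate and replicate-pooled log2(enriched/inserted) activity.

    ``controls`` is the set of negative-control element ids anchoring the
    TMM factor.  Elements with zero inserted count in a replicate are
    missing for that replicate; elements with pooled inserted count below
    ``min_inserted`` have no pooled score.
    """
    if channel not in ASSAY_OF_CHANNEL:
        raise ValueError(f"not an enriched channel: {channel!r}")
    assay = ASSAY_OF_CHANNEL[channel]
    controls = set(controls)
    sub = table[table["channel"].isin([CHANNEL_INSERTED, channel])]
    frames = []
    replicates = sorted(sub.loc[sub["replicate"] != "pooled", "replicate"]
                        .unique())
    parts = [(rep, sub[sub["replicate"] == rep]) for rep in replicates]
    if pool:
        parts.append(("pooled", _pool_counts(sub[sub["replicate"] != "pooled"])))
    for rep, part in parts:
        wide = (part.pivot_table(index="element_id", columns="channel",
                                 values="count", aggfunc="sum")
                .reindex(columns=[channel, CHANNEL_INSERTED]).fillna(0))
        depth_e = wide[channel].sum()
        depth_i = wide[CHANNEL_INSERTED].sum()
        if depth_e == 0 or depth_i == 0:
            raise ValueError(f"zero channel total in replicate {rep}")
        e_cpm = wide[channel] * 1e6 / depth_e
        i_cpm = wide[CHANNEL_INSERTED] * 1e6 / depth_i
        ctrl = wide.index.isin(controls)
        f = tmm_factor(e_cpm[ctrl], i_cpm[ctrl], trim_m, trim_a)
        act = _ratio_log2(e_cpm, i_cpm, wide[channel], wide[CHANNEL_INSERTED],
                          f, depth_e, depth_i)
        min_ins = min_inserted if rep == "pooled" else 1
        ok = wide[CHANNEL_INSERTED].values >= min_ins
        frames.append(pd.DataFrame({
            "element_id": wide.index[ok], "assay": assay, "replicate": rep,
            "log2_activity": act[ok],
            "support": wide[CHANNEL_INSERTED].values[ok].astype(int)}))
    return pd.concat(frames, ignore_index=True)[ACTIVITY_COLUMNS]


def mpra_activity(barcode_table: pd.DataFrame, controls,
                  pool: bool = True, aggregation: str = "log_mean",
                  trim_m: float = 0.30, trim_a: float = 0.05) -> pd.DataFrame:
    """Transcriptional activity from barcode-level DNA/RNA counts.

    Per replicate the per-barcode RNA/DNA ratio is computed on the CPM
    scale; ``log_mean`` aggregation averages log2 ratios across an
    element's barcodes (log of the geometric mean), ``ratio_of_sums``
    takes log2 of the summed-count ratio.  The TMM factor from control
    elements anchors the control expectation at zero.  Pooling sums
    barcode counts across replicates before the same computation.
    """
    if aggregation not in ("log_mean", "ratio_of_sums"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    controls = set(controls)
    parts = [(rep, g) for rep, g in barcode_table.groupby("replicate")]
    if pool:
        pooled = (barcode_table.groupby(["element_id", "barcode"],
                                        as_index=False)
                  .agg(dna=("dna", "sum"), rna=("rna", "sum")))
        parts.append(("pooled", pooled))
    frames = []
    for rep, part in parts:
        depth_d = part["dna"].sum()
        depth_r = part["rna"].sum()
        elem = (part.groupby("element_id")
                .agg(dna=("dna", "sum"), rna=("rna", "sum"),
                     n_barcodes=("barcode", "nunique"),
                     mean_log_ratio=("rna", lambda s: np.nan)))
        # per-barcode log2 ratios, aggregated by element
        lr = np.log2(part["rna"] / part["dna"])
        elem["mean_log_ratio"] = lr.groupby(part["element_id"]).mean()
        ctrl = elem.index.isin(controls)
        f = tmm_factor(elem.loc[ctrl, "rna"] * 1e6 / depth_r,
                       elem.loc[ctrl, "dna"] * 1e6 / depth_d,
                       trim_m, trim_a)
        if aggregation == "log_mean":
            act = (elem["mean_log_ratio"] + np.log2(depth_d / depth_r)
                   - np.log2(f))
        else:
            act = (np.log2(elem["rna"] / elem["dna"])
                   + np.log2(depth_d / depth_r) - np.log2(f))
        frames.append(pd.DataFrame({
            "element_id": elem.index, "assay": "MPRA", "replicate": rep,
            "log2_activity": act.values,
            "support": elem["n_barcodes"].values}))
    return pd.concat(frames, ignore_index=True)[ACTIVITY_COLUMNS]


def category_tests(records: pd.DataFrame, categories: dict[str, str],
                   reference: str = "random_genomic") -> pd.DataFrame:
    """Two-sided Mann-Whitney-Wilcoxon test of each category against the
    reference category, BH-adjusted within assay.

    ``records`` must carry pooled activities (one row per element per
    assay); ``categories`` maps element_id -> category label.
    """
    df = records.copy()
    df["category"] = df["element_id"].map(categories)
    out_rows = []
    for assay, sub in df.groupby("assay"):
        ref = sub.loc[sub["category"] == reference, "log2_activity"].dropna()
        if ref.empty:
            raise ValueError(f"reference category {reference!r} empty "
                             f"for assay {assay}")
        for cat, grp in sub.groupby("category"):
            if cat == reference:
                continue
            vals = grp["log2_activity"].dropna()
            if len(vals) < 2:
                warnings.warn(f"category {cat} ({assay}): <2 elements, skipped")
                continue
            u, p = stats.mannwhitneyu(vals, ref, alternative="two-sided")
            out_rows.append({"assay": assay, "category": cat,
                             "n": len(vals), "n_ref": len(ref),
                             "U": u, "p": p})
    out = pd.DataFrame(out_rows)
    if not out.empty:
        out["adjusted_p"] = np.nan
        for assay, idx in out.groupby("assay").groups.items():
            out.loc[idx, "adjusted_p"] = bh_adjust(out.loc[idx, "p"])
    return out


def replicate_qc(records: pd.DataFrame,
                 value: str = "log2_activity") -> pd.DataFrame:
    """Pairwise Spearman correlation between replicates, per assay, over
    elements observed in both members of each pair."""
    rows = []
    reps_df = records[records["replicate"] != "pooled"]
    for assay, sub in reps_df.groupby("assay"):
        wide = sub.pivot_table(index="element_id", columns="replicate",
                               values=value)
        for a, b in combinations(sorted(wide.columns), 2):
            both = wide[[a, b]].dropna()
            rho = (stats.spearmanr(both[a], both[b]).statistic
                   if len(both) > 1 else np.nan)
            rows.append({"assay": assay, "replicate_a": a, "replicate_b": b,
                         "spearman_rho": rho, "n": len(both)})
    return pd.DataFrame(rows)
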