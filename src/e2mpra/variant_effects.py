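"""Count-level variant-effect estimation for saturation-mutagenesis
libraries.

For one CRE's single-nucleotide substitution library the effect of every
variant on an assay is estimated jointly by ordinary least squares:

    log2(enriched + 0.5) ~ log2(inserted + 0.5) + N + intercept

where *enriched* is the per-element UMI (or RNA-barcode) count,
*inserted* the gDNA UMI (or DNA-barcode) count accounting for
integration frequency, and ``N`` the matrix of 0/1 indicators, one
column per variant, with the wild type as the baseline.  Observations
are element x replicate rows.  The "offset" in the model formula can be
read either as a free intercept (default) or as a fixed unit coefficient
on log2(inserted); both modes are provided.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .library_design import DesignElement
from .read_counting import (CHANNEL_ATAC, CHANNEL_DNA, CHANNEL_H3K27AC,
                            CHANNEL_INSERTED, CHANNEL_RNA)

logger = logging.getLogger(__name__)

__all__ = ["snv_regression", "winsorize_wt", "ASSAY_CHANNELS"]

#: assay -> (enriched-like channel, inserted-like channel)
ASSAY_CHANNELS = {
    "MPRA": (CHANNEL_RNA, CHANNEL_DNA),
    "ATAC": (CHANNEL_ATAC, CHANNEL_INSERTED),
    "H3K27ac": (CHANNEL_H3K27AC, CHANNEL_INSERTED),
}


def _wide_counts(counts: pd.DataFrame, num: str, den: str) -> pd.DataFrame:
    sub = counts[counts["channel"].isin([num, den])]
    wide = sub.pivot_table(index=["element_id", "replicate"],
                           columns="channel", values="count", aggfunc="sum")
    return wide.reindex(columns=[num, den]).fillna(0).reset_index()


def snv_regression(counts: pd.DataFrame, designs: list[DesignElement],
                   assay: str, offset_mode: str = "intercept",
                   pseudocount: float = 0.5,
                   alpha: float = 0.01) -> pd.DataFrame:
    """Fit the joint variant-effect model for one CRE and assay.

    ``designs`` must contain the WT element (category ``WT``) and its
    single-nucleotide variants (category ``snv``).  Returns one row per
    estimable variant with the effect ``beta`` (log2 units), its
    two-sided t-test ``p`` and a ``significant`` flag at raw p < alpha.
    Variants with no count rows are dropped and listed in
    ``attrs['missing_variants']``.
    """
    if assay not in ASSAY_CHANNELS:
        raise ValueError(f"unknown assay {assay!r}")
    if offset_mode not in ("intercept", "offset"):
        raise ValueError(f"unknown offset mode {offset_mode!r}")
    num, den = ASSAY_CHANNELS[assay]

    wt = [d for d in designs if d.category == "WT"]
    variants = {d.element_id: d for d in designs if d.category == "snv"}
    if len(wt) != 1:
        raise ValueError(f"need exactly one WT element, found {len(wt)}")
    wt_id = wt[0].element_id
    cre_id = wt[0].template_id

    wide = _wide_counts(counts, num, den)
    wide = wide[wide["element_id"].isin(set(variants) | {wt_id})]
    if wide.empty or (wide[num] == 0).all():
        raise ValueError("enriched channel is empty for this CRE")
    replicates = set(wide["replicate"])
    wt_reps = set(wide.loc[wide["element_id"] == wt_id, "replicate"])
    if wt_reps != replicates:
        raise ValueError(f"WT missing in replicates {replicates - wt_reps}: "
                         "baseline not identifiable")

    y = np.log2(wide[num] + pseudocount)
    x0 = np.log2(wide[den] + pseudocount)
    present = [v for v in variants if v in set(wide["element_id"])]
    missing = sorted(set(variants) - set(present))
    indic = pd.DataFrame(
        {v: (wide["element_id"] == v).astype(float) for v in present})
    if offset_mode == "intercept":
        X = pd.concat([x0.rename("log2_inserted"), indic], axis=1)
        X = sm.add_constant(X)
    else:  # true offset: fixed unit slope on log2(inserted)
        y = y - x0
        X = sm.add_constant(indic)
    fit = sm.OLS(y, X).fit()

    rows = []
    for v in present:
        pos, ref, alt = variants[v].variant
        rows.append({"cre_id": cre_id, "element_id": v, "position": pos,
                     "ref": ref, "alt": alt, "assay": assay,
                     "beta": fit.params[v], "p": fit.pvalues[v],
                     "significant": fit.pvalues[v] < alpha})
    out = pd.DataFrame(rows).sort_values(["position", "alt"],
                                         ignore_index=True)
    out.attrs["missing_variants"] = missing
    out.attrs["slope_log2_inserted"] = (
        float(fit.params.get("log2_inserted", 1.0)))
    out.attrs["intercept"] = float(fit.params.get("const", 0.0))
    if missing:
        logger.info("snv_regression %s/%s: %d variants unobserved",
                    cre_id, assay, len(missing))
    return out


def winsorize_wt(counts: pd.DataFrame, designs: list[DesignElement],
                 quantile: float = 0.99) -> pd.DataFrame:
    """Cap WT counts at the given quantile of the variant counts, per
    (replicate, channel), symmetrically over all channels present.

    Counters the anomalously deep WT amplification seen in fragment
    channels, which otherwise dominates the regression baseline.
    ``quantile=1.0`` is the identity.
    """
    wt_ids = {d.element_id for d in designs if d.category == "WT"}
    var_ids = {d.element_id for d in designs if d.category == "snv"}
    out = counts.copy()
    if quantile >= 1.0 or not wt_ids:
        return out
    for (rep, ch), grp in counts.groupby(["replicate", "channel"]):
        var_counts = grp.loc[grp["element_id"].isin(var_ids), "count"]
        if var_counts.empty:
            continue
        cap = float(np.quantile(var_counts, quantile))
        mask = ((out["replicate"] == rep) & (out["channel"] == ch)
                & out["element_id"].isin(wt_ids))
        out.loc[mask, "count"] = np.minimum(
            out.loc[mask, "count"], int(cap))
    return out
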