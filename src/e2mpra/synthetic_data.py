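"""Synthetic assay generator with planted ground truth.

Emulates the statistical structure of the assay so the whole pipeline is
testable end to end: each element carries a latent log2 activity per
assay built additively from planted motif effects, pairwise synergies,
variant and window effects, with negative-control elements fixed at
exactly zero.  Counts follow the error model the quantification assumes:

* per-element lentiviral integration depth (inserted gDNA UMIs) is
  negative binomial — overdispersed across elements and replicates;
* enriched epigenomic UMIs are Poisson conditional on the integration
  depth, with rate scaled by 2**latent and a per-replicate log2 offset;
* barcodes per element are truncated Poisson (>= 1); per-barcode DNA
  counts are negative binomial and RNA counts Poisson with rate
  dna * 2**latent.

Default depth scales (~80 barcodes and ~300 inserted / ~50-100 enriched
UMIs per element) mirror the coverage a typical run of the assay
reports.  Everything is bit-reproducible from (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .library_design import DesignElement, motif_counts
from .read_counting import (CHANNEL_ATAC, CHANNEL_H3K27AC, CHANNEL_INSERTED,
                            COUNT_COLUMNS, ReadRecord)

__all__ = [
    "ASSAYS",
    "CONTROL_CATEGORIES",
    "SimConfig",
    "SimTruth",
    "SimCounts",
    "plant_effects",
    "simulate_counts",
    "simulate_wt_anomaly",
    "zero_inserted_for_motif",
    "expand_to_reads",
    "make_association_reads",
]

ASSAYS = ("MPRA", "ATAC", "H3K27ac")
ENRICHED_CHANNEL = {"ATAC": CHANNEL_ATAC, "H3K27ac": CHANNEL_H3K27AC}
#: categories whose latent activity is pinned to exactly zero
CONTROL_CATEGORIES = frozenset({"random_genomic", "scrambled"})
_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Depth and noise parameters of the generator.

    ``dispersion`` is the negative-binomial alpha (var = m + alpha m^2);
    ``replicate_sd`` the sd of per-(assay, replicate) log2 offsets;
    ``noise_sd`` the sd of element-level latent noise (off by default so
    planted truths are exact).
    """

    mean_inserted: float = 300.0
    mean_enriched: float = 80.0
    mean_barcodes: float = 80.0
    mean_dna_per_barcode: float = 30.0
    dispersion: float = 0.1
    replicate_sd: float = 0.1
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.mean_inserted, self.mean_enriched, self.mean_barcodes,
               self.mean_dna_per_barcode) <= 0:
            raise ValueError("depth parameters must be positive")


@dataclass
class SimTruth:
    """Planted ground truth: latent log2 activities plus the effect maps
    and parameters they were built from."""

    seed: int
    latent: pd.DataFrame  # index element_id, columns ASSAYS
    designs: list[DesignElement]
    config: SimConfig
    motif_effects: dict = field(default_factory=dict)
    synergy: dict = field(default_factory=dict)
    variant_effects: dict = field(default_factory=dict)
    window_effects: dict = field(default_factory=dict)


@dataclass
class SimCounts:
    """Simulated count data: fragment-channel table and barcode-level
    DNA/RNA counts."""

    fragments: pd.DataFrame
    barcodes: pd.DataFrame


def plant_effects(designs: list[DesignElement], seed: int = 0,
                  motif_effects: dict[str, dict[str, float]] | None = None,
                  synergy: dict[str, dict[tuple[str, str], float]] | None = None,
                  variant_effects: dict[str, dict[str, float]] | None = None,
                  window_effects: dict[str, dict[str, float]] | None = None,
                  category_effects: dict[str, dict[str, float]] | None = None,
                  config: SimConfig | None = None) -> SimTruth:
    """Build per-element latent activities from additive planted effects.

    All effect maps are keyed by assay first: ``motif_effects['MPRA']``
    maps motif name -> per-copy effect; ``synergy[assay]`` maps a sorted
    motif pair -> extra activity for elements carrying both motifs;
    ``variant_effects[assay]`` and ``window_effects[assay]`` map
    element_id -> effect; ``category_effects[assay]`` maps a category
    label -> baseline.  Negative-control categories are pinned to zero
    regardless.  Deterministic given ``seed``.
    """
    config = config or SimConfig()
    motif_effects = motif_effects or {}
    synergy = synergy or {}
    variant_effects = variant_effects or {}
    window_effects = window_effects or {}
    category_effects = category_effects or {}

    present_motifs = {m for d in designs for m in motif_counts(d)}
    for assay, eff in motif_effects.items():
        missing = set(eff) - present_motifs
        if missing:
            raise ValueError(f"{assay}: effects for motifs absent from the "
                             f"designs: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    rows = {}
    for d in designs:
        vals = []
        mc = motif_counts(d)
        for assay in ASSAYS:
            if d.category in CONTROL_CATEGORIES:
                vals.append(0.0)
                continue
            v = category_effects.get(assay, {}).get(d.category, 0.0)
            eff = motif_effects.get(assay, {})
            v += sum(eff.get(m, 0.0) * n for m, n in mc.items())
            syn = synergy.get(assay, {})
            names = sorted(mc)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    v += syn.get((a, b), 0.0)
            v += variant_effects.get(assay, {}).get(d.element_id, 0.0)
            v += window_effects.get(assay, {}).get(d.element_id, 0.0)
            if config.noise_sd > 0:
                v += rng.normal(0.0, config.noise_sd)
            vals.append(v)
        rows[d.element_id] = vals
    latent = pd.DataFrame.from_dict(rows, orient="index", columns=list(ASSAYS))
    return SimTruth(seed=seed, latent=latent, designs=list(designs),
                    config=config, motif_effects=motif_effects,
                    synergy=synergy, variant_effects=variant_effects,
                    window_effects=window_effects)


def _nb(rng: np.random.Generator, mean, alpha: float, size) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mean), size=size)


def simulate_counts(truth: SimTruth, replicates: int = 3,
                    channels: str = "all") -> SimCounts:
    """Draw a count dataset from the planted truth.

    ``channels`` is ``'all'``, ``'fragments'`` (skip barcode simulation)
    or ``'barcodes'`` (skip the fragment channels) — useful for keeping
    large calibration sweeps cheap.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    cfg = truth.config
    rng = np.random.default_rng((truth.seed, 2 ** 16 + replicates))
    ids = truth.latent.index.to_numpy()
    n = len(ids)
    offsets = {(assay, r): rng.normal(0.0, cfg.replicate_sd)
               for assay in ASSAYS for r in range(1, replicates + 1)}

    frag_frames = []
    if channels in ("all", "fragments"):
        rate = cfg.mean_enriched / cfg.mean_inserted
        for r in range(1, replicates + 1):
            inserted = _nb(rng, cfg.mean_inserted, cfg.dispersion, (n,))
            frag_frames.append(pd.DataFrame(
                {"element_id": ids, "replicate": r,
                 "channel": CHANNEL_INSERTED, "count": inserted,
                 "n_barcodes": pd.NA}))
            for assay in ("ATAC", "H3K27ac"):
                lat = truth.latent[assay].to_numpy()
                lam = inserted * rate * 2.0 ** (lat + offsets[(assay, r)])
                frag_frames.append(pd.DataFrame(
                    {"element_id": ids, "replicate": r,
                     "channel": ENRICHED_CHANNEL[assay],
                     "count": rng.poisson(lam), "n_barcodes": pd.NA}))
    fragments = (pd.concat(frag_frames, ignore_index=True)
                 if frag_frames else pd.DataFrame(columns=COUNT_COLUMNS))

    bc_rows = []
    if channels in ("all", "barcodes"):
        n_bc = np.maximum(rng.poisson(cfg.mean_barcodes, size=n), 1)
        elem_idx = np.repeat(np.arange(n), n_bc)
        bc_labels = np.concatenate(
            [np.char.add(f"{eid}|bc", np.arange(k).astype(str))
             for eid, k in zip(ids, n_bc)])
        lat = truth.latent["MPRA"].to_numpy()[elem_idx]
        total = len(elem_idx)
        for r in range(1, replicates + 1):
            dna = _nb(rng, cfg.mean_dna_per_barcode, cfg.dispersion, (total,))
            rna = rng.poisson(dna * 2.0 ** (lat + offsets[("MPRA", r)]))
            bc_rows.append(pd.DataFrame(
                {"element_id": ids[elem_idx], "replicate": r,
                 "barcode": bc_labels, "dna": dna, "rna": rna}))
    barcodes = (pd.concat(bc_rows, ignore_index=True) if bc_rows
                else pd.DataFrame(columns=["element_id", "replicate",
                                           "barcode", "dna", "rna"]))
    # the both-channels rule: a barcode carries no ratio without both counts
    if not barcodes.empty:
        barcodes = barcodes[(barcodes["dna"] > 0)
                            & (barcodes["rna"] > 0)].reset_index(drop=True)
    return SimCounts(fragments=fragments, barcodes=barcodes)


def simulate_wt_anomaly(counts: pd.DataFrame, wt_ids,
                        factor: float = 20.0) -> pd.DataFrame:
    """Inflate WT fragment-channel counts by ``factor`` — reproduces the
    anomalously deep WT amplification that motivates the substitution-
    median MAD reference and WT winsorization."""
    out = counts.copy()
    mask = out["element_id"].isin(set(wt_ids))
    out.loc[mask, "count"] = (out.loc[mask, "count"] * factor).round() \
        .astype(int)
    return out


def zero_inserted_for_motif(counts: pd.DataFrame,
                            designs: list[DesignElement],
                            motif: str) -> pd.DataFrame:
    """Zero the inserted (gDNA) counts of every element carrying a motif —
    emulates amplification dropout of GC-rich motif sequences."""
    hit = {d.element_id for d in designs if motif in motif_counts(d)}
    out = counts.copy()
    mask = (out["element_id"].isin(hit)
            & (out["channel"] == CHANNEL_INSERTED))
    out.loc[mask, "count"] = 0
    return out


# --------------------------------------------------------------------------
# expansion to read-level fixtures
# --------------------------------------------------------------------------

def _encode_umi(index: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(_BASES[index % 4])
        index //= 4
    return "".join(out)


def expand_to_reads(truth: SimTruth, fragments: pd.DataFrame | None = None,
                    barcodes: pd.DataFrame | None = None
                    ) -> list[ReadRecord]:
    """Expand count tables into read records with globally unique UMIs
    (fragment UMIs 15-mers, barcode UMIs 16-mers), so that re-counting
    the reads reproduces the tables exactly."""
    seq_of = {d.element_id: d.sequence for d in truth.designs}
    reads: list[ReadRecord] = []
    counter = 0
    if fragments is not None:
        for r in fragments.itertuples(index=False):
            for _ in range(int(r.count)):
                reads.append(ReadRecord(seq_of[r.element_id], r.channel,
                                        int(r.replicate),
                                        umi=_encode_umi(counter, 15)))
                counter += 1
    if barcodes is not None:
        for r in barcodes.itertuples(index=False):
            for channel, k in (("dna_bc", r.dna), ("rna_bc", r.rna)):
                for _ in range(int(k)):
                    reads.append(ReadRecord(seq_of[r.element_id], channel,
                                            int(r.replicate), barcode=r.barcode,
                                            umi=_encode_umi(counter, 16)))
                    counter += 1
    return reads


def make_association_reads(truth: SimTruth, barcodes: pd.DataFrame,
                           coverage: int = 3) -> list[ReadRecord]:
    """Association-channel reads linking each simulated barcode to its
    element's sequence, ``coverage`` supporting reads per barcode."""
    seq_of = {d.element_id: d.sequence for d in truth.designs}
    pairs = barcodes[["element_id", "barcode"]].drop_duplicates()
    reads = []
    for r in pairs.itertuples(index=False):
        for j in range(coverage):
            reads.append(ReadRecord(seq_of[r.element_id], "assoc", 1,
                                    barcode=r.barcode, umi=None))
    return reads
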