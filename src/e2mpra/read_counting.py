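"""Read-level quantification: barcode association, barcode/UMI counting
and element-level count tables.

Inserts are assigned to designed elements only on exact, full-length,
same-orientation sequence identity (the library references are the
designed oligos themselves, so mismatch-free assignment is the intended
behaviour).  Barcode-to-element association requires a minimum read
support and discards barcodes claimed by more than one element.  UMIs are
deduplicated either by exact-sequence collapse (default) or by
directional adjacency clustering (1-mismatch neighbours absorbed when the
parent count is at least twice the child count minus one).

Count tables are plain pandas DataFrames with columns
``element_id, replicate, channel, count[, n_barcodes]``.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "CHANNEL_ASSOC", "CHANNEL_DNA", "CHANNEL_RNA",
    "CHANNEL_INSERTED", "CHANNEL_ATAC", "CHANNEL_H3K27AC",
    "MPRA_CHANNELS", "FRAGMENT_CHANNELS",
    "associate_barcodes",
    "count_mpra_barcodes",
    "barcode_counts_to_table",
    "count_fragment_umis",
    "filter_elements",
    "dedup_umis",
    "read_fastq_reads", "write_fastq_reads",
    "read_reads_tsv", "write_reads_tsv",
    "read_count_table", "write_count_table",
]

CHANNEL_ASSOC = "assoc"
CHANNEL_DNA = "dna_bc"
CHANNEL_RNA = "rna_bc"
CHANNEL_INSERTED = "inserted"
CHANNEL_ATAC = "enriched_ATAC"
CHANNEL_H3K27AC = "enriched_H3K27ac"
MPRA_CHANNELS = (CHANNEL_DNA, CHANNEL_RNA)
FRAGMENT_CHANNELS = (CHANNEL_INSERTED, CHANNEL_ATAC, CHANNEL_H3K27AC)
_BARCODE_CHANNELS = (CHANNEL_ASSOC, CHANNEL_DNA, CHANNEL_RNA)

COUNT_COLUMNS = ["element_id", "replicate", "channel", "count", "n_barcodes"]


@dataclass(frozen=True)
class ReadRecord:
    """One processed sequencing read.

    ``barcode`` is present for association and barcode-counting channels;
    ``umi`` is present for every counting channel.
    """

    insert_sequence: str
    channel: str
    replicate: int = 1
    barcode: str | None = None
    umi: str | None = None

    def __post_init__(self) -> None:
        if self.channel in _BARCODE_CHANNELS and self.barcode is None:
            raise ValueError(f"channel {self.channel} requires a barcode")


# --------------------------------------------------------------------------
# UMI deduplication
# --------------------------------------------------------------------------

def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return mism == 1


def dedup_umis(umis: list[str], mode: str = "unique") -> int:
    """Number of distinct molecules among raw UMI observations.

    ``unique`` collapses identical sequences; ``directional`` additionally
    absorbs 1-mismatch neighbours whose count is low relative to the
    parent (count_parent >= 2 * count_child - 1), the standard adjacency
    rule for sequencing-error UMIs.
    """
    if not umis:
        return 0
    counts = Counter(umis)
    if mode == "unique":
        return len(counts)
    if mode != "directional":
        raise ValueError(f"unknown dedup mode {mode!r}")
    order = sorted(counts, key=lambda u: (-counts[u], u))
    assigned: set[str] = set()
    n_clusters = 0
    for root in order:
        if root in assigned:
            continue
        n_clusters += 1
        stack = [root]
        assigned.add(root)
        while stack:
            parent = stack.pop()
            for child in order:
                if child in assigned:
                    continue
                if _hamming1(parent, child) and \
                        counts[parent] >= 2 * counts[child] - 1:
                    assigned.add(child)
                    stack.append(child)
    return n_clusters


# --------------------------------------------------------------------------
# barcode association
# --------------------------------------------------------------------------

def associate_barcodes(reads, designs, min_cov: int = 3) -> dict[str, tuple[str, int]]:
    """Map barcodes to elements from association reads.

    A read counts toward a barcode only when its insert matches a design
    sequence exactly and full-length.  Barcodes whose reads match more
    than one element are discarded, as are barcodes with fewer than
    ``min_cov`` supporting reads.
    """
    seq_to_element: dict[str, str] = {}
    collisions = []
    for d in designs:
        if d.sequence in seq_to_element:
            collisions.append((seq_to_element[d.sequence], d.element_id))
        seq_to_element[d.sequence] = d.element_id
    if collisions:
        raise ValueError(f"duplicate design sequences: {collisions}")

    support: dict[str, Counter] = defaultdict(Counter)
    for r in reads:
        if r.channel != CHANNEL_ASSOC:
            continue
        element = seq_to_element.get(r.insert_sequence)
        if element is not None:
            support[r.barcode][element] += 1

    out: dict[str, tuple[str, int]] = {}
    n_multi = n_low = 0
    for bc, ctr in support.items():
        if len(ctr) > 1:
            n_multi += 1
            continue
        (element, n), = ctr.items()
        if n < min_cov:
            n_low += 1
            continue
        out[bc] = (element, n)
    logger.info("associate_barcodes: kept %d barcodes, discarded %d multi-"
                "element and %d low-coverage", len(out), n_multi, n_low)
    return out


# --------------------------------------------------------------------------
# MPRA barcode counting
# --------------------------------------------------------------------------

def count_mpra_barcodes(dna_reads, rna_reads, barcode_map,
                        dedup: str = "unique") -> pd.DataFrame:
    """UMI-deduplicated DNA/RNA counts per associated barcode.

    Within each replicate only barcodes observed in *both* the DNA and
    RNA channels are retained (a barcode seen in one channel only carries
    no ratio information).  Unknown barcodes are skipped and tallied in
    the returned frame's ``attrs['n_unknown_barcodes']``.

    Returns a barcode-level frame with columns
    ``element_id, replicate, barcode, dna, rna``.
    """
    umis: dict[tuple[int, str, str], list[str]] = defaultdict(list)
    n_unknown = 0
    for reads, channel in ((dna_reads, CHANNEL_DNA), (rna_reads, CHANNEL_RNA)):
        for r in reads:
            if r.barcode not in barcode_map:
                n_unknown += 1
                continue
            umis[(r.replicate, r.barcode, channel)].append(r.umi)

    keys = {(rep, bc) for rep, bc, _ in umis}
    rows = []
    for rep, bc in sorted(keys):
        dna = dedup_umis(umis.get((rep, bc, CHANNEL_DNA), []), dedup)
        rna = dedup_umis(umis.get((rep, bc, CHANNEL_RNA), []), dedup)
        if dna == 0 or rna == 0:
            continue
        rows.append({"element_id": barcode_map[bc][0], "replicate": rep,
                     "barcode": bc, "dna": dna, "rna": rna})
    df = pd.DataFrame(rows, columns=["element_id", "replicate", "barcode",
                                     "dna", "rna"])
    df.attrs["n_unknown_barcodes"] = n_unknown
    logger.info("count_mpra_barcodes: %d barcode records, %d unknown reads",
                len(df), n_unknown)
    return df


def barcode_counts_to_table(barcode_df: pd.DataFrame) -> pd.DataFrame:
    """Collapse a barcode-level frame to an element-level count table with
    per-element barcode support (``n_barcodes``)."""
    if barcode_df.empty:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    g = barcode_df.groupby(["element_id", "replicate"])
    agg = g.agg(dna=("dna", "sum"), rna=("rna", "sum"),
                n_barcodes=("barcode", "nunique")).reset_index()
    rows = []
    for r in agg.itertuples(index=False):
        rows.append({"element_id": r.element_id, "replicate": r.replicate,
                     "channel": CHANNEL_DNA, "count": r.dna,
                     "n_barcodes": r.n_barcodes})
        rows.append({"element_id": r.element_id, "replicate": r.replicate,
                     "channel": CHANNEL_RNA, "count": r.rna,
                     "n_barcodes": r.n_barcodes})
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


# --------------------------------------------------------------------------
# fragment (epigenomic) counting
# --------------------------------------------------------------------------

def count_fragment_umis(reads, designs, dedup: str = "unique") -> pd.DataFrame:
    """Per-element deduplicated UMI counts for the fragment channels
    (inserted gDNA and the enriched epigenomic assays).

    Reads not matching any design sequence exactly are left unassigned
    and tallied in ``attrs['n_unassigned']``.
    """
    seq_to_element = {d.sequence: d.element_id for d in designs}
    umis: dict[tuple[str, int, str], list[str]] = defaultdict(list)
    n_unassigned = 0
    for r in reads:
        if r.channel not in FRAGMENT_CHANNELS:
            raise ValueError(f"unexpected channel {r.channel!r}")
        element = seq_to_element.get(r.insert_sequence)
        if element is None:
            n_unassigned += 1
            continue
        umis[(element, r.replicate, r.channel)].append(r.umi)
    rows = [{"element_id": e, "replicate": rep, "channel": ch,
             "count": dedup_umis(u, dedup), "n_barcodes": pd.NA}
            for (e, rep, ch), u in sorted(umis.items())]
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    df.attrs["n_unassigned"] = n_unassigned
    logger.info("count_fragment_umis: %d rows, %d unassigned reads",
                len(df), n_unassigned)
    return df


def filter_elements(table: pd.DataFrame, min_barcodes: int = 5) -> pd.DataFrame:
    """Drop MPRA-channel rows for (element, replicate) pairs supported by
    fewer than ``min_barcodes`` unique barcodes; other channels pass
    through untouched."""
    if table.empty or min_barcodes <= 0:
        return table.copy()
    is_mpra = table["channel"].isin(MPRA_CHANNELS)
    n_bc = pd.to_numeric(table["n_barcodes"], errors="coerce").fillna(0)
    low = is_mpra & (n_bc < min_barcodes)
    n_removed = table.loc[low, ["element_id", "replicate"]].drop_duplicates()
    if len(n_removed):
        logger.info("filter_elements: removed %d element-replicate pairs "
                    "below %d barcodes", len(n_removed), min_barcodes)
    return table.loc[~low].reset_index(drop=True)


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------
# FASTQ convention: UMI (and barcode, when present) ride in the read name,
# colon-separated — "@name:barcode:umi" for barcode channels and
# "@name:umi" for fragment channels.

def write_fastq_reads(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            parts = [f"read{i}"]
            if r.barcode is not None:
                parts.append(r.barcode)
            if r.umi is not None:
                parts.append(r.umi)
            name = ":".join(parts)
            fh.write(f"@{name} channel={r.channel} replicate={r.replicate}\n"
                     f"{r.insert_sequence}\n+\n"
                     f"{'I' * len(r.insert_sequence)}\n")


def read_fastq_reads(path: str | Path, channel: str | None = None,
                     replicate: int | None = None) -> list[ReadRecord]:
    """Parse FASTQ with header-embedded barcode/UMI.

    ``channel``/``replicate`` override the header tags when given (for
    plain FASTQ from other sources).
    """
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        tags = dict(kv.split("=") for kv in rec.description.split()[1:]
                    if "=" in kv)
        ch = channel or tags.get("channel")
        rep = replicate if replicate is not None else int(tags.get("replicate", 1))
        if ch is None:
            raise ValueError("channel not given and absent from header")
        fields = rec.id.split(":")
        barcode = umi = None
        if ch in _BARCODE_CHANNELS:
            if len(fields) < 3:
                raise ValueError(f"read {rec.id}: expected name:barcode:umi")
            barcode, umi = fields[-2], fields[-1]
        elif len(fields) >= 2:
            umi = fields[-1]
        out.append(ReadRecord(str(rec.seq), ch, rep, barcode, umi))
    return out


def write_reads_tsv(reads, path: str | Path) -> None:
    pd.DataFrame([{"insert_sequence": r.insert_sequence, "channel": r.channel,
                   "replicate": r.replicate, "barcode": r.barcode or "",
                   "umi": r.umi or ""} for r in reads]
                 ).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | Path) -> list[ReadRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [ReadRecord(r.insert_sequence, r.channel, int(r.replicate),
                       r.barcode or None, r.umi or None)
            for r in df.itertuples(index=False)]


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["count"] = df["count"].astype(int)
    return df
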