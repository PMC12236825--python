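"""Reporter-library design: synthetic-enhancer grammar, saturation
mutagenesis and window-perturbation libraries.

Three library families are produced, all on 100-bp elements:

* ``grammar`` — transcription-factor binding motifs arranged on neutral
  template sequences in three classes: homotypic copy-number series
  (Class 1), two-motif heterotypic arrangements (Class 2) and exhaustive
  orderings of four distinct motifs (Class 3).
* ``perturbation`` — per-CRE saturation mutagenesis (every position to
  every alternative base) and randomized 6-bp sliding windows, with a
  motif-creation rejection screen on the mutated context.
* ``pilot`` — a six-category benchmark library (negative controls,
  active/inactive genomic and synthetic sequences).

Coordinates are 1-based inclusive within the element; position 1 is
distal and position 100 proximal to the minimal promoter.
"""

from __future__ import annotations

import itertools
import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TFMotif",
    "DesignElement",
    "GrammarDesignSpec",
    "DesignError",
    "PlacementError",
    "WindowRejectionError",
    "default_motifs",
    "neutral_templates",
    "build_class1",
    "build_class2",
    "build_class3",
    "build_grammar_library",
    "build_snv_library",
    "build_window_library",
    "build_pilot_library",
    "build_grammar_controls",
    "scan_motifs",
    "scramble_sequence",
    "random_sequence",
    "motif_counts",
    "elements_to_frame",
    "frame_to_elements",
    "write_design_fasta",
    "write_manifest",
    "read_manifest",
    "read_motifs_tsv",
    "write_motifs_tsv",
]

ELEMENT_LENGTH = 100
DEFAULT_COPY_NUMBERS = (1, 2, 4)
# Two-motif arrangements per unordered pair: four slots filled 2:2.
DEFAULT_CLASS2_PATTERNS = ("AABB", "ABAB", "ABBA", "BBAA")
WINDOW_ATTEMPT_CAP = 1000

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASES = "ACGT"


class DesignError(ValueError):
    """Invalid design input."""


class PlacementError(DesignError):
    """A motif cannot be placed at the requested copy number."""


class WindowRejectionError(DesignError):
    """The motif-creation screen rejected every redraw for a window."""


@dataclass(frozen=True)
class TFMotif:
    """A transcription-factor binding motif given as an IUPAC consensus."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise DesignError(f"motif {self.name}: non-IUPAC codes {sorted(bad)}")
        object.__setattr__(self, "consensus", self.consensus.upper())

    @property
    def length(self) -> int:
        return len(self.consensus)

    def reverse_complement(self) -> str:
        return self.consensus.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DesignElement:
    """One designed library member.

    ``arrangement`` is a tuple of (motif name, copy index, start) with
    1-based inclusive starts.  ``variant`` is (position, ref, alt) for
    single-nucleotide elements; ``window`` is (start, width, replicate)
    for window-randomized elements.  ``k`` is the synergy-regression
    interaction indicator (0 for Class 1, per-motif copy count for
    Class 2, None elsewhere).
    """

    element_id: str
    library: str
    category: str
    template_id: str
    sequence: str
    arrangement: tuple[tuple[str, int, int], ...] = ()
    variant: tuple[int, str, str] | None = None
    window: tuple[int, int, int] | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        if set(self.sequence) - set(_BASES):
            raise DesignError(f"{self.element_id}: sequence must be ACGT")


@dataclass
class GrammarDesignSpec:
    """Inputs for the grammar library builders."""

    motifs: list[TFMotif]
    templates: list[tuple[str, str]]
    copy_numbers: tuple[int, ...] = DEFAULT_COPY_NUMBERS
    class2_patterns: tuple[str, ...] = DEFAULT_CLASS2_PATTERNS
    element_length: int = ELEMENT_LENGTH

    def __post_init__(self) -> None:
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise DesignError("motif names must be unique")
        for tid, seq in self.templates:
            if len(seq) != self.element_length or set(seq) - set(_BASES):
                raise DesignError(f"template {tid}: need {self.element_length}-bp ACGT")
        if any(n <= 0 for n in self.copy_numbers):
            raise DesignError("copy numbers must be positive")


# --------------------------------------------------------------------------
# default motif set and templates
# --------------------------------------------------------------------------

def default_motifs() -> list[TFMotif]:
    """Nine liver-TF binding motifs as synthetic stand-in consensus strings.

    The names follow the TFs assayed in HepG2 grammar libraries; the
    consensus strings are canonical literature consensus sequences
    (synthetic stand-ins, not the exact oligo-pool motif instances).
    """
    return [
        TFMotif("CEBPA", "ATTGCGCAAT"),
        TFMotif("CTCF", "CCACCAGGGGGCGCTA"),
        TFMotif("FOXA1", "TGTTTACTTA"),
        TFMotif("HNF1A", "GTTAATNATTAAC"),
        TFMotif("NR2F2", "TGACCTTTGACCC"),
        TFMotif("ONECUT1", "TATTGATTT"),
        TFMotif("PPARA", "AGGTCAAAGGTCA"),
        TFMotif("REST", "TTCAGCACCACGGACAGCGCC"),
        TFMotif("XBP1", "GCCACGTCAT"),
    ]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def neutral_templates(seed: int = 0, n: int = 2,
                      length: int = ELEMENT_LENGTH) -> list[tuple[str, str]]:
    """Seeded stand-ins for the two neutral genomic template sequences."""
    rng = np.random.default_rng(seed)
    return [(f"template{i + 1}", random_sequence(length, rng)) for i in range(n)]


# --------------------------------------------------------------------------
# grammar library (Class 1/2/3)
# --------------------------------------------------------------------------

def _even_starts(lengths: list[int], n: int, element_length: int) -> list[int]:
    """1-based starts placing ``n`` motifs with centers dividing the element
    into equal gaps: center_i = round(L * (i - 0.5) / n)."""
    starts = []
    for i, length in enumerate(lengths, start=1):
        center = int(math.floor(element_length * (i - 0.5) / n + 0.5))
        starts.append(center - length // 2)
    return starts


def _check_placement(starts: list[int], lengths: list[int], element_length: int,
                     label: str) -> None:
    prev_end = 0
    for s, length in zip(starts, lengths):
        if s < 1 or s + length - 1 > element_length:
            raise PlacementError(f"{label}: motif footprint [{s},{s + length - 1}] "
                                 f"outside [1,{element_length}]")
        if s <= prev_end:
            raise PlacementError(f"{label}: overlapping motif footprints")
        prev_end = s + length - 1


def _place(template: str, placements: list[tuple[str, int]]) -> str:
    """Substitute motif consensus strings into the template at 1-based starts.

    Ambiguity codes are resolved to their first listed base so the element
    stays plain ACGT (only relevant for degenerate consensus positions)."""
    seq = list(template)
    for consensus, start in placements:
        for j, code in enumerate(consensus):
            seq[start - 1 + j] = IUPAC[code][0]
    return "".join(seq)


def build_class1(spec: GrammarDesignSpec) -> list[DesignElement]:
    """Homotypic series: one element per (motif, copy number, template)."""
    if not spec.motifs or not spec.templates:
        raise DesignError("need at least one motif and one template")
    out = []
    for motif in spec.motifs:
        for n in sorted(spec.copy_numbers):
            lengths = [motif.length] * n
            starts = _even_starts(lengths, n, spec.element_length)
            _check_placement(starts, lengths, spec.element_length,
                             f"{motif.name} x{n}")
            for tid, tseq in spec.templates:
                seq = _place(tseq, [(motif.consensus, s) for s in starts])
                arr = tuple((motif.name, i + 1, s) for i, s in enumerate(starts))
                out.append(DesignElement(
                    element_id=f"class1|{motif.name}|x{n}|{tid}",
                    library="grammar", category="1", template_id=tid,
                    sequence=seq, arrangement=arr, k=0))
    return out


def build_class2(spec: GrammarDesignSpec) -> list[DesignElement]:
    """Heterotypic pairs: four-slot 2:2 arrangements per unordered pair."""
    if len(spec.motifs) < 2:
        raise DesignError("Class 2 needs at least two motifs")
    by_name = {m.name: m for m in spec.motifs}
    out = []
    for a, b in itertools.combinations(sorted(by_name), 2):
        for pattern in spec.class2_patterns:
            names = [a if c == "A" else b for c in pattern]
            lengths = [by_name[nm].length for nm in names]
            starts = _even_starts(lengths, len(names), spec.element_length)
            _check_placement(starts, lengths, spec.element_length,
                             f"{a}+{b} {pattern}")
            copies = Counter(names)
            k = max(copies.values())  # per-motif copy count (2 under 2:2)
            for tid, tseq in spec.templates:
                seq = _place(tseq, [(by_name[nm].consensus, s)
                                    for nm, s in zip(names, starts)])
                counter: Counter[str] = Counter()
                arr = []
                for nm, s in zip(names, starts):
                    counter[nm] += 1
                    arr.append((nm, counter[nm], s))
                out.append(DesignElement(
                    element_id=f"class2|{a}+{b}|{pattern}|{tid}",
                    library="grammar", category="2", template_id=tid,
                    sequence=seq, arrangement=tuple(arr), k=k))
    return out


def build_class3(spec: GrammarDesignSpec) -> list[DesignElement]:
    """All orderings of every four-motif subset, one copy each.

    Slot 1 is distal and slot 4 proximal to the minimal promoter.
    """
    if len(spec.motifs) < 4:
        raise DesignError("Class 3 needs at least four motifs")
    by_name = {m.name: m for m in spec.motifs}
    out = []
    for subset in itertools.combinations(sorted(by_name), 4):
        for perm in itertools.permutations(subset):
            lengths = [by_name[nm].length for nm in perm]
            starts = _even_starts(lengths, 4, spec.element_length)
            _check_placement(starts, lengths, spec.element_length,
                             "+".join(perm))
            for tid, tseq in spec.templates:
                seq = _place(tseq, [(by_name[nm].consensus, s)
                                    for nm, s in zip(perm, starts)])
                arr = tuple((nm, 1, s) for nm, s in zip(perm, starts))
                out.append(DesignElement(
                    element_id=f"class3|{'-'.join(perm)}|{tid}",
                    library="grammar", category="3", template_id=tid,
                    sequence=seq, arrangement=arr))
    return out


def build_grammar_library(spec: GrammarDesignSpec) -> list[DesignElement]:
    return build_class1(spec) + build_class2(spec) + build_class3(spec)


def motif_counts(element: DesignElement) -> Counter[str]:
    """Copies of each motif placed on an element."""
    return Counter(name for name, _, _ in element.arrangement)


# --------------------------------------------------------------------------
# perturbation library (SNV + 6-bp windows)
# --------------------------------------------------------------------------

def build_snv_library(wt: DesignElement) -> list[DesignElement]:
    """Saturation mutagenesis: every position to each alternative base.

    Returns the WT element (category ``WT``) followed by 3 x length
    single-nucleotide variants, each at Hamming distance 1 from WT.
    """
    seq = wt.sequence
    if set(seq) - set(_BASES):
        raise DesignError(f"{wt.element_id}: ambiguous base in WT sequence")
    out = [replace(wt, library="perturbation", category="WT",
                   template_id=wt.element_id)]
    for pos in range(1, len(seq) + 1):
        ref = seq[pos - 1]
        for alt in _BASES:
            if alt == ref:
                continue
            mutant = seq[:pos - 1] + alt + seq[pos:]
            out.append(DesignElement(
                element_id=f"{wt.element_id}|snv|{pos}{ref}>{alt}",
                library="perturbation", category="snv",
                template_id=wt.element_id, sequence=mutant,
                variant=(pos, ref, alt)))
    return out


def build_window_library(wt: DesignElement, width: int = 6, replicates: int = 2,
                         screen: list[TFMotif] | None = None,
                         seed: int = 0,
                         attempt_cap: int = WINDOW_ATTEMPT_CAP,
                         include_wt: bool = False) -> list[DesignElement]:
    """Randomize sliding ``width``-bp windows, 1-bp steps, ``replicates``
    independent randomizations per window.

    Every window base is redrawn uniformly from the three non-WT bases, so
    all window positions differ from WT.  A candidate is rejected and
    redrawn whenever the mutated context — the window plus ``width`` bp on
    each side, truncated at the sequence ends — contains a hit to any
    screen motif on either strand.  Raises :class:`WindowRejectionError`
    after ``attempt_cap`` redraws for one window.
    """
    seq = wt.sequence
    L = len(seq)
    if width > L:
        raise DesignError("window width exceeds sequence length")
    screen = screen or []
    rng = np.random.default_rng(seed)
    out = []
    if include_wt:
        out.append(replace(wt, library="perturbation", category="WT",
                           template_id=wt.element_id))
    for rep in range(1, replicates + 1):
        for start in range(1, L - width + 2):
            for attempt in range(attempt_cap):
                window = "".join(
                    rng.choice([b for b in _BASES if b != seq[start - 1 + j]])
                    for j in range(width))
                mutant = seq[:start - 1] + window + seq[start - 1 + width:]
                ctx_lo = max(0, start - 1 - width)
                ctx_hi = min(L, start - 1 + 2 * width)
                context = mutant[ctx_lo:ctx_hi]
                if not screen or not scan_motifs(context, screen):
                    break
            else:
                raise WindowRejectionError(
                    f"{wt.element_id}: window start {start} rejected "
                    f"{attempt_cap} times by the motif screen")
            out.append(DesignElement(
                element_id=f"{wt.element_id}|win|{start}|r{rep}",
                library="perturbation", category="window",
                template_id=wt.element_id, sequence=mutant,
                window=(start, width, rep)))
    return out


# --------------------------------------------------------------------------
# motif scanning and scrambling
# --------------------------------------------------------------------------

def _iupac_regex(consensus: str) -> str:
    return "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in consensus)


def scan_motifs(sequence: str,
                motifs: list[TFMotif]) -> list[tuple[str, int, str]]:
    """All IUPAC-consensus matches on both strands.

    Returns (motif name, 1-based start on the forward strand, strand)
    sorted by position, then name, then strand.  Overlapping matches are
    all reported.
    """
    hits = []
    for motif in motifs:
        for pat, strand in ((motif.consensus, "+"),
                            (motif.reverse_complement(), "-")):
            regex = re.compile(f"(?=({_iupac_regex(pat)}))")
            for m in regex.finditer(sequence):
                hits.append((motif.name, m.start() + 1, strand))
    # palindromic consensus: identical +/- hits collapse to one record each
    hits = sorted(set((n, s, st) for n, s, st in hits),
                  key=lambda h: (h[1], h[0], h[2]))
    return hits


def scramble_sequence(sequence: str, seed: int | np.random.Generator = 0) -> str:
    """Uniform random permutation of the input bases (seeded)."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return "".join(rng.permutation(list(sequence)))


# --------------------------------------------------------------------------
# pilot library and grammar controls
# --------------------------------------------------------------------------

PILOT_CATEGORIES: dict[str, int] = {
    "random_genomic": 50,
    "scrambled": 100,
    "active_genomic": 100,
    "inactive_genomic": 50,
    "active_synthetic": 50,
    "inactive_synthetic": 50,
}
#: categories treated as negative controls / TMM anchors downstream
NEGATIVE_CONTROL_CATEGORY = "random_genomic"


def build_pilot_library(seed: int = 0,
                        counts: dict[str, int] | None = None,
                        sources: dict[str, list[str]] | None = None,
                        length: int = ELEMENT_LENGTH) -> list[DesignElement]:
    """Six-category pilot library (default 400 elements).

    Sequences may be supplied per category via ``sources``; otherwise they
    are seeded random sequences.  Scrambled elements are generated by
    permuting the active-genomic sequences, mirroring how scramble
    controls derive from active elements.
    """
    counts = dict(PILOT_CATEGORIES if counts is None else counts)
    rng = np.random.default_rng(seed)
    sources = sources or {}
    seqs: dict[str, list[str]] = {}
    for cat, n in counts.items():
        if cat == "scrambled":
            continue
        pool = sources.get(cat)
        if pool is not None:
            if len(pool) < n:
                raise DesignError(f"pilot category {cat}: {len(pool)} sources "
                                  f"for {n} elements")
            seqs[cat] = list(pool[:n])
        else:
            seqs[cat] = [random_sequence(length, rng) for _ in range(n)]
    if "scrambled" in counts:
        donors = sources.get("scrambled")
        if donors is None:
            donors = seqs.get("active_genomic") or \
                [random_sequence(length, rng) for _ in range(counts["scrambled"])]
        donors = list(itertools.islice(itertools.cycle(donors),
                                       counts["scrambled"]))
        seqs["scrambled"] = [scramble_sequence(s, rng) for s in donors]
    out = []
    for cat in counts:
        for i, s in enumerate(seqs[cat], start=1):
            out.append(DesignElement(
                element_id=f"pilot|{cat}|{i:03d}", library="pilot",
                category=cat, template_id="pilot", sequence=s))
    return out


def build_grammar_controls(seed: int = 1000, n_per_category: int = 50,
                           length: int = ELEMENT_LENGTH) -> list[DesignElement]:
    """200 control sequences carried in the grammar/perturbation libraries
    (random genomic, scrambled, active/inactive genomic; 50 each), used
    only for the TMM anchoring of activity scores."""
    rng = np.random.default_rng(seed)
    cats = ["random_genomic", "scrambled", "active_genomic", "inactive_genomic"]
    out = []
    for cat in cats:
        for i in range(1, n_per_category + 1):
            out.append(DesignElement(
                element_id=f"control|{cat}|{i:03d}", library="grammar",
                category=cat, template_id="control",
                sequence=random_sequence(length, rng)))
    return out


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

def write_design_fasta(elements: list[DesignElement], path: str | Path) -> None:
    records = [SeqRecord(Seq(e.sequence), id=e.element_id, description="")
               for e in elements]
    SeqIO.write(records, str(path), "fasta")


def _fmt_arrangement(arr) -> str:
    return ";".join(f"{n}:{c}:{s}" for n, c, s in arr)


def elements_to_frame(elements: list[DesignElement]) -> pd.DataFrame:
    rows = []
    for e in elements:
        rows.append({
            "element_id": e.element_id,
            "library": e.library,
            "category": e.category,
            "template_id": e.template_id,
            "sequence": e.sequence,
            "arrangement": _fmt_arrangement(e.arrangement),
            "variant": (f"{e.variant[0]}:{e.variant[1]}>{e.variant[2]}"
                        if e.variant else ""),
            "window": (f"{e.window[0]}:{e.window[1]}:{e.window[2]}"
                       if e.window else ""),
            "k": "" if e.k is None else e.k,
        })
    return pd.DataFrame(rows)


def frame_to_elements(df: pd.DataFrame) -> list[DesignElement]:
    out = []
    for row in df.itertuples(index=False):
        arr = ()
        if isinstance(row.arrangement, str) and row.arrangement:
            arr = tuple(tuple([p.split(":")[0], int(p.split(":")[1]),
                               int(p.split(":")[2])])
                        for p in row.arrangement.split(";"))
            arr = tuple((a, b, c) for a, b, c in arr)
        variant = None
        if isinstance(row.variant, str) and row.variant:
            pos, change = row.variant.split(":")
            ref, alt = change.split(">")
            variant = (int(pos), ref, alt)
        window = None
        if isinstance(row.window, str) and row.window:
            s, w, r = row.window.split(":")
            window = (int(s), int(w), int(r))
        k = None
        if row.k != "" and not pd.isna(row.k):
            k = int(row.k)
        out.append(DesignElement(
            element_id=row.element_id, library=row.library,
            category=str(row.category), template_id=row.template_id,
            sequence=row.sequence, arrangement=arr, variant=variant,
            window=window, k=k))
    return out


def write_manifest(elements: list[DesignElement], path: str | Path) -> None:
    elements_to_frame(elements).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[DesignElement]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"category": str, "k": str})
    return frame_to_elements(df)


def read_motifs_tsv(path: str | Path) -> list[TFMotif]:
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "consensus"],
                     comment="#")
    return [TFMotif(r.name, r.consensus)
            for r in df.itertuples(index=False)]


def write_motifs_tsv(motifs: list[TFMotif], path: str | Path) -> None:
    pd.DataFrame({"name": [m.name for m in motifs],
                  "consensus": [m.consensus for m in motifs]}
                 ).to_csv(path, sep="\t", index=False, header=False)
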