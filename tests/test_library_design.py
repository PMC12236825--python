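"""Library-design arithmetic, placement invariants and the motif screen."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import e2mpra as m
from e2mpra.library_design import (DesignError, PlacementError,
                                   WindowRejectionError, motif_counts,
                                   random_sequence)


class TestGrammarCounts:
    def test_class_sizes_match_design(self, grammar_spec):
        assert len(m.build_class1(grammar_spec)) == 54
        assert len(m.build_class2(grammar_spec)) == 288
        assert len(m.build_class3(grammar_spec)) == 6048

    @pytest.mark.parametrize("n_motifs,expected", [(8, 48), (1, 6), (9, 54)])
    def test_class1_count_formula(self, motifs9, templates, n_motifs,
                                  expected):
        spec = m.GrammarDesignSpec(motifs=motifs9[:n_motifs],
                                   templates=templates)
        assert len(m.build_class1(spec)) == expected

    def test_class1_single(self, motifs9, templates):
        spec = m.GrammarDesignSpec(motifs=motifs9[:1],
                                   templates=templates[:1],
                                   copy_numbers=(1,))
        els = m.build_class1(spec)
        assert len(els) == 1 and len(els[0].sequence) == 100

    def test_class2_pair_patterns(self, motifs9, templates):
        spec = m.GrammarDesignSpec(motifs=motifs9[:2],
                                   templates=templates[:1])
        els = m.build_class2(spec)
        assert len(els) == 4  # 1 pair x 4 patterns
        for e in els:
            assert sorted(motif_counts(e).values()) == [2, 2]
            assert e.k == 2
        one = m.GrammarDesignSpec(motifs=motifs9[:2], templates=templates[:1],
                                  class2_patterns=("ABAB",))
        assert len(m.build_class2(one)) == 1

    def test_class2_requires_two_motifs(self, motifs9, templates):
        spec = m.GrammarDesignSpec(motifs=motifs9[:1], templates=templates)
        with pytest.raises(DesignError):
            m.build_class2(spec)

    @pytest.mark.parametrize("n_motifs,n_templates,expected",
                             [(4, 1, 24), (8, 2, 3360)])
    def test_class3_counts(self, motifs9, templates, n_motifs, n_templates,
                           expected):
        spec = m.GrammarDesignSpec(motifs=motifs9[:n_motifs],
                                   templates=templates[:n_templates])
        assert len(m.build_class3(spec)) == expected

    def test_class3_orderings_exhaustive(self, motifs9, templates):
        # brute force: every 4-subset of 6 motifs contributes its 24
        # distinct orderings exactly once per template
        spec = m.GrammarDesignSpec(motifs=motifs9[:6],
                                   templates=templates[:1])
        seen = {tuple(n for n, _, _ in e.arrangement)
                for e in m.build_class3(spec)}
        names = sorted(mm.name for mm in motifs9[:6])
        expected = {p for sub in itertools.combinations(names, 4)
                    for p in itertools.permutations(sub)}
        assert seen == expected

    def test_class3_requires_four_motifs(self, motifs9, templates):
        spec = m.GrammarDesignSpec(motifs=motifs9[:3], templates=templates)
        with pytest.raises(DesignError):
            m.build_class3(spec)

    def test_placement_error_for_oversized_motif(self, templates):
        wide = m.TFMotif("WIDE", "A" * 30)
        spec = m.GrammarDesignSpec(motifs=[wide], templates=templates,
                                   copy_numbers=(4,))
        with pytest.raises(PlacementError, match="WIDE"):
            m.build_class1(spec)

    def test_arrangement_footprints_disjoint_and_inside(self, grammar_spec):
        by_name = {mm.name: mm for mm in grammar_spec.motifs}
        for e in m.build_class1(grammar_spec) + m.build_class2(grammar_spec):
            prev_end = 0
            for name, _, start in e.arrangement:
                end = start + by_name[name].length - 1
                assert 1 <= start and end <= 100
                assert start > prev_end
                prev_end = end
                # placed consensus actually present at the stated position
                placed = e.sequence[start - 1:end]
                for base, code in zip(placed, by_name[name].consensus):
                    assert base in m.library_design.IUPAC[code]


class TestPerturbationLibraries:
    def test_snv_count_and_hamming(self, snv_designs, wt_element):
        variants = [d for d in snv_designs if d.category == "snv"]
        assert len(variants) == 300
        assert len({d.sequence for d in variants}) == 300  # pairwise distinct

    def test_snv_exhaustive_small(self):
        wt = m.DesignElement("w", "perturbation", "WT", "w", "ACGTT")
        variants = [d for d in m.build_snv_library(wt) if d.category == "snv"]
        assert len(variants) == 15
        for d in variants:
            diff = [i for i, (a, b) in enumerate(zip(d.sequence, "ACGTT"))
                    if a != b]
            pos, ref, alt = d.variant
            assert diff == [pos - 1]
            assert d.sequence[pos - 1] == alt and "ACGTT"[pos - 1] == ref

    def test_snv_single_base(self):
        wt = m.DesignElement("w", "perturbation", "WT", "w", "A")
        alts = {d.variant[2] for d in m.build_snv_library(wt)
                if d.category == "snv"}
        assert alts == {"C", "G", "T"}

    def test_snv_rejects_ambiguous_wt(self):
        with pytest.raises(DesignError):
            m.DesignElement("w", "perturbation", "WT", "w", "ACGN")

    @pytest.mark.parametrize("replicates,expected", [(2, 190), (1, 95)])
    def test_window_counts(self, wt_element, replicates, expected):
        els = m.build_window_library(wt_element, replicates=replicates,
                                     seed=1)
        assert len(els) == expected

    def test_window_tiling_and_confinement(self, wt_element):
        els = m.build_window_library(wt_element, seed=2)
        starts = sorted({d.window[0] for d in els})
        assert starts == list(range(1, 96))  # tiles positions 1..95
        for d in els:
            s, w, _ = d.window
            diffs = [i + 1 for i, (a, b) in
                     enumerate(zip(d.sequence, wt_element.sequence))
                     if a != b]
            assert diffs == list(range(s, s + w))  # every window base mutated

    def test_window_trivial(self):
        wt = m.DesignElement("w", "perturbation", "WT", "w", "ACGTAC")
        els = m.build_window_library(wt, width=6, replicates=1, seed=0)
        assert len(els) == 1 and els[0].window == (1, 6, 1)

    def test_window_screen_rejection(self, wt_element):
        screen = [m.TFMotif("POLYA", "AAAA")]
        # a WT made screen-clean so the invariant is attainable
        wt = m.DesignElement("w", "perturbation", "WT", "w",
                             "ACGTCG" * 16 + "ACGT")
        els = m.build_window_library(wt, screen=screen, seed=3)
        for d in els:
            s, w, _ = d.window
            lo, hi = max(0, s - 1 - w), min(len(d.sequence), s - 1 + 2 * w)
            assert not m.scan_motifs(d.sequence[lo:hi], screen)

    def test_window_rejection_cap(self):
        # every redraw of an all-C window is an A/G/T string; screen on any
        # single base of the three alternatives makes some windows
        # impossible only with a huge motif, so force it with N
        wt = m.DesignElement("w", "perturbation", "WT", "w", "CCCCCC")
        screen = [m.TFMotif("ANY", "NNN")]
        with pytest.raises(WindowRejectionError):
            m.build_window_library(wt, replicates=1, seed=0, screen=screen,
                                   attempt_cap=20)

    def test_window_reproducible(self, wt_element):
        a = m.build_window_library(wt_element, seed=9)
        b = m.build_window_library(wt_element, seed=9)
        assert [d.sequence for d in a] == [d.sequence for d in b]


class TestMotifScan:
    def test_literal_hit(self):
        motif = m.TFMotif("X", "GGATCC")
        hits = m.scan_motifs("AAAGGATCCAAA", [motif])
        assert ("X", 4, "+") in hits

    def test_no_hit(self):
        assert m.scan_motifs("A" * 50, [m.TFMotif("GC", "GGCC")]) == []

    def test_iupac_expansion_brute_force(self):
        # oracle: expand TGASTCA into its two literal sequences and search
        consensus = "TGASTCA"
        seq = "CCTGAGTCACC"
        literal = ["TGA" + s + "TCA" for s in "CG"]
        expected_fwd = sorted(i + 1 for lit in literal
                              for i in range(len(seq) - 6)
                              if seq[i:i + 7] == lit)
        hits = m.scan_motifs(seq, [m.TFMotif("AP1", consensus)])
        fwd = [h[1] for h in hits if h[2] == "+"]
        assert fwd == expected_fwd == [3]

    def test_reverse_strand(self):
        motif = m.TFMotif("X", "GGGTTT")  # revcomp AAACCC
        hits = m.scan_motifs("TTAAACCCTT", [motif])
        assert hits == [("X", 3, "-")]

    def test_deterministic_order(self):
        motifs = [m.TFMotif("B", "ACGT"), m.TFMotif("A", "ACGT")]
        hits = m.scan_motifs("ACGTACGT", motifs)
        assert hits == sorted(hits, key=lambda h: (h[1], h[0], h[2]))


class TestScramble:
    @settings(max_examples=25, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60),
           st.integers(0, 10_000))
    def test_composition_preserved(self, seq, seed):
        out = m.scramble_sequence(seq, seed)
        assert sorted(out) == sorted(seq)

    def test_seeded_reproducibility(self):
        seq = random_sequence(100, np.random.default_rng(0))
        assert m.scramble_sequence(seq, 7) == m.scramble_sequence(seq, 7)

    def test_usually_differs_from_input(self):
        seq = random_sequence(100, np.random.default_rng(1))
        changed = sum(m.scramble_sequence(seq, s) != seq for s in range(100))
        assert changed == 100


class TestPilotAndIO:
    def test_pilot_composition(self):
        els = m.build_pilot_library(seed=0)
        assert len(els) == 400
        from collections import Counter
        counts = Counter(e.category for e in els)
        assert counts == m.library_design.PILOT_CATEGORIES

    def test_manifest_round_trip(self, small_designs, wt_element, tmp_path):
        els = list(small_designs[:30]) + m.build_snv_library(wt_element)[:5] \
            + m.build_window_library(wt_element, replicates=1, seed=0)[:5]
        path = tmp_path / "manifest.tsv"
        m.library_design.write_manifest(els, path)
        back = m.library_design.read_manifest(path)
        assert back == els

    def test_fasta_and_motif_tsv(self, motifs9, tmp_path):
        m.library_design.write_motifs_tsv(motifs9, tmp_path / "m.tsv")
        back = m.library_design.read_motifs_tsv(tmp_path / "m.tsv")
        assert back == motifs9
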