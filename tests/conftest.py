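import numpy as np
import pytest

import e2mpra as m


@pytest.fixture(scope="session")
def motifs9():
    return m.default_motifs()


@pytest.fixture(scope="session")
def templates():
    return m.neutral_templates(seed=0)


@pytest.fixture(scope="session")
def grammar_spec(motifs9, templates):
    return m.GrammarDesignSpec(motifs=motifs9, templates=templates)


@pytest.fixture(scope="session")
def small_spec(motifs9, templates):
    """Four-motif spec for cheap end-to-end simulations."""
    return m.GrammarDesignSpec(motifs=motifs9[:4], templates=templates)


@pytest.fixture(scope="session")
def small_designs(small_spec):
    return (m.build_class1(small_spec) + m.build_class2(small_spec)
            + m.build_grammar_controls(seed=5, n_per_category=20))


@pytest.fixture(scope="session")
def control_ids(small_designs):
    return {d.element_id for d in small_designs
            if d.category == "random_genomic"}


@pytest.fixture(scope="session")
def wt_element():
    seq = m.library_design.random_sequence(100, np.random.default_rng(3))
    return m.DesignElement("cre1", "perturbation", "WT", "cre1", seq)


@pytest.fixture(scope="session")
def snv_designs(wt_element):
    return m.build_snv_library(wt_element)
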