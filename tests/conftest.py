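import numpy as np
import pytest

from plnet import AnnotationSet, Ontology


@pytest.fixture
def chain_ontology():
    """c is_a b is_a a."""
    return Ontology.from_term_parents({"a": [], "b": ["a"], "c": ["b"]})


@pytest.fixture
def diamond_ontology():
    """d below b and c, both below root a."""
    return Ontology.from_term_parents({"a": [], "b": ["a"], "c": ["a"], "d": ["b", "c"]})


@pytest.fixture
def double_diamond():
    """t1 and t2 each below the two unordered mid terms b and c."""
    return Ontology.from_term_parents(
        {"a": [], "b": ["a"], "c": ["a"], "t1": ["b", "c"], "t2": ["b", "c"]}
    )


@pytest.fixture
def toy_world():
    """Small ontology + annotations with a computable IC spectrum.

    8 annotated genes; term x annotates exactly one gene, so
    IC(x) = -log(1/8).
    """
    ont = Ontology.from_term_parents(
        {
            "root": [],
            "mid1": ["root"],
            "mid2": ["root"],
            "x": ["mid1"],
            "y": ["mid1", "mid2"],
            "z": ["mid2"],
        }
    )
    direct = {
        "g1": {"x"},
        "g2": {"y"},
        "g3": {"y", "z"},
        "g4": {"z"},
        "g5": {"mid1"},
        "g6": {"mid2"},
        "g7": {"z"},
        "g8": {"y"},
    }
    ann = AnnotationSet(direct, source="toy", ontology=ont)
    return ont, ann


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
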