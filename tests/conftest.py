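import pytest

from archsem.synthetic_data import SynthConfig, generate_annotations, generate_corpus


@pytest.fixture(scope="session")
def synth():
    """A small synthetic corpus with planted synonym groups (fidelity 1)."""
    cfg = SynthConfig(
        n_architectures=500,
        n_domains=150,
        n_synonym_groups=10,
        n_terms=80,
        seed=11,
    )
    corpus, truth = generate_corpus(cfg)
    annotations, graph = generate_annotations(corpus, truth, cfg)
    return cfg, corpus, truth, annotations, graph


@pytest.fixture()
def toy_obo(tmp_path):
    """A five-term MF ontology with an is_a chain, part_of, and noise edges."""
    text = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: mid
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf
namespace: molecular_function
relationship: part_of GO:0000002

[Term]
id: GO:0000004
name: regulator
namespace: molecular_function
relationship: regulates GO:0000002
is_a: GO:0000001

[Term]
id: GO:0000005
name: gone
namespace: molecular_function
is_obsolete: true
"""
    path = tmp_path / "toy.obo"
    path.write_text(text)
    return path
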