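import pytest

from pseudocasp import generate_caspase16_like_locus, inject_lesions
from pseudocasp.gene_models import extract_cds
from pseudocasp.synthetic_data import GeneratorParams


@pytest.fixture(scope="session")
def default_locus():
    """One generated locus at default conditions (40% copy divergence)."""
    return generate_caspase16_like_locus(1)


@pytest.fixture(scope="session")
def exact_copy_locus():
    """Locus with an exact (divergence-0) duplicated domain."""
    return generate_caspase16_like_locus(1, GeneratorParams(duplicate_divergence=0.0))


@pytest.fixture(scope="session")
def casp16p_scenario(default_locus):
    """The canonical frameshift scenario plus the intact ortholog inputs."""
    seq, model, manifest = default_locus
    ortholog_cds, _, _ = extract_cds(model, seq)
    lesioned_seq, lesioned_model, lesioned_manifest = inject_lesions(
        seq, model, manifest, "human-casp16p"
    )
    return {
        "seq": lesioned_seq,
        "model": lesioned_model,
        "manifest": lesioned_manifest,
        "ortholog_cds": ortholog_cds,
        "ortholog_protein": manifest.derived_protein,
        "intact_seq": seq,
        "intact_model": model,
    }
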