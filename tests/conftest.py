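import numpy as np
import pytest

from chargeseq import (
    ChargeProfile,
    TrnaGene,
    build_reference,
    synthetic_index,
)


def _random_trna(rng: np.random.Generator, anticodon: str, length: int = 72) -> str:
    body = list("".join("ACGT"[i] for i in rng.integers(0, 4, size=length)))
    body[34:37] = list(anticodon)
    return "".join(body)


@pytest.fixture(scope="session")
def six_genes():
    """Six genes over four anticodons; two share an identical sequence."""
    rng = np.random.default_rng(11)
    gln_ctg = _random_trna(rng, "CTG")
    gln_ttg = _random_trna(rng, "TTG")
    val_aac = _random_trna(rng, "AAC", 76)
    imet_cat = _random_trna(rng, "CAT", 74)
    genes = [
        TrnaGene("mm-Gln-CTG-1-1", "Gln", "CTG", gln_ctg),
        TrnaGene("mm-Gln-CTG-2-1", "Gln", "CTG", gln_ctg),  # identical copy
        TrnaGene(
            "mm-Gln-CTG-3-1", "Gln", "CTG",
            gln_ctg[:10] + ("A" if gln_ctg[10] != "A" else "C") + gln_ctg[11:],
        ),
        TrnaGene("mm-Gln-TTG-1-1", "Gln", "TTG", gln_ttg),
        TrnaGene("mm-Val-AAC-1-1", "Val", "AAC", val_aac),
        TrnaGene("mm-iMet-CAT-1-1", "iMet", "CAT", imet_cat),
    ]
    spike = TrnaGene(
        "yeast-Phe-GAA-1-1", "Phe", "GAA", _random_trna(rng, "GAA", 76),
        is_spike_in=True,
    )
    return genes, spike


@pytest.fixture(scope="session")
def six_gene_index(six_genes):
    genes, spike = six_genes
    return build_reference(genes, spike)


@pytest.fixture(scope="session")
def sim_index():
    """Well-separated 20-isodecoder synthetic reference for simulation tests."""
    return synthetic_index(seed=0)


@pytest.fixture(scope="session")
def small_index():
    return synthetic_index(n_isodecoders=6, seed=3)


@pytest.fixture
def uniform_profile():
    def make(index, fraction=0.8):
        keys = sorted(index.isodecoders)
        return ChargeProfile.from_dicts(
            {k: fraction for k in keys}, {k: 1.0 for k in keys}
        )

    return make
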