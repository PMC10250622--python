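import numpy as np
import pytest

from helixcpi.corpus import InteractionRecord, ReceptorRecord, Region
from helixcpi.encoder import EncoderConfig
from helixcpi.synthetic import GeneratorConfig, generate


def make_receptor(accession="R1", tm_len=12, loop_len=6, n_term=5, c_term=5,
                  rng=None, subfamily=None):
    """A valid 7-TM receptor with ECL1/2/3 between TM2-3, TM4-5, TM6-7."""
    rng = rng or np.random.default_rng(0)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    def seq(n):
        return "".join(rng.choice(aas, size=n))
    parts = [(None, seq(n_term))]
    for tm in range(1, 8):
        parts.append((f"TM{tm}", seq(tm_len)))
        if tm in (2, 4, 6):
            parts.append((f"ECL{tm // 2}", seq(loop_len)))
    parts.append((None, seq(c_term)))
    sequence = "".join(s for _, s in parts)
    regions, pos = [], 0
    for name, s in parts:
        if name:
            regions.append(Region(name, pos + 1, pos + len(s)))
        pos += len(s)
    return ReceptorRecord(accession, sequence, tuple(regions), subfamily)


def rec(acc, smi, molar, atype="IC50"):
    from helixcpi.corpus import label_interaction
    return InteractionRecord(acc, smi, atype, molar, label_interaction(molar))


@pytest.fixture(scope="session")
def small_config():
    """Reduced-width architecture for fast training-behaviour tests."""
    return EncoderConfig(embed_dim=24, d_model=16, heads=4, ff_width=32,
                         gnn_rounds=2, decoder_layers=2)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate(GeneratorConfig(n_proteins=12, n_compounds=24,
                                    n_pairs=240, seed=7))
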