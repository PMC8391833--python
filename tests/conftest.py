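import numpy as np
import pytest

from unipargen import load_default_motifs, load_reference
from unipargen.io import StrHaplotype, StrPanel


@pytest.fixture(scope="session")
def reference() -> str:
    return load_reference()


@pytest.fixture(scope="session")
def motif_panel(reference):
    return load_default_motifs(reference)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210820)


def make_haplotypes(allele_rows, panel=None, ids=None, metas=None):
    """Build StrHaplotype objects from a list of allele tuples."""
    panel = panel or StrPanel(tuple(f"L{i}" for i in range(len(allele_rows[0]))))
    out = []
    for i, row in enumerate(allele_rows):
        out.append(
            StrHaplotype(
                sample_id=ids[i] if ids else f"s{i}",
                alleles=tuple(int(a) for a in row),
                panel=panel,
                meta=metas[i] if metas else None,
            )
        )
    return out
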