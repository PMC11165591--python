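import numpy as np
import pytest

from fragbench.chem import RESIDUE_MASSES, Peptide


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_peptide(rng, min_len=7, max_len=20, with_mods=True) -> Peptide:
    letters = sorted(RESIDUE_MASSES)
    n = int(rng.integers(min_len, max_len + 1))
    seq = "".join(letters[i] for i in rng.integers(0, len(letters), size=n))
    mods = []
    for pos, aa in enumerate(seq, start=1):
        if aa == "C":
            mods.append((pos, "Carbamidomethyl"))
        elif with_mods and aa == "M" and rng.random() < 0.5:
            mods.append((pos, "Oxidation"))
    return Peptide(seq, tuple(mods))


@pytest.fixture
def toy_mgf(tmp_path):
    path = tmp_path / "toy.mgf"
    path.write_text(
        "BEGIN IONS\n"
        "TITLE=toy scan=1\n"
        "SCANS=1\n"
        "PEPMASS=500.25\n"
        "100.1000 10.0\n"
        "200.2000 20.0\n"
        "300.3000 5.5\n"
        "END IONS\n"
        "BEGIN IONS\n"
        "TITLE=toy scan=2\n"
        "SCANS=2\n"
        "150.5000 1.0\n"
        "END IONS\n"
    )
    return path
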