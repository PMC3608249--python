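import numpy as np
import pytest

from famewas.pedigree import Individual, Pedigree, kinship_matrix


@pytest.fixture
def trio():
    return Pedigree(
        [
            Individual("dad", "fam1", None, None, "male"),
            Individual("mom", "fam1", None, None, "female"),
            Individual("kid", "fam1", "dad", "mom", "female"),
        ]
    )


@pytest.fixture
def nuclear_family():
    """Two parents, three children."""
    inds = [
        Individual("f", "fam1", None, None, "male"),
        Individual("m", "fam1", None, None, "female"),
    ]
    for k in range(3):
        inds.append(Individual(f"c{k}", "fam1", "f", "m", "male" if k % 2 else "female"))
    return Pedigree(inds)


@pytest.fixture
def cousin_pedigree():
    """Three generations producing a full-first-cousin pair (c1, c2)."""
    return Pedigree(
        [
            Individual("gp", "fam1", None, None, "male"),
            Individual("gm", "fam1", None, None, "female"),
            Individual("p1", "fam1", "gp", "gm", "male"),
            Individual("p2", "fam1", "gp", "gm", "female"),
            Individual("s1", "fam1", None, None, "female"),
            Individual("s2", "fam1", None, None, "male"),
            Individual("c1", "fam1", "p1", "s1", "male"),
            Individual("c2", "fam1", "s2", "p2", "female"),
        ]
    )


@pytest.fixture
def small_multi_family():
    """Four independent nuclear families (n=20) for fast model fits."""
    inds = []
    for f in range(4):
        fam = f"fam{f}"
        inds.append(Individual(f"{fam}_f", fam, None, None, "male"))
        inds.append(Individual(f"{fam}_m", fam, None, None, "female"))
        for k in range(3):
            inds.append(
                Individual(
                    f"{fam}_c{k}", fam, f"{fam}_f", f"{fam}_m",
                    "female" if k % 2 else "male",
                )
            )
    return Pedigree(inds)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
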