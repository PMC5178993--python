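import numpy as np
import pytest

from metapheno.data_io import (
    GenotypeMatrix,
    Marker,
    PedigreeRecord,
    PedigreeTable,
    PhenotypeMatrix,
)


def make_pedigree(rows):
    """rows: (family, individual, father|None, mother|None, sex)."""
    return PedigreeTable([PedigreeRecord(*r) for r in rows])


@pytest.fixture
def trio():
    return make_pedigree(
        [
            ("F1", "dad", None, None, 1),
            ("F1", "mom", None, None, 2),
            ("F1", "kid", "dad", "mom", 1),
        ]
    )


@pytest.fixture
def sib_pedigree():
    return make_pedigree(
        [
            ("F1", "dad", None, None, 1),
            ("F1", "mom", None, None, 2),
            ("F1", "s1", "dad", "mom", 1),
            ("F1", "s2", "dad", "mom", 2),
        ]
    )


@pytest.fixture
def half_sib_pedigree():
    return make_pedigree(
        [
            ("F1", "dad", None, None, 1),
            ("F1", "mom1", None, None, 2),
            ("F1", "mom2", None, None, 2),
            ("F1", "h1", "dad", "mom1", 1),
            ("F1", "h2", "dad", "mom2", 2),
        ]
    )


@pytest.fixture
def cousin_pedigree():
    # two sibs marry unrelated spouses; their children are first cousins
    return make_pedigree(
        [
            ("F1", "gpa", None, None, 1),
            ("F1", "gma", None, None, 2),
            ("F1", "p1", "gpa", "gma", 1),
            ("F1", "p2", "gpa", "gma", 2),
            ("F1", "sp1", None, None, 2),
            ("F1", "sp2", None, None, 1),
            ("F1", "c1", "p1", "sp1", 1),
            ("F1", "c2", "sp2", "p2", 2),
        ]
    )


@pytest.fixture
def inbred_pedigree():
    # full-sib mating: child of sibs is inbred (F = 0.25)
    return make_pedigree(
        [
            ("F1", "dad", None, None, 1),
            ("F1", "mom", None, None, 2),
            ("F1", "s1", "dad", "mom", 1),
            ("F1", "s2", "dad", "mom", 2),
            ("F1", "inb", "s1", "s2", 1),
        ]
    )


@pytest.fixture
def cousin_mating_pedigree():
    # first-cousin mating: offspring inbreeding coefficient 1/16
    return make_pedigree(
        [
            ("F1", "gpa", None, None, 1),
            ("F1", "gma", None, None, 2),
            ("F1", "p1", "gpa", "gma", 1),
            ("F1", "p2", "gpa", "gma", 2),
            ("F1", "sp1", None, None, 2),
            ("F1", "sp2", None, None, 1),
            ("F1", "c1", "p1", "sp1", 1),
            ("F1", "c2", "sp2", "p2", 2),
            ("F1", "cc", "c1", "c2", 2),
        ]
    )


def geno(values, ids=None, chrom="1"):
    """Build a GenotypeMatrix from a plain array (nan = missing)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = ids or [f"i{i + 1}" for i in range(n)]
    markers = [
        Marker(f"snp{j + 1}", chrom, 1000 * (j + 1), "A", "G") for j in range(p)
    ]
    return GenotypeMatrix(values, ids, markers)


def pheno(values, trait_names=None, ids=None, **kw):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return PhenotypeMatrix(
        values=values,
        trait_names=trait_names or [f"t{j + 1}" for j in range(m)],
        individual_ids=ids or [f"i{i + 1}" for i in range(n)],
        **kw,
    )
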