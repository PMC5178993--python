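"""Generator of family-study-shaped fixtures.

Builds extended pedigrees (founder couples with Poisson offspring,
new-founder spouses), drops Mendelian genotypes through them, and
produces trait matrices as linear mixtures of latent sources: polygenic
(kinship-structured), SNP-driven (pleiotropic), and non-Gaussian
environmental sources, plus covariate effects and MCAR missingness.
Every generated object carries the ground truth needed for
parameter-recovery tests.

Default demographic knobs mimic an extended-family design of ~21
families with mean size 19: ages uniform on [1, 88], male fraction
0.85 / 1.85.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    GenotypeMatrix,
    Marker,
    PedigreeRecord,
    PedigreeTable,
    PhenotypeMatrix,
)
from .errors import ValidationError
from .kinship import kinship_matrix

_MALE_FRACTION = 0.85 / 1.85  # male:female ratio 0.85

SOURCE_TYPES = ("polygenic", "snp_driven", "laplace", "uniform", "gaussian")


@dataclass
class SimulationTruth:
    """Ground truth of one phenotype simulation."""

    mixing_matrix: np.ndarray  # q x m
    source_types: list[str]
    h2_per_source: list[float] = field(default_factory=list)
    causal_snp_ids: list[str | None] = field(default_factory=list)
    snp_variance_per_source: list[float] = field(default_factory=list)
    covariate_effects: np.ndarray | None = None  # 2 x m (age, sex rows)
    noise_sd: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=float)
        if not np.isfinite(self.mixing_matrix).all():
            raise ValidationError("mixing matrix must be finite")
        q = self.mixing_matrix.shape[0]
        if len(self.source_types) != q:
            raise ValidationError("source_types length must match mixing rows")
        for t in self.source_types:
            if t not in SOURCE_TYPES:
                raise ValidationError(f"unknown source type {t!r}")
        if not self.h2_per_source:
            self.h2_per_source = [0.0] * q
        if not self.causal_snp_ids:
            self.causal_snp_ids = [None] * q
        if not self.snp_variance_per_source:
            self.snp_variance_per_source = [0.0] * q
        for h in self.h2_per_source:
            if not 0.0 <= h <= 1.0:
                raise ValidationError("h2 must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")


def simulate_pedigrees(
    n_families: int,
    mean_size: int,
    n_generations: int = 3,
    seed: int = 0,
) -> PedigreeTable:
    """Random extended pedigrees.

    Each family starts from a founder couple; every non-terminal
    individual marries a new founder and has a Poisson number of
    children, with the rate calibrated so the expected family size is
    about ``mean_size``.
    """
    if n_families < 1:
        raise ValidationError("n_families must be >= 1")
    if n_generations not in (2, 3, 4):
        raise ValidationError("n_generations must be 2, 3 or 4")
    if mean_size < n_generations:
        raise ValidationError("mean_size smaller than the generation count")
    lam = _calibrate_offspring_rate(mean_size, n_generations)
    rng = np.random.default_rng(seed)
    records: list[PedigreeRecord] = []
    for fam in range(1, n_families + 1):
        fid = f"F{fam:02d}"
        counter = [0]

        def new_id() -> str:
            counter[0] += 1
            return f"{fid}-I{counter[0]:03d}"

        def child_sex() -> int:
            return 1 if rng.random() < _MALE_FRACTION else 2

        father, mother = new_id(), new_id()
        records.append(PedigreeRecord(fid, father, None, None, 1))
        records.append(PedigreeRecord(fid, mother, None, None, 2))
        current = [(father, mother)]
        for gen in range(1, n_generations):
            next_couples: list[tuple[str, str]] = []
            for f_id, m_id in current:
                n_children = rng.poisson(lam)
                if gen == 1:
                    n_children = max(n_children, 1)  # never a childless family
                for _ in range(n_children):
                    cid = new_id()
                    sex = child_sex()
                    records.append(PedigreeRecord(fid, cid, f_id, m_id, sex))
                    if gen < n_generations - 1:
                        sid = new_id()
                        spouse_sex = 2 if sex == 1 else 1
                        records.append(
                            PedigreeRecord(fid, sid, None, None, spouse_sex)
                        )
                        couple = (cid, sid) if sex == 1 else (sid, cid)
                        next_couples.append(couple)
            current = next_couples
    return PedigreeTable(records)


def _calibrate_offspring_rate(mean_size: int, n_generations: int) -> float:
    """Solve for the Poisson rate giving expected family size mean_size."""
    def expected(lam: float) -> float:
        total = 2.0
        couples = 1.0
        for gen in range(1, n_generations):
            children = couples * lam
            total += children
            if gen < n_generations - 1:
                total += children  # spouses
                couples = children
        return total

    lo, hi = 1e-3, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < mean_size:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def drop_genotypes(
    ped: PedigreeTable,
    n_snps: int,
    mafs: np.ndarray | float,
    seed: int = 0,
    missing_rate: float = 0.0,
    chromosome: str = "1",
) -> GenotypeMatrix:
    """Mendelian gene dropping of biallelic SNPs through a pedigree.

    Founder allele copies are Bernoulli(maf); each child receives one
    uniformly chosen allele from each parent.  SNPs are labelled
    snp0001.. and placed 10 kb apart on one chromosome.
    """
    mafs = np.broadcast_to(np.asarray(mafs, dtype=float), (n_snps,))
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValidationError("mafs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    n = len(ped.records)
    by_id = {r.individual_id: i for i, r in enumerate(ped.records)}
    order = ped.topological_order()
    # allele copies: (n, n_snps, 2) of {0 minor absent, 1 minor present}
    al = np.zeros((n, n_snps, 2), dtype=np.int8)
    for i in order:
        r = ped.records[i]
        if r.father_id is None:
            al[i, :, 0] = rng.random(n_snps) < mafs
            al[i, :, 1] = rng.random(n_snps) < mafs
        else:
            f, m = by_id[r.father_id], by_id[r.mother_id]
            pick_f = rng.integers(0, 2, size=n_snps)
            pick_m = rng.integers(0, 2, size=n_snps)
            al[i, :, 0] = al[f, np.arange(n_snps), pick_f]
            al[i, :, 1] = al[m, np.arange(n_snps), pick_m]
    values = al.sum(axis=2).astype(float)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan
    markers = [
        Marker(f"snp{j + 1:04d}", chromosome, 10_000 * (j + 1), "A", "G")
        for j in range(n_snps)
    ]
    return GenotypeMatrix(values, ped.individual_ids, markers)


def _standardize_unit(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValidationError("cannot standardize a constant source")
    return (x - x.mean()) / sd


def simulate_phenotypes(
    ped: PedigreeTable,
    G: GenotypeMatrix | None,
    truth: SimulationTruth,
) -> tuple[PhenotypeMatrix, np.ndarray]:
    """Trait matrix as a linear mixture of latent sources.

    Sources are built per ``truth.source_types`` (all unit variance):

    * ``polygenic`` — breeding values with covariance h2 * 2Phi plus an
      independent residual with variance 1 - h2, drawn per family block;
    * ``snp_driven`` — sqrt(v) * standardized genotype + sqrt(1-v) noise;
    * ``laplace`` / ``uniform`` / ``gaussian`` — i.i.d. draws.

    X = S @ A + measurement noise, then covariate (age, sex) effects.
    Returns the phenotype matrix (with covariates attached) and S.
    """
    rng = np.random.default_rng(truth.seed)
    A = truth.mixing_matrix
    q, m = A.shape
    n = len(ped.records)
    S = np.zeros((n, q))
    chol_cache: np.ndarray | None = None
    for s_idx, stype in enumerate(truth.source_types):
        if stype == "polygenic":
            h2 = truth.h2_per_source[s_idx]
            if chol_cache is None:
                K2 = kinship_matrix(ped).additive
                # small jitter: pedigrees with duplicated founder roles can
                # make 2*Phi numerically semidefinite
                chol_cache = np.linalg.cholesky(K2 + 1e-9 * np.eye(n))
            bv = chol_cache @ rng.standard_normal(n)
            src = np.sqrt(h2) * bv + np.sqrt(1.0 - h2) * rng.standard_normal(n)
        elif stype == "snp_driven":
            if G is None:
                raise ValidationError("snp_driven source requires genotypes")
            snp_id = truth.causal_snp_ids[s_idx]
            if snp_id not in G.snp_ids:
                raise ValidationError(f"causal SNP {snp_id!r} not in genotypes")
            g = G.values[:, G.snp_ids.index(snp_id)]
            if np.isnan(g).any():
                raise ValidationError("causal SNP column must be complete")
            v = truth.snp_variance_per_source[s_idx]
            src = np.sqrt(v) * _standardize_unit(g) + np.sqrt(1.0 - v) * (
                rng.standard_normal(n)
            )
        elif stype == "laplace":
            src = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=n)
        elif stype == "uniform":
            src = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n)
        else:  # gaussian
            src = rng.standard_normal(n)
        S[:, s_idx] = src
    X = S @ A + truth.noise_sd * rng.standard_normal((n, m))

    age = rng.uniform(1.0, 88.0, size=n)
    sex = np.array([1.0 if r.sex == 1 else 0.0 for r in ped.records])
    if truth.covariate_effects is not None:
        ce = np.asarray(truth.covariate_effects, dtype=float)
        if ce.shape != (2, m):
            raise ValidationError("covariate_effects must be 2 x m (age, sex)")
        X = X + np.outer(age, ce[0]) + np.outer(sex, ce[1])

    pheno = PhenotypeMatrix(
        values=X,
        trait_names=[f"T{j + 1:02d}" for j in range(m)],
        individual_ids=ped.individual_ids,
        covariates=np.column_stack([age, sex]),
        covariate_names=["age", "sex"],
        family_ids=[r.family_id for r in ped.records],
    )
    return pheno, S


def inject_missing(
    X: PhenotypeMatrix, rate: float, seed: int = 0
) -> PhenotypeMatrix:
    """MCAR deletion at the given rate, guaranteeing at least one
    observed cell in every row and column."""
    if not 0.0 <= rate <= 0.5:
        raise ValidationError("rate must lie in [0, 0.5]")
    vals = np.asarray(X.values, dtype=float).copy()
    n, m = vals.shape
    if rate == 0.0:
        return X
    rng = np.random.default_rng(seed)
    mask = rng.random((n, m)) < rate
    # repair rows/columns that would become fully missing
    for i in np.flatnonzero(mask.all(axis=1)):
        mask[i, rng.integers(0, m)] = False
    for j in np.flatnonzero(mask.all(axis=0)):
        mask[rng.integers(0, n), j] = False
    if mask.all(axis=1).any() or mask.all(axis=0).any():
        raise ValidationError("missing rate leaves an empty row or column")
    vals[mask] = np.nan
    return PhenotypeMatrix(
        values=vals,
        trait_names=list(X.trait_names),
        individual_ids=list(X.individual_ids),
        covariates=X.covariates.copy(),
        covariate_names=list(X.covariate_names),
        family_ids=list(X.family_ids) if X.family_ids is not None else None,
    )


def default_truth(
    m: int = 8,
    seed: int = 0,
    causal_snp_id: str | None = None,
    snp_variance: float = 0.5,
    h2: float = 0.5,
    missing_rate: float = 0.05,
) -> SimulationTruth:
    """A convenient three-source truth: one polygenic, one SNP-driven
    (if a causal SNP is given), one Laplace environmental source."""
    rng = np.random.default_rng(seed)
    types = ["polygenic", "laplace"]
    if causal_snp_id is not None:
        types.insert(1, "snp_driven")
    q = len(types)
    A = rng.normal(0.0, 1.0, size=(q, m))
    return SimulationTruth(
        mixing_matrix=A,
        source_types=types,
        h2_per_source=[h2 if t == "polygenic" else 0.0 for t in types],
        causal_snp_ids=[causal_snp_id if t == "snp_driven" else None for t in types],
        snp_variance_per_source=[
            snp_variance if t == "snp_driven" else 0.0 for t in types
        ],
        covariate_effects=None,
        noise_sd=0.1,
        missing_rate=missing_rate,
        seed=seed,
    )
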