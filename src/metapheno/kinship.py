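"""Pedigree kinship coefficients and a Monte-Carlo gene-dropping oracle.

The recursive (tabular) method yields the kinship matrix Phi; the mixed
model downstream uses the additive relationship matrix 2*Phi.  Gene
dropping simulates Mendelian transmission of founder alleles and
estimates the same coefficients empirically, serving as an independent
oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import PedigreeTable
from .errors import ValidationError


@dataclass
class KinshipMatrix:
    """Kinship coefficient matrix aligned with a pedigree's individuals."""

    values: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValidationError("kinship matrix shape does not match ids")

    @property
    def additive(self) -> np.ndarray:
        """The numerator relationship matrix 2*Phi."""
        return 2.0 * self.values

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise ValidationError(f"ids not in kinship matrix: {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(ids))


def kinship_matrix(ped: PedigreeTable) -> KinshipMatrix:
    """Recursive kinship computation.

    Founders: Phi_ii = 0.5 and Phi between distinct founders = 0.
    Non-founder i with parents f, m: Phi_ij = 0.5 * (Phi_fj + Phi_mj)
    for previously processed j, and Phi_ii = 0.5 * (1 + Phi_fm).
    Inbreeding falls out of the recursion (diagonal may exceed 0.5).
    """
    ped.validate()
    order = ped.topological_order()
    n = len(ped.records)
    by_id = {r.individual_id: i for i, r in enumerate(ped.records)}
    phi = np.zeros((n, n))
    processed: list[int] = []
    for i in order:
        r = ped.records[i]
        if r.father_id is None:
            phi[i, i] = 0.5
        else:
            f, m = by_id[r.father_id], by_id[r.mother_id]
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            for j in processed:
                v = 0.5 * (phi[f, j] + phi[m, j])
                phi[i, j] = phi[j, i] = v
        processed.append(i)
    return KinshipMatrix(phi, ped.individual_ids)


def gene_drop_kinship(
    ped: PedigreeTable, n_replicates: int, seed: int
) -> np.ndarray:
    """Monte-Carlo kinship estimate by gene dropping.

    Each founder receives two globally unique allele labels; alleles are
    transmitted Mendelianly.  Entry (i, j) is the fraction, over
    replicates and the four allele pairings, of identical-by-descent
    pairs — the empirical kinship coefficient.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    ped.validate()
    rng = np.random.default_rng(seed)
    n = len(ped.records)
    by_id = {r.individual_id: i for i, r in enumerate(ped.records)}
    order = ped.topological_order()

    # alleles[r, i, c]: allele label of chromosome copy c in individual i, rep r
    alleles = np.zeros((n_replicates, n, 2), dtype=np.int32)
    next_label = 0
    reps = np.arange(n_replicates)
    for i in order:
        r = ped.records[i]
        if r.father_id is None:
            alleles[:, i, 0] = next_label
            alleles[:, i, 1] = next_label + 1
            next_label += 2
        else:
            f, m = by_id[r.father_id], by_id[r.mother_id]
            pick_f = rng.integers(0, 2, size=n_replicates)
            pick_m = rng.integers(0, 2, size=n_replicates)
            alleles[:, i, 0] = alleles[reps, f, pick_f]
            alleles[:, i, 1] = alleles[reps, m, pick_m]

    est = np.zeros((n, n))
    for i in range(n):
        ai0, ai1 = alleles[:, i, 0], alleles[:, i, 1]
        for j in range(i, n):
            aj0, aj1 = alleles[:, j, 0], alleles[:, j, 1]
            share = (
                (ai0 == aj0).mean()
                + (ai0 == aj1).mean()
                + (ai1 == aj0).mean()
                + (ai1 == aj1).mean()
            ) / 4.0
            est[i, j] = est[j, i] = share
    return est
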