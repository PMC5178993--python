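"""Readers and writers for the external text formats.

This is the only module that touches files. Supported dialects:

* PLINK text genotypes (``.ped``/``.map``), recoded additively against
  the minor allele observed in the file;
* pedigree and phenotype tables as delimited text with a header;
* the association-result table as TSV.

Coordinates are 1-based as in ``.map`` files. Alleles are taken as
written (no strand handling).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Cell values treated as missing in delimited tables (besides empty cells).
DEFAULT_NA_VALUES = ("NA",)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: family/parent links and sex (1=male, 2=female, 0=unknown)."""

    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: int


@dataclass
class PedigreeTable:
    """A collection of pedigree records spanning one or more families.

    Invariants (checked by :meth:`validate`): individual ids unique;
    both parents null (founder) or both non-null; parents belong to the
    same family; the parent graph is acyclic.
    """

    records: list[PedigreeRecord]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def individual_ids(self) -> list[str]:
        return [r.individual_id for r in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        seen: set[str] = set()
        by_id: dict[str, PedigreeRecord] = {}
        for r in self.records:
            if r.individual_id in seen:
                raise ValidationError(
                    f"duplicate individual id {r.individual_id!r}"
                )
            seen.add(r.individual_id)
            by_id[r.individual_id] = r
        for r in self.records:
            if (r.father_id is None) != (r.mother_id is None):
                raise ValidationError(
                    f"individual {r.individual_id!r} has exactly one known "
                    "parent; both or neither are required"
                )
            for pid in (r.father_id, r.mother_id):
                if pid is None:
                    continue
                if pid not in by_id:
                    raise ValidationError(
                        f"parent {pid!r} of {r.individual_id!r} is not in the pedigree"
                    )
                if by_id[pid].family_id != r.family_id:
                    raise ValidationError(
                        f"parent {pid!r} of {r.individual_id!r} belongs to a "
                        "different family"
                    )
            if r.sex not in (0, 1, 2):
                raise ValidationError(
                    f"individual {r.individual_id!r} has invalid sex code {r.sex}"
                )
        # acyclicity: walk up from every individual
        for r in self.records:
            stack, seen_anc = [r.individual_id], set()
            while stack:
                iid = stack.pop()
                if iid in seen_anc:
                    continue
                seen_anc.add(iid)
                rec = by_id[iid]
                for pid in (rec.father_id, rec.mother_id):
                    if pid == r.individual_id:
                        raise ValidationError(
                            f"pedigree cycle through {r.individual_id!r}"
                        )
                    if pid is not None:
                        stack.append(pid)

    def topological_order(self) -> list[int]:
        """Indices into ``records`` with every parent before its children."""
        by_id = {r.individual_id: i for i, r in enumerate(self.records)}
        order: list[int] = []
        state = [0] * len(self.records)  # 0 unvisited, 1 active, 2 done

        def visit(i: int) -> None:
            if state[i] == 2:
                return
            if state[i] == 1:
                raise ValidationError("pedigree cycle detected")
            state[i] = 1
            r = self.records[i]
            for pid in (r.father_id, r.mother_id):
                if pid is not None:
                    visit(by_id[pid])
            state[i] = 2
            order.append(i)

        for i in range(len(self.records)):
            visit(i)
        return order


@dataclass(frozen=True)
class Marker:
    """SNP metadata: id, chromosome, 1-based position, minor/major alleles."""

    snp_id: str
    chromosome: str
    position: int
    allele_minor: str
    allele_major: str


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive genotypes (count of the minor allele).

    ``values`` is a float array with ``nan`` for missing cells; every
    observed cell is 0, 1 or 2.
    """

    values: np.ndarray
    individual_ids: list[str]
    markers: list[Marker]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be a 2-D matrix")
        if self.values.shape[0] != len(self.individual_ids):
            raise ValidationError(
                "genotype row count does not match number of individual ids"
            )
        if self.values.shape[1] != len(self.markers):
            raise ValidationError(
                "genotype column count does not match number of markers"
            )
        snp_ids = [m.snp_id for m in self.markers]
        if len(set(snp_ids)) != len(snp_ids):
            raise ValidationError("duplicate snp_id in marker list")
        for m in self.markers:
            if m.position < 0:
                raise ValidationError(f"negative position for {m.snp_id!r}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [m.snp_id for m in self.markers]

    def subset(
        self,
        individuals: Sequence[int] | None = None,
        snps: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        vals = self.values
        ids = self.individual_ids
        markers = self.markers
        if individuals is not None:
            idx = np.asarray(individuals, dtype=int)
            vals = vals[idx, :]
            ids = [ids[i] for i in idx]
        if snps is not None:
            jdx = np.asarray(snps, dtype=int)
            vals = vals[:, jdx]
            markers = [markers[j] for j in jdx]
        return GenotypeMatrix(vals.copy(), list(ids), list(markers))


@dataclass
class PhenotypeMatrix:
    """Individuals x traits real matrix with covariates.

    ``values`` may contain ``nan`` (missing measurement); ``covariates``
    must be complete.
    """

    values: np.ndarray
    trait_names: list[str]
    individual_ids: list[str]
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)
    family_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("phenotype values must be a 2-D matrix")
        if self.values.shape[1] != len(self.trait_names):
            raise ValidationError("trait_names length does not match columns")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ValidationError("trait names must be unique")
        if self.values.shape[0] != len(self.individual_ids):
            raise ValidationError("individual_ids length does not match rows")
        if self.covariates is None:
            self.covariates = np.empty((self.values.shape[0], 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.shape != (self.values.shape[0], len(self.covariate_names)):
            raise ValidationError(
                "covariate matrix shape does not match covariate_names/rows"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# PLINK text genotypes
# ---------------------------------------------------------------------------

def _read_map(map_path: Path) -> list[tuple[str, str, int]]:
    entries = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 4 columns, found {len(parts)}"
                )
            chrom, snp_id, _gdist, pos = parts
            try:
                position = int(pos)
            except ValueError as exc:
                raise FormatError(
                    f"{map_path}:{lineno}: non-integer position {pos!r}"
                ) from exc
            entries.append((chrom, snp_id, position))
    return entries


def read_plink(
    ped_path: str | Path, map_path: str | Path
) -> tuple[PedigreeTable, GenotypeMatrix]:
    """Read text PLINK ``.ped``/``.map`` files.

    Genotypes are recoded as counts of the minor allele determined from
    the file itself; "0 0" allele pairs become missing.  When both
    alleles have frequency exactly 0.5 the alphabetically first allele
    is labelled minor (deterministic tie-break).
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    map_entries = _read_map(map_path)
    n_snps = len(map_entries)

    records: list[PedigreeRecord] = []
    allele_rows: list[list[tuple[str, str]]] = []
    seen: set[tuple[str, str]] = set()
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                    f"for {n_snps} SNPs, found {len(parts)}"
                )
            fid, iid, father, mother, sex, _pheno = parts[:6]
            if (fid, iid) in seen:
                raise ValidationError(
                    f"{ped_path}:{lineno}: duplicate individual {iid!r} "
                    f"within family {fid!r}"
                )
            seen.add((fid, iid))
            records.append(
                PedigreeRecord(
                    family_id=fid,
                    individual_id=iid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=int(sex),
                )
            )
            alleles = parts[6:]
            allele_rows.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_snps)]
            )

    n = len(records)
    values = np.full((n, n_snps), np.nan)
    markers: list[Marker] = []
    for j, (chrom, snp_id, position) in enumerate(map_entries):
        counts: dict[str, int] = {}
        for i in range(n):
            a1, a2 = allele_rows[i][j]
            if a1 == "0" or a2 == "0":
                continue
            counts[a1] = counts.get(a1, 0) + 1
            counts[a2] = counts.get(a2, 0) + 1
        alleles_seen = sorted(counts)
        if len(alleles_seen) > 2:
            raise FormatError(
                f"{ped_path}: SNP {snp_id!r} has more than two alleles: "
                f"{alleles_seen}"
            )
        if not alleles_seen:
            minor, major = "0", "0"
        elif len(alleles_seen) == 1:
            minor, major = alleles_seen[0], alleles_seen[0]
        else:
            a, b = alleles_seen  # alphabetical
            if counts[a] == counts[b]:
                minor, major = a, b
            elif counts[a] < counts[b]:
                minor, major = a, b
            else:
                minor, major = b, a
        for i in range(n):
            a1, a2 = allele_rows[i][j]
            if a1 == "0" or a2 == "0":
                continue
            values[i, j] = (a1 == minor) + (a2 == minor)
        if len(alleles_seen) == 1:
            # monomorphic: observed allele is major, coded column all zero
            values[:, j] = np.where(np.isnan(values[:, j]), np.nan, 0.0)
            minor, major = "0", alleles_seen[0]
        markers.append(Marker(snp_id, chrom, position, minor, major))

    ped = PedigreeTable(records)
    return ped, GenotypeMatrix(values, [r.individual_id for r in records], markers)


def write_plink(
    ped: PedigreeTable,
    G: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Write text PLINK files; inverse of :func:`read_plink` up to allele labels."""
    if ped.individual_ids != G.individual_ids:
        raise ValidationError("pedigree and genotype individual ids differ")
    with open(map_path, "w") as fh:
        for m in G.markers:
            fh.write(f"{m.chromosome}\t{m.snp_id}\t0\t{m.position}\n")
    with open(ped_path, "w") as fh:
        for i, r in enumerate(ped.records):
            cols = [
                r.family_id,
                r.individual_id,
                r.father_id or "0",
                r.mother_id or "0",
                str(r.sex),
                "-9",
            ]
            for j, m in enumerate(G.markers):
                g = G.values[i, j]
                if math.isnan(g):
                    cols += ["0", "0"]
                else:
                    k = int(round(g))
                    mi = m.allele_minor if m.allele_minor != "0" else m.allele_major
                    cols += [mi] * k + [m.allele_major] * (2 - k)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Pedigree / phenotype tables
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path, sep: str = "\t") -> PedigreeTable:
    """Read a pedigree TSV with columns family_id, individual_id, father_id,
    mother_id, sex; "0" or empty parent fields mean founder."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = ["family_id", "individual_id", "father_id", "mother_id", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"pedigree file lacks columns {missing}; available: {list(df.columns)}"
        )
    records = [
        PedigreeRecord(
            family_id=row.family_id,
            individual_id=row.individual_id,
            father_id=None if row.father_id in ("0", "") else row.father_id,
            mother_id=None if row.mother_id in ("0", "") else row.mother_id,
            sex=int(row.sex),
        )
        for row in df.itertuples()
    ]
    return PedigreeTable(records)


def write_pedigree(ped: PedigreeTable, path: str | Path, sep: str = "\t") -> Path:
    df = pd.DataFrame(
        {
            "family_id": [r.family_id for r in ped.records],
            "individual_id": [r.individual_id for r in ped.records],
            "father_id": [r.father_id or "0" for r in ped.records],
            "mother_id": [r.mother_id or "0" for r in ped.records],
            "sex": [r.sex for r in ped.records],
        }
    )
    df.to_csv(path, sep=sep, index=False)
    return Path(path)


def read_phenotypes(
    path: str | Path,
    trait_columns: Sequence[str],
    covariate_columns: Sequence[str] = (),
    id_column: str = "individual_id",
    family_column: str = "family_id",
    sep: str = "\t",
    na_values: Iterable[str] = DEFAULT_NA_VALUES,
) -> PhenotypeMatrix:
    """Read a delimited phenotype table with a header row.

    Empty cells and any sentinel in ``na_values`` (default ``"NA"``)
    parse as missing.  Covariate columns must be complete.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    available = list(df.columns)
    wanted = [id_column, *trait_columns, *covariate_columns]
    absent = [c for c in wanted if c not in df.columns]
    if absent:
        raise ValidationError(
            f"requested columns {absent} not in file; available: {available}"
        )
    na = set(na_values) | {""}

    def parse_block(cols: Sequence[str]) -> np.ndarray:
        out = np.full((len(df), len(cols)), np.nan)
        for j, c in enumerate(cols):
            for i, cell in enumerate(df[c]):
                if cell.strip() in na:
                    continue
                out[i, j] = float(cell)
        return out

    values = parse_block(list(trait_columns))
    covariates = parse_block(list(covariate_columns))
    if covariate_columns and np.isnan(covariates).any():
        raise ValidationError("covariate columns contain missing values")
    family_ids = (
        list(df[family_column]) if family_column in df.columns else None
    )
    return PhenotypeMatrix(
        values=values,
        trait_names=list(trait_columns),
        individual_ids=list(df[id_column]),
        covariates=covariates,
        covariate_names=list(covariate_columns),
        family_ids=family_ids,
    )


def write_phenotypes(X: PhenotypeMatrix, path: str | Path, sep: str = "\t") -> Path:
    """Write a phenotype table (inverse of :func:`read_phenotypes`)."""
    data: dict[str, object] = {"individual_id": X.individual_ids}
    if X.family_ids is not None:
        data["family_id"] = X.family_ids
    for j, name in enumerate(X.covariate_names):
        data[name] = X.covariates[:, j]
    for j, name in enumerate(X.trait_names):
        data[name] = X.values[:, j]
    df = pd.DataFrame(data)
    df.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.12g")
    return Path(path)


# ---------------------------------------------------------------------------
# Association results
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = [
    "snp_id",
    "chromosome",
    "position",
    "metaphenotype",
    "maf",
    "beta",
    "lrt_stat",
    "p_raw",
    "p_adjusted",
    "significant",
]


def write_assoc_table(results: Sequence, path: str | Path) -> Path:
    """Write association results as TSV, sorted by (chromosome, position,
    metaphenotype).  ``results`` are AssocResult objects from the GWAS
    module (duck-typed to avoid a circular import)."""
    if not results:
        raise ValidationError("no association results to write")
    rows = [
        {
            "snp_id": r.snp_id,
            "chromosome": r.chromosome,
            "position": r.position,
            "metaphenotype": r.metaphenotype_label,
            "maf": r.maf,
            "beta": r.beta_snp,
            "lrt_stat": r.lrt_stat,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "significant": bool(r.significant),
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    df = df.sort_values(
        ["chromosome", "position", "metaphenotype"], kind="mergesort"
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return Path(path)


def read_assoc_table(path: str | Path) -> pd.DataFrame:
    """Read an association TSV back into a DataFrame (for reports/round-trips)."""
    return pd.read_csv(path, sep="\t")


def write_kinship(values: np.ndarray, ids: Sequence[str], path: str | Path) -> Path:
    """Export a kinship matrix as TSV with an id header row and column."""
    df = pd.DataFrame(np.asarray(values), index=list(ids), columns=list(ids))
    df.to_csv(path, sep="\t", float_format="%.12g")
    return Path(path)


def read_kinship(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_matrix(
    values: np.ndarray,
    path: str | Path,
    columns: Sequence[str],
    index: Sequence[str] | None = None,
    index_label: str = "id",
) -> Path:
    """Generic labelled-matrix TSV writer (loadings, scores, PRESS curves)."""
    df = pd.DataFrame(np.asarray(values), columns=list(columns))
    if index is not None:
        df.insert(0, index_label, list(index))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return Path(path)


def asdict_marker(m: Marker) -> dict:
    return dataclasses.asdict(m)
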