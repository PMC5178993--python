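"""Sample- and marker-level genotype quality control.

Filter order is fixed: sample call rate -> sample heterozygosity ->
sample IBS (the member of a flagged pair with the lower call rate is
dropped) -> marker call rate -> marker MAF.  Defaults follow common
GWAS-cleaning conventions: call rates >= 0.95, MAF >= 0.0064, pairwise
IBS <= 0.95, heterozygosity outliers at FDR 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import GenotypeMatrix
from .errors import PipelineError, UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    sample_call_rate_min: float = 0.95
    sample_ibs_max: float = 0.95
    sample_het_fdr: float = 0.01
    marker_call_rate_min: float = 0.95
    maf_min: float = 0.0064

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "sample_ibs_max", "marker_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.sample_het_fdr < 1.0:
            raise ValidationError("sample_het_fdr must lie in (0, 1)")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValidationError("maf_min must lie in [0, 0.5]")


@dataclass
class QCReport:
    """Itemized removals; each (entity, reason) pair appears exactly once."""

    removed_individuals: list[tuple[str, str]] = field(default_factory=list)
    removed_markers: list[tuple[str, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.removed_individuals + self.removed_markers:
            out[reason] = out.get(reason, 0) + 1
        return out


def maf(column: np.ndarray) -> float:
    """Minor allele frequency of an additively coded genotype column."""
    col = np.asarray(column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise UndefinedStatisticError("MAF undefined for an all-missing column")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def call_rate(column: np.ndarray) -> float:
    col = np.asarray(column, dtype=float)
    return float(1.0 - np.isnan(col).mean()) if col.size else 0.0


def ibs_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state: mean over jointly observed SNPs of
    1 - |g_i - g_j| / 2.  Pairs with no jointly observed SNP are nan."""
    vals = G.values
    n, p = vals.shape
    if n < 2 or p < 1:
        raise ValidationError("IBS requires >= 2 individuals and >= 1 SNP")
    observed = ~np.isnan(vals)
    filled = np.where(observed, vals, 0.0)
    # |g_i - g_j| has no bilinear expansion; loop over rows (desk scale)
    out = np.full((n, n), np.nan)
    for i in range(n):
        both = observed[i] & observed
        diff = np.abs(filled[i] - filled)
        diff[~both] = 0.0
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = 1.0 - (diff.sum(axis=1) / cnt) / 2.0
        sim[cnt == 0] = np.nan
        out[i] = sim
    np.fill_diagonal(out, 1.0)
    return out


def heterozygosity(G: GenotypeMatrix) -> np.ndarray:
    """Per-sample fraction of heterozygous calls among observed genotypes."""
    vals = G.values
    obs = ~np.isnan(vals)
    het = (vals == 1.0) & obs
    with np.errstate(invalid="ignore"):
        return het.sum(axis=1) / obs.sum(axis=1)


def heterozygosity_outliers(G: GenotypeMatrix, fdr: float) -> list[str]:
    """Flag samples whose heterozygosity is an outlier.

    A robust z-score (median / scaled MAD) gives two-sided normal
    p-values, which are thresholded by Benjamini-Hochberg at ``fdr``.
    """
    if not 0.0 < fdr < 1.0:
        raise ValidationError("fdr must lie in (0, 1)")
    h = heterozygosity(G)
    ok = ~np.isnan(h)
    med = np.median(h[ok])
    mad = np.median(np.abs(h[ok] - med))
    if mad == 0.0:
        logger.warning("zero MAD of heterozygosity; no outliers flagged")
        return []
    z = (h - med) / (1.4826 * mad)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~ok] = 1.0
    reject = _benjamini_hochberg(p, fdr)
    return sorted(
        (G.individual_ids[i] for i in np.flatnonzero(reject)),
        key=G.individual_ids.index,
    )


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean rejection mask of the BH step-up procedure."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.flatnonzero(below))
        reject[order[: kmax + 1]] = True
    return reject


def apply_qc(
    G: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the fixed-order QC filters and itemize every removal."""
    report = QCReport()
    vals = G.values
    n = G.n_individuals

    keep = np.ones(n, dtype=bool)
    sample_cr = 1.0 - np.isnan(vals).mean(axis=1)

    # 1. sample call rate
    for i in np.flatnonzero(sample_cr < thresholds.sample_call_rate_min):
        keep[i] = False
        report.removed_individuals.append(
            (G.individual_ids[i], "sample_call_rate")
        )

    # 2. sample heterozygosity (on survivors)
    sub = G.subset(individuals=np.flatnonzero(keep))
    if sub.n_individuals >= 3:
        flagged = set(heterozygosity_outliers(sub, thresholds.sample_het_fdr))
        for i in range(n):
            if keep[i] and G.individual_ids[i] in flagged:
                keep[i] = False
                report.removed_individuals.append(
                    (G.individual_ids[i], "sample_heterozygosity")
                )

    # 3. sample IBS: drop the member of each too-similar pair with lower call rate
    idx = np.flatnonzero(keep)
    if idx.size >= 2:
        sub = G.subset(individuals=idx)
        ibs = ibs_matrix(sub)
        order = np.argsort(-sample_cr[idx], kind="mergesort")  # best first
        dropped_local: set[int] = set()
        for a_pos in range(len(order)):
            a = order[a_pos]
            if a in dropped_local:
                continue
            for b_pos in range(a_pos + 1, len(order)):
                b = order[b_pos]
                if b in dropped_local:
                    continue
                v = ibs[a, b]
                if not np.isnan(v) and v > thresholds.sample_ibs_max:
                    dropped_local.add(b)
        for b in sorted(dropped_local):
            gi = idx[b]
            keep[gi] = False
            report.removed_individuals.append((G.individual_ids[gi], "sample_ibs"))

    if not keep.any():
        raise PipelineError("QC removed every individual")

    # 4/5. marker filters on surviving samples: call rate, then MAF
    sub = G.subset(individuals=np.flatnonzero(keep))
    keep_m = np.ones(sub.n_snps, dtype=bool)
    marker_cr = 1.0 - np.isnan(sub.values).mean(axis=0)
    for j in np.flatnonzero(marker_cr < thresholds.marker_call_rate_min):
        keep_m[j] = False
        report.removed_markers.append((sub.markers[j].snp_id, "marker_call_rate"))
    for j in np.flatnonzero(keep_m):
        if maf(sub.values[:, j]) < thresholds.maf_min:
            keep_m[j] = False
            report.removed_markers.append((sub.markers[j].snp_id, "marker_maf"))

    clean = sub.subset(snps=np.flatnonzero(keep_m))
    return clean, report


def write_qc_report(report: QCReport, path) -> None:
    import pandas as pd

    rows = [
        {"entity_type": "individual", "entity_id": eid, "reason": reason}
        for eid, reason in report.removed_individuals
    ] + [
        {"entity_type": "marker", "entity_id": eid, "reason": reason}
        for eid, reason in report.removed_markers
    ]
    pd.DataFrame(rows, columns=["entity_type", "entity_id", "reason"]).to_csv(
        path, sep="\t", index=False
    )
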