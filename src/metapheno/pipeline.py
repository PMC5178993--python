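"""End-to-end orchestration of the two-stage methodology.

``run_pipeline`` executes qc -> impute -> decompose (ICA and optionally
PCA) -> orient/order -> heritability -> gwas -> compare/graphs from a
single config mapping, writes every stage artifact into the output
directory, and finishes with a manifest listing all outputs with
content hashes (the reproducibility contract: same config + seed =>
identical hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import compare_report, data_io, decomposition, impute_bpca
from .errors import PipelineError, ValidationError
from .genotype_qc import QCThresholds, apply_qc, write_qc_report
from .kinship import kinship_matrix
from .varcomp_gwas import (
    gwas,
    heritability,
    write_heritability_table,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "qc": {},
    "impute": {"q": None, "max_iter": 500, "tol": 1e-5},
    "decompose": {
        "methods": ["ica", "pca"],
        "k": "auto",
        "k_max": None,
        "n_folds": 5,
        "contrast": "logcosh",
    },
    "covariates": ["age", "sex"],
    "alpha": 0.05,
    "seed": 0,
    "graphs": True,
}


def _merged(config: Mapping[str, Any]) -> dict[str, Any]:
    out = json.loads(json.dumps({k: v for k, v in DEFAULT_CONFIG.items()}))
    for k, v in config.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any]) -> Path:
    """Run every stage; returns the output directory.

    Required config keys: ``paths`` (ped, map, phenotypes, output_dir)
    and ``traits``.  A stage failure aborts with the stage name; partial
    outputs are retained.
    """
    cfg = _merged(config)
    paths = cfg.get("paths") or {}
    for key in ("ped", "map", "phenotypes", "output_dir"):
        if key not in paths:
            raise ValidationError(f"config paths.{key} is required")
    out_dir = Path(paths["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    alpha = float(cfg["alpha"])
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    stage = "read"
    try:
        ped, G = data_io.read_plink(paths["ped"], paths["map"])
        logger.info("read %d individuals x %d SNPs", G.n_individuals, G.n_snps)

        stage = "qc"
        thresholds = QCThresholds(**cfg["qc"])
        G_clean, report = apply_qc(G, thresholds)
        qc_path = out_dir / "qc_report.tsv"
        write_qc_report(report, qc_path)
        emit(qc_path)
        logger.info(
            "qc kept %d individuals x %d SNPs (seed %d)",
            G_clean.n_individuals, G_clean.n_snps, seed,
        )

        stage = "phenotypes"
        traits = list(cfg["traits"])
        X = data_io.read_phenotypes(
            paths["phenotypes"],
            trait_columns=traits,
            covariate_columns=list(cfg["covariates"]),
        )
        keep_ids = [i for i in X.individual_ids if i in set(G_clean.individual_ids)]
        if not keep_ids:
            raise PipelineError("no individuals shared by genotypes and phenotypes")
        missing_from_ped = [i for i in keep_ids if i not in set(ped.individual_ids)]
        if missing_from_ped:
            raise ValidationError(
                f"individuals absent from the pedigree: {missing_from_ped[:5]}"
            )
        xpos = {iid: i for i, iid in enumerate(X.individual_ids)}
        xi = [xpos[i] for i in keep_ids]
        X = data_io.PhenotypeMatrix(
            values=X.values[xi],
            trait_names=X.trait_names,
            individual_ids=keep_ids,
            covariates=X.covariates[xi],
            covariate_names=X.covariate_names,
            family_ids=[X.family_ids[i] for i in xi] if X.family_ids else None,
        )
        gpos = {iid: i for i, iid in enumerate(G_clean.individual_ids)}
        G_clean = G_clean.subset(individuals=[gpos[i] for i in keep_ids])

        stage = "impute"
        icfg = cfg["impute"]
        model = impute_bpca.fit_bpca(
            X, q=icfg.get("q"), max_iter=int(icfg["max_iter"]),
            tol=float(icfg["tol"]), seed=seed,
        )
        X_imp = impute_bpca.impute(X, model)
        imp_path = out_dir / "phenotypes_imputed.tsv"
        data_io.write_phenotypes(X_imp, imp_path)
        emit(imp_path)

        stage = "kinship"
        K = kinship_matrix(ped).subset(keep_ids)
        kin_path = out_dir / "kinship.tsv"
        data_io.write_kinship(K.values, K.individual_ids, kin_path)
        emit(kin_path)

        stage = "decompose"
        Xs, center, scale = decomposition.standardize(X_imp.values, X_imp.trait_names)
        dcfg = cfg["decompose"]
        methods = [m.lower() for m in dcfg["methods"]]
        m_traits = len(traits)
        if dcfg["k"] == "auto":
            k_max = dcfg.get("k_max") or min(m_traits - 1, 10)
            k, press = decomposition.choose_k_cv(
                Xs, k_max=int(k_max), n_folds=int(dcfg["n_folds"]), seed=seed
            )
            press_path = out_dir / "press_curve.tsv"
            data_io.write_matrix(
                press[None, :], press_path,
                columns=[f"k{i + 1}" for i in range(len(press))],
            )
            emit(press_path)
            logger.info("choose_k_cv selected k=%d", k)
        else:
            k = int(dcfg["k"])

        decomps: dict[str, decomposition.Decomposition] = {}
        for method in methods:
            if method == "ica":
                d = decomposition.fastica(
                    Xs, k=k, seed=seed, contrast=dcfg["contrast"],
                    trait_names=traits, center=center, scale=scale,
                )
            elif method == "pca":
                d = decomposition.pca(
                    Xs, k=k, trait_names=traits, center=center, scale=scale
                )
            else:
                raise ValidationError(f"unknown decomposition method {method!r}")
            d = decomposition.orient_and_order(d)
            decomps[method] = d
            lpath = out_dir / f"{method}_loadings.tsv"
            data_io.write_matrix(
                d.weights, lpath, columns=traits,
                index=d.component_labels, index_label="component",
            )
            emit(lpath)
            spath = out_dir / f"{method}_scores.tsv"
            data_io.write_matrix(
                d.scores, spath, columns=d.component_labels,
                index=keep_ids, index_label="individual_id",
            )
            emit(spath)

        stage = "heritability"
        C = X_imp.covariates if X_imp.covariates.size else None
        for method, d in decomps.items():
            herits = [
                heritability(d.scores[:, c], C, K, label=d.component_labels[c])
                for c in range(d.k)
            ]
            hpath = out_dir / f"heritability_{method}.tsv"
            write_heritability_table(herits, hpath)
            emit(hpath)

        stage = "gwas"
        assoc_by_method = {}
        for method, d in decomps.items():
            results = gwas(
                d.scores, G_clean, C, K, alpha=alpha,
                component_labels=d.component_labels,
            )
            assoc_by_method[method] = results
            apath = out_dir / f"assoc_{method}.tsv"
            data_io.write_assoc_table(results, apath)
            emit(apath)

        stage = "compare"
        if "ica" in decomps and "pca" in decomps:
            matches = compare_report.match_components(
                decomps["ica"], decomps["pca"]
            )
            cpath = out_dir / "compare_ica_pca.tsv"
            compare_report.write_match_table(matches, cpath)
            emit(cpath)

        stage = "graphs"
        if cfg["graphs"] and "ica" in decomps:
            d = decomps["ica"]
            for label in d.component_labels:
                graph = compare_report.build_graph(d, label, X_imp)
                gpath = out_dir / f"graph_ica_{label}.graphml"
                compare_report.write_graphml(graph, gpath)
                emit(gpath)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": seed,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir
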