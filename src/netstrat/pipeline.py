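"""End-to-end workflow: inputs -> SCN -> smoothing -> consensus netNMF_HC
over a range of k -> survival / stage / grade association -> differentially
mutated genes, with a manifest recording parameters, seeds and checksums.

All defaults equal the method's operating point: alpha=0.7, p=11 nearest
neighbours, lambda=200, k=2..8, 100 consensus replicates at 80% subsampling,
Bonferroni level 0.05, minimum 10 mutations per sample, 10-year follow-up.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import (DAYS_PER_YEAR, chi_squared_association, logrank_test,
                       truncate_followup)
from .coexpression import build_cn, build_scn, knn_graph, spearman_all_pairs
from .consensus import consensus_cluster
from .diffmut import sam_qvalues, select_differential
from .io import (align_universes, filter_samples_min_mutations,
                 filter_zero_expression_genes, read_clinical, read_edge_list,
                 read_matrix, read_mutation_pairs, validate_mutation_matrix,
                 write_matrix)
from .smoothing import smooth_profiles

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run (YAML-loadable)."""

    mutations: str = ""
    expression: str = ""
    clinical: str = ""
    prior_network: str | None = None     # edge list; skips the SCN stage
    prior_weighted: bool = False
    mutations_as_pairs: bool = False
    alpha: float = 0.7
    knn_p: int = 11
    reg: float = 200.0
    k_min: int = 2
    k_max: int = 8
    consensus_iters: int = 100
    frac: float = 0.8
    scn_alpha: float = 0.05
    min_mutations: int = 10
    horizon_years: int = 10
    assignment: str = "hc"               # 'hc' (netNMF_HC) or 'argmax' (netNMF)
    n_perm: int = 1000
    diffmut_input: str = "smoothed"      # 'smoothed' or 'binary'
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Run every stage, writing TSV outputs and a JSON manifest to ``outdir``.

    A failing stage aborts with the stage named; partial outputs are kept
    alongside a FAILED marker file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "netstrat_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(cfg),
        "stages": [],
        "outputs": {},
    }
    stage = "load"
    try:
        # ---- load ---------------------------------------------------------
        if cfg.mutations_as_pairs:
            F0 = read_mutation_pairs(cfg.mutations)
        else:
            F0 = validate_mutation_matrix(read_matrix(cfg.mutations))
        clin = read_clinical(cfg.clinical) if cfg.clinical else None
        E = read_matrix(cfg.expression) if cfg.expression else None
        if E is None and cfg.prior_network is None:
            raise ValueError("need an expression matrix or a prior network")
        manifest["stages"].append(stage)

        # ---- filter -------------------------------------------------------
        stage = "filter"
        F0 = filter_samples_min_mutations(F0, cfg.min_mutations)
        if E is not None:
            E = filter_zero_expression_genes(E)
        logger.info("after filters: %d samples, %d mutation genes",
                    *F0.shape)
        manifest["stages"].append(stage)

        # ---- network ------------------------------------------------------
        stage = "network"
        if cfg.prior_network:
            net = read_edge_list(cfg.prior_network, weighted=cfg.prior_weighted)
            knn_source = net
            manifest["network_mode"] = "prior"
        else:
            corr = spearman_all_pairs(E)
            cn = build_cn(corr)
            net = build_scn(corr, alpha_level=cfg.scn_alpha)
            knn_source = cn
            manifest["network_mode"] = "scn"
            manifest["scn_edges"] = net.n_edges
        F0, net = align_universes(F0, net)
        knn = knn_graph(knn_source, p=cfg.knn_p).subset(net.genes)
        manifest["stages"].append(stage)

        # ---- smoothing (k-independent, computed once) ---------------------
        stage = "smoothing"
        smoothed = smooth_profiles(F0, net, alpha=cfg.alpha)
        write_matrix(smoothed, outdir / "smoothed.tsv")
        manifest["stages"].append(stage)

        # ---- consensus / clinical / diffmut per k -------------------------
        all_labels = {}
        for k in range(cfg.k_min, cfg.k_max + 1):
            stage = f"consensus_k{k}"
            result = consensus_cluster(
                F0, net, knn, k=k, n_iter=cfg.consensus_iters, frac=cfg.frac,
                seed=cfg.seed, alpha=cfg.alpha, lam=cfg.reg,
                assignment=cfg.assignment,
            )
            labels = pd.Series(result.labels, index=F0.index, name="label")
            all_labels[k] = labels
            labels.rename_axis("sample").to_frame().assign(k=k).to_csv(
                outdir / f"labels_k{k}.tsv", sep="\t")
            pd.DataFrame(result.similarity, index=F0.index,
                         columns=F0.index).to_csv(
                outdir / f"consensus_k{k}.tsv", sep="\t")
            manifest["stages"].append(stage)

            if clin is not None:
                stage = f"clinical_k{k}"
                horizon = cfg.horizon_years * DAYS_PER_YEAR
                trunc = truncate_followup(clin, horizon_days=horizon)
                rows = []
                surv = logrank_test(labels, trunc)
                rows.append({"k": k, "test": "logrank",
                             "statistic": surv.statistic, "df": surv.df,
                             "p": surv.p_value})
                for col in ("stage", "grade"):
                    if col in clin.columns:
                        try:
                            s, df_, p, _ = chi_squared_association(
                                labels, clin[col])
                            rows.append({"k": k, "test": f"chi2_{col}",
                                         "statistic": s, "df": df_, "p": p})
                        except ValueError as exc:
                            logger.warning("chi2 %s at k=%d skipped: %s",
                                           col, k, exc)
                pd.DataFrame(rows).to_csv(outdir / f"clinical_k{k}.tsv",
                                          sep="\t", index=False)
                manifest["stages"].append(stage)

            stage = f"diffmut_k{k}"
            diff_input = smoothed if cfg.diffmut_input == "smoothed" else F0.T
            for subtype in sorted(labels.unique()):
                if (labels == subtype).sum() < 2:
                    logger.warning("subtype %d at k=%d has < 2 samples; "
                                   "skipping diffmut", subtype, k)
                    continue
                res = sam_qvalues(diff_input, labels, subtype,
                                  n_perm=cfg.n_perm, seed=cfg.seed)
                res.to_frame().to_csv(
                    outdir / f"diffmut_k{k}_subtype{subtype}.tsv", sep="\t")
                genes = select_differential(res)
                (outdir / f"genes_k{k}_subtype{subtype}.txt").write_text(
                    "\n".join(map(str, genes)) + "\n")
            manifest["stages"].append(stage)

        manifest["outputs"] = {
            p.name: _sha256(p) for p in sorted(outdir.iterdir())
            if p.suffix in {".tsv", ".txt"}
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return outdir
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
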