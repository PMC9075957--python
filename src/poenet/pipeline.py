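"""End-to-end orchestration: ASE -> DE -> network -> phenotype -> epistasis.

Stage filtering follows the candidate funnel of the analysis: only
ASE-significant genes become edge sources, only DE-significant genes become
edge targets, only flagged edges joined with |r| >= 0.5, FDR-passing
gene-phenotype correlations proceed to epistasis.  A master seed
deterministically derives per-stage seeds, every stage writes its table to
the run directory, and a manifest records seeds, thresholds, and input
checksums so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import de as de_mod
from . import epistasis as epi_mod
from . import network as net_mod
from . import phenotype as pheno_mod
from . import simulate as sim_mod

__all__ = ["RunConfig", "run_pipeline", "synthetic_inputs"]


@dataclass
class RunConfig:
    """All thresholds and iteration counts for one pipeline run."""

    out_dir: str = "poenet_run"
    seed: int = 0
    fdr_ase: float = 0.1
    alpha_score: float = 0.01
    min_ase_depth: float = 20.0
    fdr_de: float = 0.1
    min_fc: float = 1.5
    min_de_count: float = 10.0
    fdr_edge: float = 0.1
    alpha_mte: float = 0.01
    r_min: float = 0.5
    fdr_pheno: float = 0.05
    fdr_epi: float = 0.1
    window: float = 1.5e6
    ase_iterations: int = 10
    edge_iterations: int = 10
    epi_iterations: int = 10
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        return cfg


def _stage_seeds(master_seed: int, n: int = 8):
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def synthetic_inputs(seed: int = 0, n_per_cell: int = 4, n_genes: int = 60):
    """A small fully-synthetic input bundle with planted signal at every stage.

    Plants imprinted ASE genes, cross-DE genes, ASE->DE couplings, and one
    imprinting-by-imprinting epistatic triple, and returns the ground truth
    alongside the tables so integration tests can check recovery.
    """
    seeds = _stage_seeds(seed, 6)
    design = sim_mod.make_design(n_per_cell, "F1")
    genes = [f"g{i:04d}" for i in range(n_genes)]
    ase_genes = {genes[0]: {"LxS": 0.05, "SxL": 0.95}, genes[1]: {"LxS": 0.9, "SxL": 0.1}}
    de_genes = {genes[2]: 1.5, genes[3]: -1.2}
    edges = [(genes[0], genes[2], 0.6), (genes[1], genes[3], -0.5)]
    markers = [("1", int(3e6 + 2e6 * i)) for i in range(10)] + [
        ("2", int(3e6 + 2e6 * i)) for i in range(10)
    ]
    marker_ids = [f"m_{c}_{p}" for c, p in markers]
    triple = (marker_ids[2], marker_ids[12], "basal_glucose", 0.5)
    truth = sim_mod.GroundTruth(
        ase_genes=ase_genes, de_genes=de_genes, edges=edges, epistatic_triples=[triple]
    )
    allelic = sim_mod.simulate_allelic_counts(design, truth, genes, seed=seeds[0])
    expr = sim_mod.simulate_expression(design, truth, genes, seed=seeds[1])
    genotypes, f16_pheno, marker_map = sim_mod.simulate_intercross(
        n_animals=400, markers=markers, truth=truth, seed=seeds[2]
    )
    rng = np.random.default_rng(seeds[3])
    # F1 phenotype correlated with the first DE gene's expression
    z = np.log1p(expr.loc[genes[2]].to_numpy(dtype=float))
    z = (z - z.mean()) / z.std()
    f1_pheno = pd.DataFrame(
        {"basal_glucose": 10 + 2 * z + rng.normal(0, 0.5, len(design))},
        index=design["sample_id"],
    )
    gene_pos = {
        genes[0]: ("1", int(6.9e6), int(7.1e6)),
        genes[1]: ("1", int(14.9e6), int(15.1e6)),
        genes[2]: ("2", int(6.9e6), int(7.1e6)),
        genes[3]: ("2", int(14.9e6), int(15.1e6)),
    }
    return {
        "design": design,
        "allelic": allelic,
        "expression": expr,
        "f1_phenotypes": f1_pheno,
        "genotypes": genotypes,
        "f16_phenotypes": f16_pheno,
        "marker_map": marker_map,
        "gene_positions": gene_pos,
        "truth": truth,
    }


def run_pipeline(config: RunConfig, inputs: dict) -> dict:
    """Run every stage on the provided input bundle and persist outputs.

    ``inputs`` carries the tables produced by :func:`synthetic_inputs` or
    loaded from files with matching keys.  Returns the stage result tables;
    writes TSVs plus a manifest to ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 8)
    results: dict = {}

    # stage 1: parent-of-origin ASE
    ase_res = ase_mod.ase_scan(
        inputs["allelic"],
        min_depth=config.min_ase_depth,
        n_iterations=config.ase_iterations,
        fdr_threshold=config.fdr_ase,
        alpha_score=config.alpha_score,
        seed=seeds[0],
    )
    results["ase"] = ase_res
    ase_res.to_csv(out / "ase_results.tsv", sep="\t")

    # stage 2: DE by reciprocal cross
    de_res = de_mod.de_scan(
        inputs["expression"],
        inputs["design"],
        min_normalized_count=config.min_de_count,
        fdr_threshold=config.fdr_de,
        min_fold_change=config.min_fc,
    )
    results["de"] = de_res
    de_res.to_csv(out / "de_results.tsv", sep="\t")

    # stage 3: network edges (ASE-significant sources x DE-significant targets)
    ase_sig = ase_res.index[ase_res["significant"]].tolist()
    de_sig = de_res.index[de_res["significant"]].tolist()
    candidates = [(a, d) for a in ase_sig for d in de_sig if a != d]
    lbias = ase_mod.compute_lbias(inputs["allelic"])
    log_expr = np.log1p(inputs["expression"].astype(float))
    if candidates:
        edges = net_mod.test_candidate_edges(
            candidates, log_expr, log_expr, lbias, inputs["design"], seed=seeds[1]
        )
        null, null_mte = net_mod.stabilized_null(
            candidates, log_expr, log_expr, lbias, inputs["design"],
            n_iterations=max(config.edge_iterations, 5), seed=seeds[2],
        )
        edges = net_mod.edge_fdr(
            edges, null, null_mte, alpha_mte=config.alpha_mte, fdr_threshold=config.fdr_edge
        )
    else:
        edges = pd.DataFrame(
            columns=["ase_gene", "de_gene", "mte", "lrt_stat", "lrt_p",
                     "untestable", "calibrated_p", "fdr", "significant"]
        )
    results["network"] = edges
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)

    # stage 4: phenotype correlation on residualized phenotypes
    design_idx = inputs["design"].set_index("sample_id").loc[inputs["f1_phenotypes"].index]
    resid = {}
    for pheno in inputs["f1_phenotypes"].columns:
        y, _ = pheno_mod.normalize_phenotype(inputs["f1_phenotypes"][pheno])
        resid[pheno] = pheno_mod.residualize(y, design_idx)
    resid = pd.DataFrame(resid, index=inputs["f1_phenotypes"].index)
    net_genes = sorted({g for e in edges.itertuples() for g in (e.ase_gene, e.de_gene)
                        if getattr(e, "significant", False)})
    corr = pheno_mod.correlate_genes(
        log_expr.loc[net_genes, resid.index] if net_genes else log_expr.iloc[0:0],
        resid, r_min=config.r_min, fdr_threshold=config.fdr_pheno,
    ) if net_genes else pd.DataFrame(columns=["gene", "phenotype", "r", "p", "q", "significant"])
    results["phenotype"] = corr
    corr.to_csv(out / "phenotype_correlations.tsv", sep="\t", index=False)

    # stage 5: epistasis on candidate ASE/DE/phenotype sets
    sig_edges = edges[edges.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
    sig_corr = corr[corr["significant"]] if not corr.empty else corr
    pairs = []
    for e in sig_edges.itertuples():
        for c in sig_corr.itertuples():
            if c.gene not in (e.ase_gene, e.de_gene):
                continue
            a_markers = epi_mod.select_markers(
                inputs["gene_positions"][e.ase_gene], inputs["marker_map"], config.window
            ) if e.ase_gene in inputs["gene_positions"] else []
            d_markers = epi_mod.select_markers(
                inputs["gene_positions"][e.de_gene], inputs["marker_map"], config.window
            ) if e.de_gene in inputs["gene_positions"] else []
            for am in a_markers:
                for dm in d_markers:
                    pairs.append((am, dm, c.phenotype))
    pairs = sorted(set(pairs))
    if pairs:
        scores = epi_mod.score_matrix(inputs["genotypes"])
        f16 = inputs["f16_phenotypes"]
        r_pheno = {}
        for pheno in {p for _, _, p in pairs}:
            r_pheno[pheno] = epi_mod.covariate_screen(f16[pheno], f16[["sex", "diet"]])
        r_pheno = pd.DataFrame(r_pheno, index=f16.index)
        epi_res, _ = epi_mod.epistasis_permutation_fdr(
            pairs, scores, r_pheno,
            n_iterations=config.epi_iterations, fdr_threshold=config.fdr_epi, seed=seeds[3],
        )
    else:
        epi_res = pd.DataFrame(
            columns=["ase_locus", "de_locus", "phenotype", "p_interaction",
                     "status", "fdr", "significant"]
        )
    results["epistasis"] = epi_res
    epi_res.to_csv(out / "epistasis_results.tsv", sep="\t", index=False)

    manifest = {
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "stage_seeds": seeds,
        "input_checksums": {
            "expression": _checksum(inputs["expression"]),
            "f1_phenotypes": _checksum(inputs["f1_phenotypes"]),
            "genotypes": _checksum(inputs["genotypes"]),
        },
        "stage_rows": {k: int(len(v)) for k, v in results.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
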