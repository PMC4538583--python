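"""End-to-end orchestration: simulate -> normalize -> structure -> DE ->
accounting -> clustering -> monotony -> concordance, with a JSON manifest.

Every stage output is a TSV under the run directory; the manifest records
package and library versions, the global seed and the per-stage seeds fanned
out from it, the thresholds in force, and the gene counts each stage
produced.  Reruns with an identical config reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accounting import crossline_common, recurrence_partition, select_validation_genes
from .clustering import FcmConfig, build_profiles, choose_c, summarize_clusters
from .crossplatform import platform_fold_changes
from .diffexp import run_comparison
from .io import read_count_matrix, write_count_matrix, write_expression_tsv
from .monotonicity import MonotonyConfig, classify_genes, compare_lines
from .normalize import compute_rpkm, filter_expressed, log2_transform
from .simulate import SimulationConfig, generate_dataset, simulate_qpcr
from .structure import pca_samples, sample_spearman

# fixed offsets fanning the global seed out to the stochastic stages
SEED_OFFSETS = {"simulate": 0, "fcm": 1009, "monotony": 2003, "qpcr": 3001}


@dataclasses.dataclass
class RunConfig:
    """Aggregated configuration of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    fcm: FcmConfig = dataclasses.field(default_factory=FcmConfig)
    monotony: MonotonyConfig = dataclasses.field(default_factory=MonotonyConfig)
    fdr_standard: float = 0.05
    fdr_strict: float = 0.01
    lfc_strict: float = 1.0
    validation_rpkm_threshold: float = 50.0
    max_validation_genes: int = 12
    # optional pre-existing input TSVs; when set, simulation is skipped
    counts_tsv: str | None = None
    samples_tsv: str | None = None
    lengths_tsv: str | None = None

    def validate(self) -> None:
        if self.fdr_standard <= 0 or self.fdr_strict <= 0 or self.lfc_strict <= 0:
            raise ValueError("thresholds must be positive")
        paths = (self.counts_tsv, self.samples_tsv, self.lengths_tsv)
        if any(p is not None for p in paths):
            for p, name in zip(paths, ("counts", "samples", "lengths")):
                if p is None:
                    raise FileNotFoundError(f"input mode requires a {name} file")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        fcm_cfg = FcmConfig(**{**raw.pop("fcm", {})})
        mono = MonotonyConfig(**raw.pop("monotony", {}))
        cfg = cls(simulation=sim, fcm=fcm_cfg, monotony=mono, **raw)
        return cfg


def comparison_plan(pd_labels) -> list:
    """Four consecutive PD pairs plus first-vs-last, in plot order."""
    pds = list(pd_labels)
    pairs = [(pds[i], pds[i + 1]) for i in range(len(pds) - 1)]
    pairs.append((pds[0], pds[-1]))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {
            "fibrotime": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "stage_seeds": {k: config.seed + v for k, v in SEED_OFFSETS.items()},
        "thresholds": {
            "fdr_standard": config.fdr_standard,
            "fdr_strict": config.fdr_strict,
            "lfc_strict": config.lfc_strict,
        },
        "stages": {},
        "outputs": {},
    }

    # ---- input: simulate or load -------------------------------------------
    if config.counts_tsv is not None:
        cm = read_count_matrix(config.counts_tsv, config.samples_tsv, config.lengths_tsv)
        truth = None
        manifest["stages"]["input"] = {"mode": "files", "n_genes": len(cm.gene_ids)}
    else:
        sim = dataclasses.replace(
            config.simulation, seed=config.seed + SEED_OFFSETS["simulate"]
        )
        cm, truth = generate_dataset(sim)
        paths = write_count_matrix(cm, outdir)
        truth_path = outdir / "truth.tsv"
        truth.write_tsv(truth_path)
        paths["truth"] = str(truth_path)
        manifest["outputs"].update(paths)
        manifest["stages"]["input"] = {
            "mode": "simulated",
            "n_genes": len(cm.gene_ids),
            "n_samples": len(cm.sample_ids),
        }

    cell_lines = list(pd.unique(cm.sample_meta["cell_line"]))

    # ---- normalize ----------------------------------------------------------
    expressed = filter_expressed(cm)
    rpkm = compute_rpkm(expressed)
    log2rpkm = log2_transform(rpkm)
    write_expression_tsv(rpkm, outdir / "rpkm.tsv")
    manifest["outputs"]["rpkm"] = str(outdir / "rpkm.tsv")
    manifest["stages"]["normalize"] = {
        "n_expressed": len(expressed.gene_ids),
        "n_removed": len(cm.gene_ids) - len(expressed.gene_ids),
    }

    # ---- global structure ---------------------------------------------------
    corr = sample_spearman(log2rpkm)
    pca = pca_samples(log2rpkm)
    corr.rho.to_csv(outdir / "sample_spearman.tsv", sep="\t")
    pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    pd.Series(
        pca.variance_explained,
        index=[f"PC{i + 1}" for i in range(len(pca.variance_explained))],
        name="variance_pct",
    ).to_csv(outdir / "pca_variance.tsv", sep="\t")
    manifest["outputs"]["sample_spearman"] = str(outdir / "sample_spearman.tsv")
    manifest["outputs"]["pca_scores"] = str(outdir / "pca_scores.tsv")
    manifest["stages"]["structure"] = {
        "dendrogram_order": corr.order,
        "variance_pc1_3_pct": float(pca.variance_explained[:3].sum()),
    }

    # ---- differential expression -------------------------------------------
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    de_results: dict = {}
    de_counts = []
    for line in cell_lines:
        pds = sorted(cm.sample_meta.loc[cm.sample_meta["cell_line"] == line, "pd"].unique())
        for pd_from, pd_to in comparison_plan(pds):
            res = run_comparison(
                expressed,
                line,
                pd_from,
                pd_to,
                config.fdr_standard,
                config.fdr_strict,
                config.lfc_strict,
            )
            key = f"{line}_PD{pd_from}_vs_PD{pd_to}"
            de_results[(line, pd_from, pd_to)] = res
            table = pd.concat(
                [rpkm.values.loc[res.index], res], axis=1
            )
            table.rename_axis("gene_id").to_csv(de_dir / f"{key}.tsv", sep="\t")
            de_counts.append(
                {
                    "comparison": key,
                    "cell_line": line,
                    "pd_from": pd_from,
                    "pd_to": pd_to,
                    "deg_standard": int(res["deg_standard"].sum()),
                    "deg_strict": int(res["deg_strict"].sum()),
                }
            )
    de_table = pd.DataFrame(de_counts)
    de_table.to_csv(outdir / "deg_counts.tsv", sep="\t", index=False)
    manifest["outputs"]["de_dir"] = str(de_dir)
    manifest["stages"]["diffexp"] = {
        row["comparison"]: {
            "deg_standard": row["deg_standard"],
            "deg_strict": row["deg_strict"],
        }
        for row in de_counts
    }

    # ---- accounting ---------------------------------------------------------
    plan_order = []
    for line in cell_lines:
        for (l, a, b), res in de_results.items():
            if l == line:
                plan_order.append(
                    (f"{l}_PD{a}_vs_PD{b}", set(res.index[res["deg_standard"]]))
                )
    recurrence = recurrence_partition(plan_order)
    recurrence.counts.to_csv(outdir / "recurrence_counts.tsv", sep="\t")

    first_last = {}
    for line in cell_lines:
        pds = sorted(cm.sample_meta.loc[cm.sample_meta["cell_line"] == line, "pd"].unique())
        first_last[line] = de_results[(line, pds[0], pds[-1])]
    l1, l2 = cell_lines[0], cell_lines[1] if len(cell_lines) > 1 else cell_lines[0]
    strict1 = set(first_last[l1].index[first_last[l1]["deg_strict"]])
    strict2 = set(first_last[l2].index[first_last[l2]["deg_strict"]])
    cross = crossline_common(
        strict1, strict2, first_last[l1]["log2fc"], first_last[l2]["log2fc"]
    )
    manifest["stages"]["accounting"] = {
        "recurrence_new": {
            k: int(v) for k, v in recurrence.new_counts().items()
        },
        "strict_first_last": {l1: len(strict1), l2: len(strict2)},
        "intersection": len(cross.intersection),
        "common_up": len(cross.common_up),
        "common_down": len(cross.common_down),
        "discordant": len(cross.discordant),
    }

    # ---- profile clustering -------------------------------------------------
    strict_union = {}
    for line in cell_lines:
        sets = [
            set(res.index[res["deg_strict"]])
            for (l, _, _), res in de_results.items()
            if l == line
        ]
        strict_union[line] = set().union(*sets)
    cluster_genes = sorted(set.intersection(*strict_union.values()))
    cluster_stage: dict = {"n_candidate_genes": len(cluster_genes)}
    if len(cluster_genes) > config.fcm.c_range[0] + 1:
        fcm_cfg = dataclasses.replace(
            config.fcm, seed=config.seed + SEED_OFFSETS["fcm"]
        )
        lo, hi = fcm_cfg.c_range
        hi = min(hi, len(cluster_genes) - 1)
        fcm_cfg = dataclasses.replace(fcm_cfg, c_range=(lo, hi))
        profiles = build_profiles(rpkm, cm.sample_meta, cluster_genes, lines=cell_lines)
        chosen_c, validity, results = choose_c(profiles, fcm_cfg)
        result = results[chosen_c]
        suppl = pd.concat(
            [profiles.raw_means, result.hard.rename("cluster")], axis=1
        )
        suppl.rename_axis("gene_id").to_csv(outdir / "clusters.tsv", sep="\t")
        validity.to_csv(outdir / "cluster_validity.tsv", sep="\t")
        summary = summarize_clusters(result, profiles)
        summary.to_csv(outdir / "cluster_profiles.tsv", sep="\t")
        manifest["outputs"]["clusters"] = str(outdir / "clusters.tsv")
        cluster_stage.update(
            {
                "n_clustered": int(result.hard.size),
                "n_dropped_constant": len(profiles.dropped),
                "chosen_c": int(chosen_c),
                "cluster_sizes": {
                    str(k): int(v)
                    for k, v in result.hard.value_counts().sort_index().items()
                },
            }
        )
    else:
        cluster_stage["skipped"] = "too few strict DEG shared by both lines"
    manifest["stages"]["clustering"] = cluster_stage

    # ---- monotonicity -------------------------------------------------------
    mono_cfg = dataclasses.replace(
        config.monotony, seed=config.seed + SEED_OFFSETS["monotony"]
    )
    mono_results = {}
    mono_stage = {}
    for line in cell_lines:
        res = classify_genes(rpkm.values, cm.sample_meta, line, mono_cfg)
        mono_results[line] = res
        mono_stage[line] = {k: int(v) for k, v in res.counts().items()}
    mono_table = pd.concat(
        {line: res.table for line, res in mono_results.items()}, axis=1
    )
    mono_table.columns = ["_".join(col) for col in mono_table.columns]
    mono_table.rename_axis("gene_id").to_csv(outdir / "monotonicity.tsv", sep="\t")
    manifest["outputs"]["monotonicity"] = str(outdir / "monotonicity.tsv")
    if len(cell_lines) > 1:
        venn = compare_lines(mono_results[l1], mono_results[l2])
        mono_stage["venn"] = {k: len(v) for k, v in venn.items()}
    manifest["stages"]["monotonicity"] = mono_stage

    # ---- cross-platform concordance (synthetic qPCR) ------------------------
    concord_stage: dict = {}
    if truth is not None and len(cell_lines) > 1:
        per_pd_max = {}
        for line in cell_lines:
            sub = cm.sample_meta[cm.sample_meta["cell_line"] == line]
            for pd_label in sorted(sub["pd"].unique()):
                samples = sub[sub["pd"] == pd_label].index
                per_pd_max[f"{line}:{pd_label}"] = rpkm.values[list(samples)].mean(axis=1)
        max_mean = pd.DataFrame(per_pd_max).max(axis=1)
        rows = pd.DataFrame(
            {
                "deg_strict_line1": first_last[l1]["deg_strict"],
                "deg_strict_line2": first_last[l2]["deg_strict"],
                "max_mean_rpkm": max_mean,
            }
        ).dropna()
        selected = sorted(
            select_validation_genes(rows, config.validation_rpkm_threshold)
        )[: config.max_validation_genes]
        concord_stage["n_selected"] = len(selected)
        if selected:
            qpcr = simulate_qpcr(
                rpkm.values, selected, seed=config.seed + SEED_OFFSETS["qpcr"]
            )
            rho_means = {}
            for line in cell_lines:
                pds = sorted(
                    cm.sample_meta.loc[cm.sample_meta["cell_line"] == line, "pd"].unique()
                )
                conc = platform_fold_changes(
                    rpkm.values, cm.sample_meta, qpcr, line, pds[0], pds[-1]
                )
                conc.to_csv(outdir / f"concordance_{line}.tsv", sep="\t")
                rho_means[line] = float(conc["spearman_rho"].mean())
            concord_stage["mean_spearman_rho"] = rho_means
    manifest["stages"]["concordance"] = concord_stage

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
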