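"""End-to-end orchestration of the synthetic analysis pipeline.

``run_pipeline`` executes the stages in dependency order on generated
inputs with recorded ground truth: simulate -> per-comparison enrichment ->
consensus signature -> promoter scan + stress-element enrichment -> CAG
correlation with permutation FDR -> interactome overlay and tri-set
prioritization. Every stage writes plain TSV into the run directory, a
manifest records parameters, derived seeds and SHA-256 hashes of all
written inputs, and the whole run is a pure function of the config
(byte-identical outputs on re-run).

Config is a flat TOML file; all stochastic stages draw their seeds
deterministically from ``[run] seed``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import cag_correlation, consensus, enrichment_stats, gsea_core, motif_scan, network_prioritize
from .io_gene_sets import GeneSet, write_cls, write_expression, write_gmt
from .synthetic_data import simulate_cag_series, simulate_expression, simulate_network, simulate_promoters

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULTS: dict[str, dict[str, Any]] = {
    "run": {"outdir": "uprhd_run", "seed": None},
    "expression": {
        "n_genes": 400, "n_case": 8, "n_control": 8, "planted_set_size": 40,
        "effect": 1.5, "noise_sd": 1.0, "n_murine": 6, "human_comparison": "human_ipsc",
    },
    "gsea": {"metric": "signal2noise", "n_perm": 300, "n_decoy_sets": 5, "decoy_set_size": 40},
    "consensus": {"min_support": 4},
    "promoters": {"upre_rate": 0.03, "erse1_rate": 0.01, "erse2_rate": 0.01, "boosted_upre_rate": 0.8},
    "cag": {"replicates": 4, "effect": 2.0, "noise_sd": 0.5, "n_perm": 300, "fdr": 0.01},
    "network": {"n_nodes": 300, "n_edges": 900, "apoptosis_overlap": 40, "htt_overlap": 6},
    "prioritize": {"n_hdtt_decoys": 60, "n_httint": 25, "n_direct": 5},
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with path.open("rb") as fh:
        raw = tomllib.load(fh)
    return validate_config(raw)


def validate_config(raw: Mapping[str, Any]) -> dict:
    """Merge defaults, check seed, numeric sanity and referenced paths."""
    cfg: dict[str, dict[str, Any]] = {}
    for section, defaults in DEFAULTS.items():
        merged = dict(defaults)
        extra = raw.get(section, {})
        if not isinstance(extra, Mapping):
            raise ConfigError(f"section [{section}] must be a table")
        merged.update(extra)
        cfg[section] = merged
    if cfg["run"]["seed"] is None:
        raise ConfigError("[run] seed is mandatory: stochastic stages refuse to run unseeded")
    if not isinstance(cfg["run"]["seed"], int):
        raise ConfigError("[run] seed must be an integer")
    for section, merged in cfg.items():
        for key, value in merged.items():
            if key.endswith("path") and value:
                if not Path(value).exists():
                    raise ConfigError(f"[{section}] {key} = {value!r} does not exist")
    for key in ("n_genes", "n_case", "n_control", "planted_set_size"):
        if cfg["expression"][key] <= 0:
            raise ConfigError(f"[expression] {key} must be positive")
    if cfg["consensus"]["min_support"] < 0:
        raise ConfigError("[consensus] min_support must be >= 0")
    return cfg


def _stage_seed(base: int, offset: int) -> int:
    return int((base * 1009 + offset) % (2**31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: Mapping[str, Any] | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute all stages; returns the run directory.

    Raises :class:`ConfigError` before any stage runs on invalid config and
    :class:`StageError` naming the failing stage otherwise (partial outputs
    are retained).
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else validate_config(config)
    out = Path(outdir) if outdir is not None else Path(cfg["run"]["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["run"]["seed"]
    manifest: dict[str, Any] = {"config": cfg, "stages": {}, "inputs": {}}
    log_lines: list[str] = []

    def log_stage(stage: str, **info: Any) -> None:
        manifest["stages"][stage] = info
        line = f"{stage}: " + ", ".join(f"{k}={v}" for k, v in info.items())
        log_lines.append(line)
        logger.info(line)

    # ---------------- stage 1: simulate ----------------
    stage = "simulate"
    try:
        ecfg = cfg["expression"]
        comparisons = [f"murine_{i+1}" for i in range(ecfg["n_murine"])] + [ecfg["human_comparison"]]
        datasets = {}
        truths = {}
        for i, comp in enumerate(comparisons):
            ds, truth = simulate_expression(
                n_genes=ecfg["n_genes"], n_case=ecfg["n_case"], n_control=ecfg["n_control"],
                planted_set_size=ecfg["planted_set_size"], effect=ecfg["effect"],
                noise_sd=ecfg["noise_sd"], seed=_stage_seed(seed, 100 + i),
            )
            datasets[comp] = ds
            truths[comp] = truth
            write_expression(ds.to_frame(), out / f"expr_{comp}.tsv")
            write_cls(ds.phenotype, out / f"expr_{comp}.cls")
        genes = datasets[comparisons[0]].gene_ids
        planted = sorted(truths[comparisons[0]].planted_set)

        gcfg = cfg["gsea"]
        rng = np.random.default_rng(_stage_seed(seed, 7))
        gene_sets = [GeneSet("UPR_SYNTH", "planted coordinately shifted set", frozenset(planted))]
        for d in range(gcfg["n_decoy_sets"]):
            members = rng.choice(genes, size=min(gcfg["decoy_set_size"], len(genes)), replace=False)
            gene_sets.append(GeneSet(f"DECOY_{d+1}", "random background set", frozenset(members)))
        write_gmt(gene_sets, out / "gene_sets.gmt")

        pcfg = cfg["promoters"]
        promoters, motif_truth = simulate_promoters(
            n_genes=len(genes),
            motif_rates={"UPRE": pcfg["upre_rate"], "ERSE-I": pcfg["erse1_rate"], "ERSE-II": pcfg["erse2_rate"]},
            seed=_stage_seed(seed, 11),
            boosted_genes=planted,
            boosted_rates={"UPRE": pcfg["boosted_upre_rate"]},
        )
        motif_scan.write_promoters_fasta(promoters, out / "promoters.fasta")

        ccfg = cfg["cag"]
        series, cag_truth = simulate_cag_series(
            replicates=ccfg["replicates"], effect=ccfg["effect"], noise_sd=ccfg["noise_sd"],
            seed=_stage_seed(seed, 13), gene_ids=genes,
            planted_pos=planted[: len(planted) // 2], planted_neg=(),
        )
        fpkm = pd.DataFrame(series.fpkm, index=series.gene_ids, columns=series.sample_ids)
        write_expression(fpkm, out / "cag_fpkm.tsv")
        pd.DataFrame({"sample": series.sample_ids, "cag": series.cag.astype(int)}).to_csv(
            out / "cag_samples.tsv", sep="\t", index=False)

        ncfg = cfg["network"]
        edges, annotations, net_truth = simulate_network(
            n_nodes=ncfg["n_nodes"], n_edges=ncfg["n_edges"],
            planted_apoptosis_overlap=ncfg["apoptosis_overlap"],
            planted_htt_overlap=ncfg["htt_overlap"], seed=_stage_seed(seed, 17),
        )
        pd.DataFrame(edges, columns=["geneA", "geneB"]).to_csv(out / "edges.tsv", sep="\t", index=False)
        for name, members in annotations.items():
            (out / f"annot_{name}.txt").write_text("\n".join(sorted(members)) + "\n")

        # gene-namespace membership lists for tri-set prioritization
        prcfg = cfg["prioritize"]
        rng_p = np.random.default_rng(_stage_seed(seed, 19))
        non_planted = [g for g in genes if g not in set(planted)]
        hdtt = sorted(set(planted) | set(rng_p.choice(non_planted, size=min(prcfg["n_hdtt_decoys"], len(non_planted)), replace=False)))
        htt_pool = sorted(rng_p.choice(planted, size=min(prcfg["n_httint"], len(planted)), replace=False))
        htt_types = {g: ("direct" if i < prcfg["n_direct"] else "indirect") for i, g in enumerate(htt_pool)}
        (out / "hdtt.txt").write_text("\n".join(hdtt) + "\n")
        pd.DataFrame(sorted(htt_types.items()), columns=["gene", "interaction_type"]).to_csv(
            out / "htt_interactors.tsv", sep="\t", index=False)

        truth_rows = []
        for comp, truth in truths.items():
            for r in truth.to_records():
                truth_rows.append({"dataset": comp, **r})
        for label, truth in (("promoters", motif_truth), ("cag", cag_truth), ("network", net_truth)):
            for r in truth.to_records():
                truth_rows.append({"dataset": label, **r})
        pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
        log_stage(stage, comparisons=len(comparisons), genes=len(genes), planted=len(planted))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    for f in sorted(out.glob("*")):
        if f.is_file():
            manifest["inputs"][f.name] = _sha256(f)

    # ---------------- stage 2: per-comparison enrichment ----------------
    stage = "gsea"
    try:
        leading_up: dict[str, set[str]] = {}
        for i, comp in enumerate(comparisons):
            results = gsea_core.gsea(
                datasets[comp], gene_sets, metric=gcfg["metric"],
                n_perm=gcfg["n_perm"], seed=_stage_seed(seed, 200 + i),
            )
            gsea_core.results_to_frame(results).to_csv(out / f"gsea_{comp}.tsv", sep="\t", index=False)
            for r in results:
                if r.set_name == "UPR_SYNTH" and r.direction == "up":
                    leading_up[comp] = set(r.leading_edge)
        log_stage(stage, comparisons=len(comparisons), upregulated=len(leading_up))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---------------- stage 3: consensus signature ----------------
    stage = "consensus"
    try:
        human = ecfg["human_comparison"]
        required = (human,) if human in leading_up else ()
        min_support = min(cfg["consensus"]["min_support"], max(len(leading_up) - len(required), 0))
        if leading_up:
            sig = consensus.consensus_signature(leading_up, required=required, min_support=min_support, direction="up")
        else:
            sig = consensus.ConsensusSignature(direction="up", genes=frozenset())
        sig.to_frame().to_csv(out / "consensus_up.tsv", sep="\t", index=False)
        log_stage(stage, genes=len(sig.genes), required=list(required), min_support=min_support)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---------------- stage 4: promoter scan + enrichment ----------------
    stage = "motif_scan"
    try:
        table = motif_scan.presence_table(promoters)
        table.counts.to_csv(out / "motif_counts.tsv", sep="\t", index_label="gene")
        table.hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        enr = enrichment_stats.motif_enrichment(table.presence, sig.genes)
        enr.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
        log_stage(stage, promoters=len(promoters), consensus_genes=len(sig.genes))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---------------- stage 5: CAG correlation ----------------
    stage = "cag_correlation"
    try:
        corr = cag_correlation.permutation_fdr(
            series, n_perm=ccfg["n_perm"], seed=_stage_seed(seed, 23), fdr_threshold=ccfg["fdr"])
        corr.to_csv(out / "cag_correlation.tsv", sep="\t", index=False)
        significant = corr.loc[corr["significant_pos"], "gene"]
        p_over = cag_correlation.set_overrepresentation(significant, planted, genes)
        (out / "cag_overrepresentation.tsv").write_text(f"target\tp\nUPR_SYNTH\t{p_over:.6g}\n")
        log_stage(stage, significant_pos=int(corr["significant_pos"].sum()), fisher_p=f"{p_over:.3g}")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---------------- stage 6: network + tri-set prioritization ----------------
    stage = "network_prioritize"
    try:
        net = network_prioritize.build_interactome(edges)
        network_prioritize.write_sif(net, out / "interactome.sif")
        _, n_apop = network_prioritize.overlay_annotation(net, annotations["apoptosis"])
        cross = network_prioritize.cross_annotation(
            net, annotations["apoptosis"],
            {g: "indirect" for g in annotations["htt_interactors"]})
        cross.to_csv(out / "apoptosis_htt_cross.tsv", sep="\t", index=False)
        prio = network_prioritize.triset_prioritize(sig, hdtt, htt_types, table, corr)
        prio.to_csv(out / "prioritization.tsv", sep="\t", index=False)
        log_stage(stage, interactome_nodes=len(net), apoptosis_in_net=n_apop,
                  apoptosis_htt=len(cross), prioritized=len(prio))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return out
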