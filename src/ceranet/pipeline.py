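"""End-to-end orchestration: dea -> cerna -> netprio -> tfnet -> deconv -> markers.

A single :class:`PipelineConfig` (flat YAML or JSON) names every input
file and stage parameter; defaults are the published thresholds
(|log2FC| > 1.5, p < 0.01, n_perm 1000, rho > 0.6, Pe < 0.01, restart
0.7, top-30 hubs, TF |rho| >= 0.5 / p < 0.05, top-3 drivers). One global
seed deterministically derives per-stage substreams, so re-running a
stage from saved intermediates reproduces the full run bit-for-bit.
Missing optional inputs (e.g. no signature matrix) skip their stage with
a log entry; any other stage failure aborts with the stage name and
cause. A manifest records input hashes, parameters, package version and
seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cerna import CeRNATripletAssembler, triplets_to_frame
from .data_model import (
    DataModelError,
    read_expression,
    read_gmt,
    read_groups,
    read_interactions,
)
from .dea import differential_expression, write_de_table
from .deconv import SignatureDeconvolver, compare_fractions
from .markers import auc_table, enrich
from .netprio import RandomWalkRestart, build_network, extract_hub_subnets
from .tfnet import TFNetworkBuilder, edges_to_frame
from .data_model import SignatureMatrix

__all__ = ["PipelineConfig", "PipelineError", "run_all", "PAPER_DEFAULTS"]

PAPER_DEFAULTS = {
    "lfc": 1.5,
    "pval": 0.01,
    "moderation": True,
    "n_perm": 1000,
    "rho": 0.6,
    "pe": 0.01,
    "restart": 0.7,
    "topk": 30,
    "tf_rho": 0.5,
    "tf_pval": 0.05,
    "top_drivers": 3,
}

STAGES = ("dea", "cerna", "netprio", "tfnet", "deconv", "markers")


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and cause."""


@dataclass
class PipelineConfig:
    expr_rna: str = ""
    groups_rna: str = ""
    expr_mir: str = ""
    groups_mir: str = ""
    interactions: str = ""
    seed_genes: str = ""          # GMT; union of sets = RWR seeds
    immune_genes: str = ""        # GMT; union of sets = TF-network restriction
    bulk: str = ""                # optional
    signature: str = ""           # optional
    groups_bulk: str = ""         # optional
    gene_sets: str = ""           # optional GMT for enrichment
    outdir: str = "ceranet_out"
    seed: int = 0
    params: dict = field(default_factory=lambda: dict(PAPER_DEFAULTS))

    def __post_init__(self) -> None:
        merged = dict(PAPER_DEFAULTS)
        merged.update(self.params or {})
        self.params = merged
        p = self.params
        for key in ("lfc", "rho", "tf_rho"):
            if p[key] < 0:
                raise ValueError(f"{key} must be >= 0")
        for key in ("pval", "pe", "tf_pval"):
            if not (0 <= p[key] <= 1):
                raise ValueError(f"{key} must be in [0, 1]")
        if not (0 < p["restart"] <= 1):
            raise ValueError("restart must be in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def stage_seed(self, stream: int) -> int:
        return int(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
            .generate_state(1)[0]
            % (2**31)
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = cfg.params
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "params": dict(p),
        "inputs": {},
        "stages": {},
    }
    report: list[str] = []
    for key in (
        "expr_rna", "groups_rna", "expr_mir", "groups_mir", "interactions",
        "seed_genes", "immune_genes", "bulk", "signature", "groups_bulk",
        "gene_sets",
    ):
        path = getattr(cfg, key)
        if path and Path(path).exists():
            manifest["inputs"][key] = _sha256(path)

    def fail(stage: str, exc: Exception):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # ---- dea ---------------------------------------------------------------
    try:
        expr_rna = read_expression(cfg.expr_rna)
        design_rna = read_groups(cfg.groups_rna)
        expr_mir = read_expression(cfg.expr_mir)
        design_mir = read_groups(cfg.groups_mir)
        de_rna = differential_expression(
            expr_rna, design_rna, p["moderation"], p["lfc"], p["pval"]
        )
        de_mir = differential_expression(
            expr_mir, design_mir, p["moderation"], p["lfc"], p["pval"]
        )
        write_de_table(de_rna, out / "de_rna.tsv")
        write_de_table(de_mir, out / "de_mir.tsv")
    except (OSError, ValueError, DataModelError) as exc:
        fail("dea", exc)
    n_de_rna = int((de_rna["direction"] != "ns").sum())
    n_de_mir = int((de_mir["direction"] != "ns").sum())
    manifest["stages"]["dea"] = {
        "status": "completed", "n_de_rna": n_de_rna, "n_de_mir": n_de_mir,
    }
    report.append(f"dea: {n_de_rna} DE RNA features, {n_de_mir} DE miRNAs")

    # ---- cerna -------------------------------------------------------------
    try:
        interactions = read_interactions(cfg.interactions)
        assembler = CeRNATripletAssembler(
            n_perm=p["n_perm"], rho_min=p["rho"], pe_max=p["pe"],
            random_state=cfg.stage_seed(1),
        ).fit(expr_rna, de_rna, de_mir, interactions)
        triplets = assembler.triplets_
        triplets_to_frame(triplets).to_csv(out / "triplets.tsv", sep="\t", index=False)
    except (OSError, ValueError, DataModelError) as exc:
        fail("cerna", exc)
    manifest["stages"]["cerna"] = {"status": "completed", "n_triplets": len(triplets)}
    report.append(f"cerna: {len(triplets)} triplets")

    # ---- netprio -----------------------------------------------------------
    hubs: set[str] = set()
    if not triplets:
        manifest["stages"]["netprio"] = {
            "status": "skipped", "reason": "empty ceRNA network (no triplets)",
        }
        report.append("netprio: skipped (empty ceRNA network)")
    else:
        try:
            seeds = sorted(
                {g for name in read_gmt(cfg.seed_genes).names()
                 for g in read_gmt(cfg.seed_genes)[name]}
            )
            net = build_network(triplets)
            rwr = RandomWalkRestart(
                restart_prob=p["restart"], top_k=p["topk"]
            ).fit(net, seeds)
            hubs = rwr.hubs_
            rwr.probabilities_.loc[rwr.ranking_].to_csv(out / "rwr_ranking.tsv", sep="\t")
            subnets = extract_hub_subnets(triplets, rwr)
            rows = []
            for i, comp in enumerate(subnets, start=1):
                for t in comp:
                    rows.append((i, t.lncrna, t.mirna, t.mrna))
            pd.DataFrame(
                rows, columns=["subnet", "lncrna", "mirna", "mrna"]
            ).to_csv(out / "hub_subnets.tsv", sep="\t", index=False)
        except (OSError, ValueError, DataModelError) as exc:
            fail("netprio", exc)
        manifest["stages"]["netprio"] = {
            "status": "completed",
            "n_hubs": len(hubs),
            "n_subnets": len(subnets),
            "n_iter": rwr.n_iter_,
        }
        report.append(f"netprio: {len(hubs)} hubs, {len(subnets)} hub subnets")

    # ---- tfnet -------------------------------------------------------------
    try:
        immune = sorted(
            {g for name in read_gmt(cfg.immune_genes).names()
             for g in read_gmt(cfg.immune_genes)[name]}
        )
        builder = TFNetworkBuilder(
            rho_min=p["tf_rho"], p_max=p["tf_pval"], top_n=p["top_drivers"]
        ).fit(de_rna, expr_rna, interactions, immune)
        edges_to_frame(builder.edges_).to_csv(out / "tf_edges.tsv", sep="\t", index=False)
        pd.Series(builder.drivers_, name="driver_tf").to_csv(
            out / "drivers.tsv", sep="\t", index=False
        )
    except (OSError, ValueError, DataModelError) as exc:
        fail("tfnet", exc)
    manifest["stages"]["tfnet"] = {
        "status": "completed",
        "n_edges": len(builder.edges_),
        "drivers": list(builder.drivers_),
    }
    report.append(f"tfnet: {len(builder.edges_)} edges, drivers {builder.drivers_}")

    # ---- deconv ------------------------------------------------------------
    if not (cfg.bulk and cfg.signature):
        manifest["stages"]["deconv"] = {
            "status": "skipped", "reason": "no bulk/signature input",
        }
        report.append("deconv: skipped (no bulk/signature input)")
    else:
        try:
            bulk = read_expression(cfg.bulk)
            sig = SignatureMatrix(
                pd.read_csv(cfg.signature, sep="\t", index_col=0)
            )
            dec = SignatureDeconvolver().fit(sig)
            fractions = dec.transform(bulk)
            fractions.to_csv(out / "fractions.tsv", sep="\t")
            n_cmp = 0
            if cfg.groups_bulk:
                cmp_tab = compare_fractions(fractions, read_groups(cfg.groups_bulk))
                cmp_tab.to_csv(out / "fraction_comparison.tsv", sep="\t")
                n_cmp = len(cmp_tab)
        except (OSError, ValueError, DataModelError) as exc:
            fail("deconv", exc)
        manifest["stages"]["deconv"] = {
            "status": "completed",
            "n_samples": fractions.shape[0],
            "n_cell_types": fractions.shape[1],
            "n_compared": n_cmp,
        }
        report.append(f"deconv: {fractions.shape[0]} samples x {fractions.shape[1]} types")

    # ---- markers -----------------------------------------------------------
    try:
        if hubs:
            feats_rna = [f for f in expr_rna.feature_ids if f in hubs]
            feats_mir = [f for f in expr_mir.feature_ids if f in hubs]
        else:
            feats_rna = de_rna.nsmallest(10, "p_value").index.tolist()
            feats_mir = de_mir.nsmallest(5, "p_value").index.tolist()
        roc = pd.concat(
            [
                auc_table(expr_rna, design_rna, feats_rna),
                auc_table(expr_mir, design_mir, feats_mir),
            ]
        )
        roc.to_csv(out / "roc.tsv", sep="\t")
        n_enriched = 0
        if cfg.gene_sets:
            de_genes = de_rna.index[
                (de_rna["direction"] != "ns")
                & (expr_rna.feature_class == "mRNA").reindex(de_rna.index, fill_value=False)
            ].tolist()
            background = expr_rna.features_of_class("mRNA")
            enr = enrich(de_genes, read_gmt(cfg.gene_sets), background)
            enr.to_csv(out / "enrichment.tsv", sep="\t")
            n_enriched = len(enr)
    except (OSError, ValueError, DataModelError) as exc:
        fail("markers", exc)
    manifest["stages"]["markers"] = {
        "status": "completed", "n_roc": len(roc), "n_sets": n_enriched,
    }
    report.append(f"markers: {len(roc)} ROC summaries, {n_enriched} gene sets tested")

    manifest["n_completed"] = sum(
        1 for s in manifest["stages"].values() if s["status"] == "completed"
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return manifest
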