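"""Synthetic two-series transcriptome data with planted, recoverable structure.

The generator emulates the study design the pipeline targets: two
microarray-style log2-intensity matrices with *disjoint* sample sets
(mRNA+lncRNA profiled in one series, miRNA in another), database-style
miRNA-target and TF-target edge lists, a disease seed-gene list, an
immunosuppressive-related gene list, and linear-scale bulk mixtures of a
cell-type signature. Every planted element is recorded in a
:class:`GroundTruth` so each downstream stage has an exact answer key.

Model
-----
Background feature g: x_gs ~ Normal(mu_g, sigma^2) iid across samples,
mu_g ~ Normal(8, 2^2) drawn once per feature. Planted differential
features add +/- delta to case samples (default delta 2.5, sigma 0.5,
10 vs 10 samples in the RNA series, 12 vs 11 in the miRNA series). A
planted ceRNA triplet (L, M, R) makes the miRNA M differential in one
direction, the mRNA R in the other, and copies R's row into L with a
Normal(0, 0.1^2) perturbation, so the lncRNA-mRNA pair is strongly
co-expressed. Planted hub TFs are differential mRNA features whose
targets' rows are the TF row (possibly sign-flipped around its mean) plus
noise, giving |rho| well above the 0.5 gate. Because the two series share
no samples, miRNA-target co-expression is deliberately not computable -
only direction opposition links the series, as in real two-series data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionMatrix,
    GroupDesign,
    InteractionTable,
    SignatureMatrix,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_interactions",
    "simulate_mixtures",
    "simulate_all",
]


@dataclass
class SimulationConfig:
    seed: int = 0
    # RNA (mRNA+lncRNA) series
    n_case: int = 10
    n_control: int = 10
    # miRNA series (disjoint samples)
    n_case_mir: int = 12
    n_control_mir: int = 11
    n_mrna: int = 400
    n_lncrna: int = 400
    n_mirna: int = 80
    # free-standing planted DE features per class (beyond triplet/TF members)
    n_planted_de_mrna: int = 30
    n_planted_de_lncrna: int = 30
    n_planted_de_mirna: int = 5
    delta: float = 2.5          # planted log2 effect size
    sigma: float = 0.5          # residual noise sd (log2 scale)
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    coexpr_noise_sd: float = 0.1  # lncRNA copy perturbation within a triplet
    n_planted_triplets: int = 20
    n_decoy_interactions: int = 200
    # TF network structure
    n_planted_hub_tfs: int = 3
    targets_per_hub_tf: int = 12
    tf_noise_sd: float = 0.5
    n_decoy_tfs: int = 50
    targets_per_decoy_tf: int = 4
    n_extra_immune_genes: int = 60
    # mixture / deconvolution design
    n_cell_types: int = 5
    n_markers_per_type: int = 20
    n_mix_samples: int = 20
    mixture_noise_frac: float = 0.05  # noise sd as a fraction of mean clean signal

    def validate(self) -> None:
        counts = {
            k: v
            for k, v in asdict(self).items()
            if k.startswith("n_") or k.startswith("targets_")
        }
        for k, v in counts.items():
            if v < 0:
                raise ValueError(f"{k} must be >= 0, got {v}")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        t = self.n_planted_triplets
        if t + self.n_planted_de_lncrna > self.n_lncrna:
            raise ValueError("planted lncRNA structure exceeds n_lncrna")
        if t + self.n_planted_de_mirna > self.n_mirna:
            raise ValueError("planted miRNA structure exceeds n_mirna")
        n_tf_block = self.n_planted_hub_tfs * (1 + self.targets_per_hub_tf)
        if t + self.n_planted_de_mrna + n_tf_block > self.n_mrna:
            raise ValueError("planted mRNA structure exceeds n_mrna")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        )


@dataclass
class GroundTruth:
    """Answer key for every planted element."""

    de_rna: dict[str, str] = field(default_factory=dict)      # feature -> up|down
    de_mir: dict[str, str] = field(default_factory=dict)
    triplets: list[tuple[str, str, str]] = field(default_factory=list)  # (L, M, R)
    hub_nodes: list[str] = field(default_factory=list)
    hub_tfs: list[str] = field(default_factory=list)
    tf_targets: dict[str, list[str]] = field(default_factory=dict)
    decoy_tfs: list[str] = field(default_factory=list)
    decoy_tf_targets: dict[str, list[str]] = field(default_factory=dict)
    immunosuppressive_genes: list[str] = field(default_factory=list)
    fractions: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        d = {
            "de_rna": self.de_rna,
            "de_mir": self.de_mir,
            "triplets": [list(t) for t in self.triplets],
            "hub_nodes": self.hub_nodes,
            "hub_tfs": self.hub_tfs,
            "tf_targets": self.tf_targets,
            "decoy_tfs": self.decoy_tfs,
            "decoy_tf_targets": self.decoy_tf_targets,
            "immunosuppressive_genes": self.immunosuppressive_genes,
            "fractions": None
            if self.fractions is None
            else self.fractions.to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _sample_ids(prefix: str, n_case: int, n_control: int) -> tuple[list[str], GroupDesign]:
    case = [f"{prefix}_case{i + 1:02d}" for i in range(n_case)]
    ctrl = [f"{prefix}_ctrl{i + 1:02d}" for i in range(n_control)]
    design = GroupDesign(
        pd.Series(["case"] * n_case + ["control"] * n_control, index=case + ctrl)
    )
    return case + ctrl, design


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroupDesign, GroupDesign, GroundTruth]:
    """Generate the two expression series and the ground truth.

    Returns (rna_matrix, mirna_matrix, rna_design, mirna_design, truth);
    the two matrices have disjoint sample id sets.
    """
    cfg.validate()
    rng = cfg.rng(0)
    truth = GroundTruth()

    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(cfg.n_lncrna)]
    mir_ids = [f"MIR{i + 1:04d}" for i in range(cfg.n_mirna)]

    rna_samples, rna_design = _sample_ids("R", cfg.n_case, cfg.n_control)
    mir_samples, mir_design = _sample_ids("M", cfg.n_case_mir, cfg.n_control_mir)
    n_rna, n_mir = len(rna_samples), len(mir_samples)
    case_mask_rna = np.array([s.startswith("R_case") for s in rna_samples])
    case_mask_mir = np.array([s.startswith("M_case") for s in mir_samples])

    def background(ids, n_samp):
        mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(ids))
        return mu[:, None] + rng.normal(0.0, cfg.sigma, size=(len(ids), n_samp))

    rna_ids = mrna_ids + lnc_ids
    rna_vals = background(rna_ids, n_rna)
    mir_vals = background(mir_ids, n_mir)
    rna = pd.DataFrame(rna_vals, index=rna_ids, columns=rna_samples)
    mir = pd.DataFrame(mir_vals, index=mir_ids, columns=mir_samples)

    def plant(df, feature, case_mask, direction):
        off = cfg.delta if direction == "up" else -cfg.delta
        df.loc[feature, np.asarray(case_mask)] += off

    # --- planted triplets: M opposes L and R; L copies R's row -------------
    t = cfg.n_planted_triplets
    trip_m = mir_ids[:t]
    trip_l = lnc_ids[:t]
    trip_r = mrna_ids[:t]
    for L, M, R in zip(trip_l, trip_m, trip_r):
        mdir = "up" if rng.random() < 0.5 else "down"
        tdir = "down" if mdir == "up" else "up"
        plant(mir, M, case_mask_mir, mdir)
        plant(rna, R, case_mask_rna, tdir)
        rna.loc[L] = rna.loc[R].to_numpy() + rng.normal(0.0, cfg.coexpr_noise_sd, n_rna)
        truth.de_mir[M] = mdir
        truth.de_rna[R] = tdir
        truth.de_rna[L] = tdir
        truth.triplets.append((L, M, R))
    truth.hub_nodes = sorted({x for tr in truth.triplets for x in tr})

    # --- planted hub TFs and their targets ---------------------------------
    ntf = cfg.n_planted_hub_tfs
    ktf = cfg.targets_per_hub_tf
    pos = t  # next free mRNA slot
    for j in range(ntf):
        tf = mrna_ids[pos]
        pos += 1
        tdir = "up" if rng.random() < 0.5 else "down"
        plant(rna, tf, case_mask_rna, tdir)
        truth.de_rna[tf] = tdir
        truth.hub_tfs.append(tf)
        targets = mrna_ids[pos : pos + ktf]
        pos += ktf
        tf_row = rna.loc[tf].to_numpy()
        center = tf_row.mean()
        for i, tgt in enumerate(targets):
            sign = -1.0 if i % 3 == 2 else 1.0  # a third of targets repressed
            base = rna.loc[tgt].to_numpy().mean()
            rna.loc[tgt] = (
                base
                + sign * (tf_row - center)
                + rng.normal(0.0, cfg.tf_noise_sd, n_rna)
            )
            truth.de_rna[tgt] = tdir if sign > 0 else ("down" if tdir == "up" else "up")
        truth.tf_targets[tf] = list(targets)

    # --- free-standing planted DE -------------------------------------------
    for ids_pool, count, df, mask, book in (
        (mrna_ids[pos:], cfg.n_planted_de_mrna, rna, case_mask_rna, truth.de_rna),
        (lnc_ids[t:], cfg.n_planted_de_lncrna, rna, case_mask_rna, truth.de_rna),
        (mir_ids[t:], cfg.n_planted_de_mirna, mir, case_mask_mir, truth.de_mir),
    ):
        for feat in ids_pool[:count]:
            d = "up" if rng.random() < 0.5 else "down"
            plant(df, feat, mask, d)
            book[feat] = d

    # --- decoy TFs and the immunosuppressive-related list -------------------
    unused = [m for m in mrna_ids[pos + cfg.n_planted_de_mrna :]]
    decoys = list(rng.choice(unused, size=min(cfg.n_decoy_tfs, len(unused)), replace=False))
    truth.decoy_tfs = [str(d) for d in decoys]
    all_targets = [m for m in mrna_ids if m not in truth.decoy_tfs]
    for dtf in truth.decoy_tfs:
        tgt = rng.choice(
            [m for m in all_targets if m != dtf],
            size=cfg.targets_per_decoy_tf,
            replace=False,
        )
        truth.decoy_tf_targets[dtf] = [str(x) for x in tgt]

    immune = set(truth.hub_tfs)
    for tf in truth.hub_tfs:
        immune.update(truth.tf_targets[tf])
    extra_pool = [m for m in mrna_ids if m not in immune]
    n_extra = min(cfg.n_extra_immune_genes, len(extra_pool))
    immune.update(str(x) for x in rng.choice(extra_pool, size=n_extra, replace=False))
    truth.immunosuppressive_genes = sorted(immune)

    classes = pd.Series(
        ["mRNA"] * cfg.n_mrna + ["lncRNA"] * cfg.n_lncrna, index=rna_ids
    )
    em_rna = ExpressionMatrix(rna, classes)
    em_mir = ExpressionMatrix(mir, pd.Series(["miRNA"] * cfg.n_mirna, index=mir_ids))
    return em_rna, em_mir, rna_design, mir_design, truth


def simulate_interactions(cfg: SimulationConfig, truth: GroundTruth) -> InteractionTable:
    """Emit miRNA-target and TF-target edges: planted structure plus decoys."""
    cfg.validate()
    rng = cfg.rng(1)
    rows: list[tuple[str, str, str, str, str]] = []
    for L, M, R in truth.triplets:
        rows.append((M, L, "miRNA", "lncRNA", "planted"))
        rows.append((M, R, "miRNA", "mRNA", "planted"))
    planted = {(r[0], r[1]) for r in rows}

    mir_ids = [f"MIR{i + 1:04d}" for i in range(cfg.n_mirna)]
    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(cfg.n_lncrna)]
    n_added, guard = 0, 0
    while n_added < cfg.n_decoy_interactions and guard < 50 * (cfg.n_decoy_interactions + 1):
        guard += 1
        m = str(rng.choice(mir_ids))
        if rng.random() < 0.5:
            tgt, tcls = str(rng.choice(lnc_ids)), "lncRNA"
        else:
            tgt, tcls = str(rng.choice(mrna_ids)), "mRNA"
        if (m, tgt) in planted:
            continue
        planted.add((m, tgt))
        rows.append((m, tgt, "miRNA", tcls, "decoy"))
        n_added += 1

    for tf in truth.hub_tfs:
        for tgt in truth.tf_targets.get(tf, []):
            rows.append((tf, tgt, "TF", "mRNA", "plantedTF"))
    for tf in truth.decoy_tfs:
        for tgt in truth.decoy_tf_targets.get(tf, []):
            rows.append((tf, tgt, "TF", "mRNA", "decoyTF"))

    return InteractionTable(
        pd.DataFrame(rows, columns=list(InteractionTable.COLUMNS))
    )


def simulate_mixtures(
    cfg: SimulationConfig, fractions: np.ndarray | None = None
) -> tuple[ExpressionMatrix, SignatureMatrix, pd.DataFrame]:
    """Linear-scale bulk mixtures of a synthetic cell-type signature.

    bulk = signature @ fractions.T + Normal(0, noise_sd), truncated at 0;
    fractions are flat-Dirichlet per sample unless a fixed design is given.
    Returns (bulk, signature, true fraction matrix samples x cell types).
    """
    cfg.validate()
    rng = cfg.rng(2)
    k, mpt = cfg.n_cell_types, cfg.n_markers_per_type
    types = [f"CT{j + 1}" for j in range(k)]
    markers = [f"MK{i + 1:03d}" for i in range(k * mpt)]
    sig = rng.uniform(0.5, 2.0, size=(k * mpt, k))
    for j in range(k):
        sig[j * mpt : (j + 1) * mpt, j] = rng.uniform(8.0, 16.0, size=mpt)
    signature = SignatureMatrix(pd.DataFrame(sig, index=markers, columns=types))

    n = cfg.n_mix_samples
    if fractions is None:
        frac = rng.dirichlet(np.ones(k), size=n)
    else:
        frac = np.asarray(fractions, dtype=float)
        if frac.ndim != 2 or frac.shape[1] != k:
            raise ValueError("fixed fractions must be (n_samples, n_cell_types)")
        frac = frac / frac.sum(axis=1, keepdims=True)
        n = frac.shape[0]
    samples = [f"MIX{i + 1:02d}" for i in range(n)]
    clean = sig @ frac.T
    noise_sd = cfg.mixture_noise_frac * float(clean.mean())
    bulk = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    bulk = np.maximum(bulk, 0.0)
    em = ExpressionMatrix(
        pd.DataFrame(bulk, index=markers, columns=samples),
        pd.Series(["mRNA"] * len(markers), index=markers),
    )
    return em, signature, pd.DataFrame(frac, index=samples, columns=types)


def simulate_all(cfg: SimulationConfig):
    """Run all three generators; returns a dict of every pipeline input."""
    rna, mir, d_rna, d_mir, truth = simulate_expression(cfg)
    inter = simulate_interactions(cfg, truth)
    bulk, signature, frac = simulate_mixtures(cfg)
    truth.fractions = frac
    half = frac.shape[0] // 2
    if half >= 2 and frac.shape[0] - half >= 2:
        bulk_design = GroupDesign(
            pd.Series(
                ["case"] * half + ["control"] * (frac.shape[0] - half),
                index=frac.index,
            )
        )
    else:
        bulk_design = None
    return {
        "expr_rna": rna,
        "expr_mir": mir,
        "design_rna": d_rna,
        "design_mir": d_mir,
        "interactions": inter,
        "bulk": bulk,
        "signature": signature,
        "fractions": frac,
        "bulk_design": bulk_design,
        "truth": truth,
    }
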