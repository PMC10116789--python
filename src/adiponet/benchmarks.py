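"""Self-validation benchmarks: calibration and recovery studies.

Each function builds its own synthetic scenario from a seed, runs the
relevant pipeline stage, and returns summary metrics, so the package's
statistical calibration (type-I error), generator consistency, and
network-recovery performance can be recomputed from scratch at any time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import anni, synthetic
from .cohort_stats import compare_groups, two_way_anova
from .qpcr import quantify

__all__ = [
    "one_way_type1_rate",
    "two_way_type1_rate",
    "generator_consistency_error",
    "ct_roundtrip_error",
    "planted_recovery_scenario",
    "network_recovery_metrics",
    "anni_null_excess_fraction",
]


def one_way_type1_rate(
    seed: int, n_sims: int = 1000, n_per_group: int = 20
) -> float:
    """Empirical rejection rate of the routed 3-group comparison under the null."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(["a", "b", "c"], n_per_group)
    rejections = 0
    for _ in range(n_sims):
        values = rng.standard_normal(3 * n_per_group)
        rejections += compare_groups(values, labels).p_value < 0.05
    return rejections / n_sims


def two_way_type1_rate(seed: int, n_sims: int = 1000, n_per_cell: int = 8) -> float:
    """Empirical interaction rejection rate of two-way ANOVA under the null."""
    rng = np.random.default_rng(seed)
    a = np.repeat(["x", "y"], 2 * n_per_cell)
    b = np.tile(np.repeat(["u", "v"], n_per_cell), 2)
    rejections = 0
    for _ in range(n_sims):
        values = rng.standard_normal(4 * n_per_cell)
        res = two_way_anova(values, a, b)
        rejections += res.effects["interaction"]["p"] < 0.05
    return rejections / n_sims


def generator_consistency_error(seed: int, n: int = 5000) -> float:
    """Max |empirical - target| correlation entry on a size-n cohort.

    Targets apply on the latent scale: log for genes, linear for covariates.
    """
    cfg = synthetic.SyntheticConfig(
        n_lean=0, n_overweight=n, n_obese=0,
        group_shifts={"overweight": {}}, seed=seed,
    )
    expr, clin, truth = synthetic.generate_cohort(cfg)
    merged = pd.concat(
        [np.log(expr[cfg.genes]), clin[cfg.covariate_names]], axis=1
    )
    return float((merged.corr() - truth.correlation_targets).abs().to_numpy().max())


def ct_roundtrip_error(seed: int, n: int = 30) -> float:
    """Max relative error of noise-free Ct simulation -> quantification."""
    cfg = synthetic.SyntheticConfig(
        n_lean=n // 3, n_overweight=n // 3, n_obese=n - 2 * (n // 3),
        ct_noise_sd=0.0, ct_housekeeping_sd=0.0, seed=seed,
    )
    expr, _, _ = synthetic.generate_cohort(cfg)
    recovered = quantify(synthetic.generate_ct_plates(cfg, expr))
    a = recovered.set_index("sample_id")[cfg.genes].to_numpy()
    b = expr.set_index("sample_id")[cfg.genes].to_numpy()
    return float(np.abs(a / b - 1.0).max())


def planted_recovery_scenario(
    seed: int, n_samples: int = 150, n_genes: int = 15, edge_weight: float = 0.8
):
    """A gene panel with 5 strong planted edges on otherwise independent genes.

    Returns ``(expression, adjacency, genes)``; edges connect disjoint gene
    pairs with alternating signs, so the implied correlation structure is
    block-diagonal and the planted pairs are unambiguous.
    """
    genes = [f"G{i:02d}" for i in range(1, n_genes + 1)]
    adjacency = pd.DataFrame(0.0, index=genes, columns=genes)
    edges = [
        (genes[0], genes[1], edge_weight),
        (genes[2], genes[3], -edge_weight),
        (genes[4], genes[5], edge_weight),
        (genes[6], genes[7], -edge_weight),
        (genes[8], genes[9], edge_weight),
    ]
    for src, tgt, w in edges:
        adjacency.at[src, tgt] = w
    cfg = synthetic.SyntheticConfig(
        n_lean=0,
        n_overweight=n_samples,
        n_obese=0,
        bat_genes=genes[: n_genes // 2],
        inflammatory_genes=genes[n_genes // 2 :],
        covariate_scales={},
        target_correlation=synthetic.implied_correlation(adjacency),
        planted_network=adjacency,
        group_shifts={"overweight": {}},
        seed=seed,
    )
    expr, _, _ = synthetic.generate_cohort(cfg)
    return expr, adjacency, genes


def network_recovery_metrics(seed: int, mc_resamples: int = 50) -> dict:
    """Edge-recovery AUROC and top-5 hit count on the planted-edge panel.

    Scores each unordered gene pair by the larger |W| of its two directions
    (cross-sectional expression carries no directional information) and
    labels it positive when either direction is planted.
    """
    expr, adjacency, genes = planted_recovery_scenario(seed)
    cfg = anni.AnnConfig(mc_resamples=mc_resamples, hidden_units=3, seed=seed)
    im = anni.interaction_matrix(expr, cfg, genes=genes)
    scores, labels = [], []
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            scores.append(max(abs(im.W.at[gi, gj]), abs(im.W.at[gj, gi])))
            labels.append(
                int(adjacency.at[gi, gj] != 0 or adjacency.at[gj, gi] != 0)
            )
    top5 = anni.rank_interactions(im, top_k=5, undirected=True)
    planted_pairs = {
        frozenset((s, t))
        for s in genes
        for t in genes
        if adjacency.at[s, t] != 0
    }
    hits = sum(
        frozenset((e.source, e.target)) in planted_pairs
        for e in top5.itertuples()
    )
    signs_ok = sum(
        np.sign(im.W.at[s, t]) == np.sign(adjacency.at[s, t])
        for s in genes
        for t in genes
        if adjacency.at[s, t] != 0
    )
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "top5_planted_recovered": int(hits),
        "planted_sign_matches": int(signs_ok),
        "n_planted": len(planted_pairs),
        "interaction_matrix": im,
    }


def anni_null_excess_fraction(
    seed: int, n_genes: int = 8, n_samples: int = 100, mc_resamples: int = 15
) -> float:
    """Fraction of |W| entries above the permutation-null 95th percentile
    on fully independent genes (should stay near the nominal 5%)."""
    rng = np.random.default_rng(seed)
    genes = [f"N{i}" for i in range(n_genes)]
    expr = pd.DataFrame(rng.normal(size=(n_samples, n_genes)), columns=genes)
    cfg = anni.AnnConfig(mc_resamples=mc_resamples, seed=seed)
    im = anni.interaction_matrix(expr, cfg)
    threshold = anni.permutation_null_threshold(expr, cfg, n_permutations=3)
    mask = ~np.eye(n_genes, dtype=bool)
    return float((np.abs(im.W.to_numpy()[mask]) > threshold).mean())
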