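"""Neural-network gene-interaction inference (ANNi).

For every gene in a panel, a small single-hidden-layer feed-forward network
(sigmoid hidden units, linear output) is trained to predict that gene from
all the others, under Monte Carlo cross-validation: repeated random
train/validation/test splits with early stopping on validation error to
limit over-fitting.  The signed influence of predictor gene i on target
gene j is read off the trained weights as the composite input-to-output
weight

    c[i -> j] = sum_h W1[i, h] * w2[h]

(first-layer times second-layer weight, summed over hidden units), averaged
across resamples with the sign retained.  Collapsing the resulting
interaction matrix by row sums and column sums identifies the most
influential and the most influenced genes; ranked edges can be exported to
Cytoscape-readable SIF or GraphML.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnConfig",
    "InteractionMatrix",
    "fit_target_models",
    "interaction_matrix",
    "collapse_influence",
    "rank_interactions",
    "export_network",
    "permutation_null_threshold",
]


@dataclass
class AnnConfig:
    """Training and resampling configuration of the inference engine."""

    hidden_units: int = 3
    mc_resamples: int = 50
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    max_epochs: int = 600
    learning_rate: float = 0.02
    early_stop_patience: int = 60
    l2_penalty: float = 1e-4
    seed: int = 0
    scaling: str = "unit_interval"  # or "zscore"

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.mc_resamples < 2:
            raise ValueError("mc_resamples must be >= 2")
        fracs = tuple(float(f) for f in self.split_fractions)
        if len(fracs) != 3 or min(fracs) <= 0:
            raise ValueError("split_fractions must be three positive numbers")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        self.split_fractions = fracs
        if self.scaling not in ("unit_interval", "zscore"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclass
class InteractionMatrix:
    """Signed gene x gene influence weights averaged over MC resamples."""

    genes: list[str]
    W: pd.DataFrame  # W.loc[source, target]
    dispersion: pd.DataFrame  # across-resample standard deviations

    def __post_init__(self) -> None:
        if list(self.W.index) != self.genes or list(self.W.columns) != self.genes:
            raise ValueError("W must be indexed by the gene list on both axes")
        if np.any(np.diag(self.W.to_numpy()) != 0):
            raise ValueError("interaction matrix diagonal must be zero")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _train_mlp(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: AnnConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, int]:
    """Full-batch Adam training with early stopping on validation MSE.

    Returns (W1, b1, w2, b2-as-scalar ...) packed as
    ``(W1, w2, b1, b2, best_val_mse, epochs_run)``.
    """
    n, p = x_train.shape
    h = config.hidden_units
    w1 = rng.normal(0.0, 1.0 / math.sqrt(max(p, 1)), size=(p, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, 1.0 / math.sqrt(h), size=h)
    b2 = 0.0
    params = [w1, b1, w2, np.array([b2])]
    m_state = [np.zeros_like(q) for q in params]
    v_state = [np.zeros_like(q) for q in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    lam = config.l2_penalty

    def val_mse() -> float:
        hidden = _sigmoid(x_val @ params[0] + params[1])
        pred = hidden @ params[2] + params[3][0]
        return float(np.mean((pred - y_val) ** 2))

    best = [q.copy() for q in params]
    best_val = val_mse()
    since_best = 0
    epochs_run = 0
    for epoch in range(1, config.max_epochs + 1):
        epochs_run = epoch
        act = x_train @ params[0] + params[1]
        hidden = _sigmoid(act)
        pred = hidden @ params[2] + params[3][0]
        err = (pred - y_train) * (2.0 / n)
        g_w2 = hidden.T @ err + 2 * lam * params[2]
        g_b2 = np.array([err.sum()])
        d_hidden = np.outer(err, params[2]) * hidden * (1.0 - hidden)
        g_w1 = x_train.T @ d_hidden + 2 * lam * params[0]
        g_b1 = d_hidden.sum(axis=0)
        grads = [g_w1, g_b1, g_w2, g_b2]
        for q, m, v, g in zip(params, m_state, v_state, grads):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            m_hat = m / (1 - beta1**epoch)
            v_hat = v / (1 - beta2**epoch)
            q -= lr * m_hat / (np.sqrt(v_hat) + eps)
        current = val_mse()
        if current < best_val - 1e-12:
            best_val = current
            best = [q.copy() for q in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    w1, b1, w2, b2_arr = best
    return w1, w2, b1, float(b2_arr[0]), best_val, epochs_run


def _scale_columns(
    train: np.ndarray, other: np.ndarray, scaling: str
) -> tuple[np.ndarray, np.ndarray]:
    if scaling == "unit_interval":
        lo = train.min(axis=0)
        span = np.ptp(train, axis=0)
        span = np.where(span == 0, 1.0, span)
        return (train - lo) / span, (other - lo) / span
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


def _numeric_columns(expr: pd.DataFrame) -> list[str]:
    return [c for c in expr.columns if pd.api.types.is_numeric_dtype(expr[c])]


def fit_target_models(
    expr: pd.DataFrame,
    target_gene: str,
    config: AnnConfig,
    predictors: list[str] | None = None,
) -> list[dict]:
    """Fit the Monte Carlo ensemble of models predicting one target gene.

    Each resample draws a fresh train/validation/test split, scales
    predictors and target on the training fraction only, trains the network
    with early stopping, and records the learned weights and the
    test-fraction error.  Fully reproducible from ``config.seed``.
    """
    numeric = _numeric_columns(expr)
    if target_gene not in numeric:
        raise ValueError(f"target gene {target_gene!r} not in expression table")
    if predictors is None:
        predictors = [c for c in numeric if c != target_gene]
    predictors = list(predictors)
    keep = []
    for gene in predictors:
        if expr[gene].nunique() <= 1:
            warnings.warn(
                f"dropping zero-variance predictor {gene!r}", stacklevel=2
            )
        else:
            keep.append(gene)
    predictors = keep
    if len(predictors) < 2:
        raise ValueError("need at least 2 non-degenerate predictor genes")
    x_all = expr[predictors].to_numpy(dtype=float)
    y_all = expr[target_gene].to_numpy(dtype=float)
    n = x_all.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    f_train, f_val, _ = config.split_fractions
    n_train = max(2, int(round(f_train * n)))
    n_val = max(1, int(round(f_val * n)))
    if n_train + n_val >= n:
        raise ValueError("split leaves no test samples")
    target_idx = numeric.index(target_gene)
    seeds = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(target_idx,)
    ).spawn(config.mc_resamples)
    records = []
    for r, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        idx_train = perm[:n_train]
        idx_val = perm[n_train : n_train + n_val]
        idx_test = perm[n_train + n_val :]
        x_train, x_rest = _scale_columns(
            x_all[idx_train], x_all[perm[n_train:]], config.scaling
        )
        y_train, y_rest = _scale_columns(
            y_all[idx_train, None], y_all[perm[n_train:], None], config.scaling
        )
        x_val, x_test = x_rest[: len(idx_val)], x_rest[len(idx_val) :]
        y_val, y_test = (
            y_rest[: len(idx_val), 0],
            y_rest[len(idx_val) :, 0],
        )
        w1, w2, b1, b2, best_val, epochs = _train_mlp(
            x_train, y_train[:, 0], x_val, y_val, config, rng
        )
        pred = _sigmoid(x_test @ w1 + b1) @ w2 + b2
        sse = float(np.sum((pred - y_test) ** 2))
        sst = float(np.sum((y_test - y_test.mean()) ** 2))
        records.append(
            {
                "resample": r,
                "predictors": predictors,
                "w1": w1,
                "w2": w2,
                "test_mse": sse / max(len(y_test), 1),
                "test_r2": 1.0 - sse / sst if sst > 0 else float("nan"),
                "val_mse": best_val,
                "epochs": epochs,
            }
        )
    return records


def interaction_matrix(
    expr: pd.DataFrame,
    config: AnnConfig,
    genes: list[str] | None = None,
) -> InteractionMatrix:
    """Infer the signed interaction matrix over a gene panel.

    ``genes`` defaults to every numeric column; clinical covariates such as
    BMI or endotoxin can be included as pseudo-genes simply by leaving their
    columns in the table (they are treated identically to genes).
    """
    if genes is None:
        genes = _numeric_columns(expr)
    if len(genes) < 3:
        raise ValueError("interaction inference needs at least 3 genes")
    table = expr[
        [c for c in expr.columns if c not in genes] + list(genes)
    ]
    k = len(genes)
    w = np.zeros((k, k))
    disp = np.zeros((k, k))
    for j, target in enumerate(genes):
        try:
            records = fit_target_models(
                table, target, config, predictors=[g for g in genes if g != target]
            )
        except ValueError as exc:
            raise ValueError(f"model for target {target!r} failed: {exc}") from exc
        composites = np.stack([rec["w1"] @ rec["w2"] for rec in records])
        mean = composites.mean(axis=0)
        sd = composites.std(axis=0, ddof=1)
        preds = records[0]["predictors"]
        for gene, mu, s in zip(preds, mean, sd):
            i = genes.index(gene)
            w[i, j] = mu
            disp[i, j] = s
    w_df = pd.DataFrame(w, index=genes, columns=genes)
    d_df = pd.DataFrame(disp, index=genes, columns=genes)
    return InteractionMatrix(genes=list(genes), W=w_df, dispersion=d_df)


def collapse_influence(im: InteractionMatrix) -> pd.DataFrame:
    """Collapse the interaction matrix to per-gene influence summaries.

    influence_exerted(g) is the sum of weights out of g (row sum) and
    influence_received(g) the sum into g (column sum); both totals equal
    the grand sum of W.  Ranks run from most negative (rank 1, most
    suppressive) upward, ties broken by gene-name lexical order.
    """
    w = im.W.to_numpy(dtype=float)
    exerted = [math.fsum(row) for row in w]
    received = [math.fsum(col) for col in w.T]

    def ranks(values: list[float]) -> list[int]:
        order = sorted(range(len(values)), key=lambda i: (values[i], im.genes[i]))
        out = [0] * len(values)
        for pos, i in enumerate(order):
            out[i] = pos + 1
        return out

    return pd.DataFrame(
        {
            "gene": im.genes,
            "influence_exerted": exerted,
            "influence_received": received,
            "rank_exerted": ranks(exerted),
            "rank_received": ranks(received),
        }
    ).set_index("gene")


def rank_interactions(
    im: InteractionMatrix, top_k: int, undirected: bool = False
) -> pd.DataFrame:
    """Rank interactions by absolute averaged weight.

    Returns the ``top_k`` strongest edges with sign, magnitude, and
    across-resample dispersion; ties break on (source, target) lexical
    order.  With ``undirected=True`` the two directions of each gene pair
    are merged, keeping the direction with the larger magnitude — useful
    when the underlying data carry no directional information.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    rows = []
    for i, src in enumerate(im.genes):
        for j, tgt in enumerate(im.genes):
            if i == j:
                continue
            if undirected and src > tgt:
                continue
            weight = float(im.W.iat[i, j])
            disp = float(im.dispersion.iat[i, j])
            if undirected:
                back = float(im.W.at[tgt, src])
                if abs(back) > abs(weight):
                    weight = back
                    disp = float(im.dispersion.at[tgt, src])
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "weight": weight,
                    "sign": "+" if weight >= 0 else "-",
                    "magnitude": abs(weight),
                    "dispersion": disp,
                }
            )
    if top_k > len(rows):
        raise ValueError(f"top_k={top_k} exceeds the {len(rows)} available edges")
    rows.sort(key=lambda e: (-e["magnitude"], e["source"], e["target"]))
    return pd.DataFrame(rows[:top_k])


def export_network(edges: pd.DataFrame, path: str, fmt: str = "SIF") -> list[str]:
    """Write a ranked edge list as a Cytoscape-loadable network.

    ``SIF`` writes tab-separated ``source  influences_pos|influences_neg
    target`` lines plus a sidecar ``.edges.csv`` with weight and dispersion
    attributes; ``GraphML`` writes a directed graph with weight/sign/
    dispersion edge attributes.  Returns the list of files written.
    """
    if len(edges) == 0:
        raise ValueError("edge list is empty")
    fmt_norm = fmt.upper()
    if fmt_norm == "SIF":
        sif_path = path if path.endswith(".sif") else path + ".sif"
        with open(sif_path, "w") as fh:
            for _, e in edges.iterrows():
                rel = "influences_pos" if e["weight"] >= 0 else "influences_neg"
                fh.write(f"{e['source']}\t{rel}\t{e['target']}\n")
        attr_path = sif_path[: -len(".sif")] + ".edges.csv"
        edges.to_csv(attr_path, index=False)
        return [sif_path, attr_path]
    if fmt_norm == "GRAPHML":
        import networkx as nx

        graph = nx.DiGraph()
        for _, e in edges.iterrows():
            graph.add_edge(
                e["source"],
                e["target"],
                weight=float(e["weight"]),
                sign=str(e["sign"]),
                dispersion=float(e["dispersion"]),
            )
        gml_path = path if path.endswith(".graphml") else path + ".graphml"
        nx.write_graphml(graph, gml_path)
        return [gml_path]
    raise ValueError(f"unknown network format {fmt!r} (use 'SIF' or 'GraphML')")


def permutation_null_threshold(
    expr: pd.DataFrame,
    config: AnnConfig,
    genes: list[str] | None = None,
    n_permutations: int = 3,
    quantile: float = 0.95,
) -> float:
    """Null magnitude threshold from label-permuted data.

    Shuffles each gene column independently (destroying all inter-gene
    dependence while keeping marginals), re-runs the full inference, and
    returns the requested quantile of the pooled off-diagonal |W| entries.
    """
    if genes is None:
        genes = _numeric_columns(expr)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
    pooled = []
    for b in range(n_permutations):
        shuffled = expr.copy()
        for gene in genes:
            shuffled[gene] = rng.permutation(shuffled[gene].to_numpy())
        im = interaction_matrix(shuffled, config, genes=genes)
        vals = im.W.to_numpy()
        mask = ~np.eye(len(genes), dtype=bool)
        pooled.append(np.abs(vals[mask]))
    return float(np.quantile(np.concatenate(pooled), quantile))
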