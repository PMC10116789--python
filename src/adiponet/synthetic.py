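"""Synthetic cohort generator for adipose browning / inflammation studies.

Emulates the data structure of a BMI-stratified cross-sectional cohort
(lean / overweight / obese), a paired pre/post-bariatric-surgery subcohort,
and replicate-level qPCR plates, together with the ground truth needed to
test every downstream analysis stage (target correlations, group effects,
surgery effects, and a planted signed gene-interaction network).

Generation model
----------------
Variables (genes and clinical covariates) share a latent multivariate
standard-normal vector with a user-specified target correlation matrix
(Cholesky factorisation after a positive-semi-definite repair).  Group
membership adds per-variable mean offsets on the latent scale.  Gene
latents are scaled by ``noise_sd`` and exponentiated, giving skewed,
strictly positive relative-expression values whose *log-scale* correlations
match the targets; covariates are mapped linearly onto their natural
clinical scales.  Paired data couple post-minus-pre changes through the
same correlation matrix on the delta scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BAT_PANEL",
    "INFLAMMATORY_PANEL",
    "COVARIATE_SCALES",
    "GROUPS",
    "SyntheticConfig",
    "PlantedTruth",
    "repair_correlation",
    "default_target_correlation",
    "implied_correlation",
    "generate_cohort",
    "generate_paired",
    "generate_ct_plates",
]

#: Brown/BRITE adipocyte marker panel.
BAT_PANEL = ["UCP1", "PGC1A", "CIDEA", "ELOVL3", "PLIN5", "SLC27A2"]

#: Inflammatory marker panel.
INFLAMMATORY_PANEL = ["IL6", "MCP1", "TNFA", "IL1B", "CD14", "CD68", "IL10"]

GROUPS = ("lean", "overweight", "obese")

#: Natural-scale (mean, sd) of each clinical covariate in an unshifted
#: (roughly overweight) reference population.
COVARIATE_SCALES: dict[str, tuple[float, float]] = {
    "bmi": (27.0, 3.0),  # kg/m^2
    "endotoxin": (6.0, 1.8),  # EU/mL
    "glucose_mmol": (4.4, 1.0),  # mmol/L
    "insulin_pmol": (55.0, 15.0),  # pmol/L
    "total_cholesterol": (7.0, 0.9),  # mmol/L
    "hdl": (1.5, 0.3),  # mmol/L
    "tg": (3.0, 0.7),  # mmol/L
    "weight": (85.0, 12.0),  # kg
    "ideal_weight": (65.0, 5.0),  # kg
}

# Factor loadings generating the default target correlation.  Factor 1 is the
# adiposity-inflammation axis (browning genes high when BMI, endotoxin and
# inflammatory genes are low), factor 2 body size, factor 3 lipids.  A factor
# structure keeps the default matrix positive semi-definite by construction.
_DEFAULT_LOADINGS: dict[str, tuple[float, float, float]] = {
    **{g: (0.60, 0.0, 0.0) for g in BAT_PANEL},
    **{g: (-0.50, 0.0, 0.0) for g in INFLAMMATORY_PANEL},
    "bmi": (-0.65, 0.50, 0.0),
    "endotoxin": (-0.55, 0.0, 0.0),
    "glucose_mmol": (-0.45, 0.0, 0.0),
    "insulin_pmol": (-0.45, 0.0, 0.0),
    "total_cholesterol": (0.20, 0.0, 0.55),
    "hdl": (0.40, 0.0, 0.25),
    "tg": (-0.10, 0.0, 0.50),
    "weight": (-0.50, 0.60, 0.0),
    "ideal_weight": (0.0, 0.45, 0.0),
}

# Per-group latent mean shifts (unit-variance scale).  Covariate shifts place
# the group means at values typical of BMI-stratified cohorts; gene shifts
# encode lower browning-gene and higher inflammatory-gene expression with
# increasing adiposity.
_DEFAULT_GROUP_SHIFTS: dict[str, dict[str, float]] = {
    "lean": {
        "bmi": -1.62, "glucose_mmol": -0.82, "insulin_pmol": -1.01,
        "hdl": 0.80, "tg": 0.16, "total_cholesterol": 0.79,
        "weight": -0.80, "endotoxin": -0.50,
        **{g: 0.5 for g in BAT_PANEL},
        **{g: -0.5 for g in INFLAMMATORY_PANEL},
    },
    "overweight": {
        "bmi": 0.10, "glucose_mmol": -0.77, "insulin_pmol": 0.64,
        "hdl": 0.10, "tg": 0.37, "total_cholesterol": 0.72,
    },
    "obese": {
        "bmi": 3.12, "glucose_mmol": 1.52, "insulin_pmol": 0.53,
        "hdl": -0.50, "tg": -0.50, "total_cholesterol": -0.70,
        "weight": 0.90, "endotoxin": 0.60,
        **{g: -0.5 for g in BAT_PANEL},
        **{g: 0.5 for g in INFLAMMATORY_PANEL},
    },
}

# Latent baseline shifts of the bariatric-surgery subcohort (severely obese
# at baseline) and natural-scale post-minus-pre mean changes: endotoxin falls
# and browning-gene expression rises after surgery, alongside weight loss and
# glycaemic improvement.
_DEFAULT_PAIRED_BASELINE: dict[str, float] = {
    "bmi": 5.07, "glucose_mmol": 4.80, "insulin_pmol": -1.54,
    "hdl": -1.40, "tg": -1.67, "total_cholesterol": -2.23,
    "weight": 3.00, "endotoxin": 1.00,
    **{g: -0.5 for g in BAT_PANEL},
    **{g: 0.5 for g in INFLAMMATORY_PANEL},
}

_DEFAULT_SURGERY_EFFECT: dict[str, float] = {
    "endotoxin": -2.0, "bmi": -5.5, "weight": -15.0,
    "glucose_mmol": -2.26, "insulin_pmol": -14.7,
    "tg": -0.44, "total_cholesterol": -0.60, "hdl": -0.04,
    **{g: 0.4 for g in BAT_PANEL},
    **{g: -0.2 for g in INFLAMMATORY_PANEL},
}

_DEFAULT_DELTA_SD: dict[str, float] = {
    "endotoxin": 1.5, "bmi": 1.5, "weight": 4.0,
    "glucose_mmol": 1.0, "insulin_pmol": 8.0,
    "tg": 0.4, "total_cholesterol": 0.5, "hdl": 0.15, "ideal_weight": 0.0,
}
_DEFAULT_GENE_DELTA_SD = 0.3

_MIN_EXPRESSION = 1e-6
_PSD_REJECT_EIG = -1e-6
_PSD_CLIP_EIG = 1e-8


def repair_correlation(corr: pd.DataFrame) -> pd.DataFrame:
    """Validate and PSD-repair a target correlation matrix.

    Requires symmetry and a unit diagonal.  Slightly indefinite matrices
    (smallest eigenvalue >= -1e-6) are repaired by clipping eigenvalues at
    1e-8 and renormalising to unit diagonal; anything worse is rejected
    with the offending eigenvalue in the message.
    """
    mat = corr.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("target correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
        raise ValueError("target correlation matrix must have a unit diagonal")
    if np.any(np.abs(mat) > 1 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")
    eigvals, eigvecs = np.linalg.eigh(mat)
    if eigvals.min() < _PSD_REJECT_EIG:
        raise ValueError(
            "target correlation is not positive semi-definite: smallest "
            f"eigenvalue {eigvals.min():.3e} is below the repair tolerance"
        )
    if eigvals.min() >= _PSD_CLIP_EIG:
        return corr.astype(float)
    clipped = np.clip(eigvals, _PSD_CLIP_EIG, None)
    repaired = (eigvecs * clipped) @ eigvecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return pd.DataFrame(repaired, index=corr.index, columns=corr.columns)


def default_target_correlation(variables: list[str]) -> pd.DataFrame:
    """Factor-model default correlation over the given variables.

    Variables with known default loadings (study gene panels and clinical
    covariates) get the factor-implied correlations; unknown variables are
    uncorrelated with everything.
    """
    loadings = np.array(
        [_DEFAULT_LOADINGS.get(v, (0.0, 0.0, 0.0)) for v in variables]
    )
    corr = loadings @ loadings.T
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=variables, columns=variables)


def implied_correlation(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Correlation matrix implied by a signed linear network.

    Treats the adjacency as a linear structural model x = A^T x + e with
    unit-variance independent noise (A[i, j] is the effect of gene i on
    gene j), so planted edges become proportionally strong correlations.
    """
    genes = list(adjacency.index)
    a = adjacency.to_numpy(dtype=float)
    if np.any(np.diag(a) != 0):
        raise ValueError("planted network must have a zero diagonal")
    eye = np.eye(len(genes))
    try:
        b = np.linalg.inv(eye - a.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("planted network implies a singular system") from exc
    sigma = b @ b.T
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the emulated study: a BMI-stratified cohort of
    44 lean + 49 overweight + 63 obese participants, a paired surgery
    subcohort of 26, six browning genes negatively coupled to seven
    inflammatory genes, to BMI, and to serum endotoxin.
    """

    n_lean: int = 44
    n_overweight: int = 49
    n_obese: int = 63
    n_paired: int = 26
    bat_genes: list[str] = field(default_factory=lambda: list(BAT_PANEL))
    inflammatory_genes: list[str] = field(
        default_factory=lambda: list(INFLAMMATORY_PANEL)
    )
    covariate_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(COVARIATE_SCALES)
    )
    target_correlation: pd.DataFrame | None = None
    group_shifts: dict[str, dict[str, float]] | None = None
    planted_network: pd.DataFrame | None = None
    noise_sd: float = 0.5
    surgery_effect: dict[str, float] | None = None
    delta_sd: dict[str, float] | None = None
    paired_baseline_shift: dict[str, float] | None = None
    ct_noise_sd: float = 0.15
    ct_housekeeping_mean: float = 20.0
    ct_housekeeping_sd: float = 0.3
    include_depot: bool = False
    seed: int = 20230419

    @property
    def genes(self) -> list[str]:
        return list(self.bat_genes) + list(self.inflammatory_genes)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariate_scales)

    @property
    def variables(self) -> list[str]:
        return self.genes + self.covariate_names

    def __post_init__(self) -> None:
        if min(self.n_lean, self.n_overweight, self.n_obese, self.n_paired) < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("gene and covariate names must be unique")
        if self.target_correlation is None:
            self.target_correlation = default_target_correlation(self.variables)
        else:
            # pad a partial specification out to the full variable set
            full = pd.DataFrame(
                np.eye(len(self.variables)),
                index=self.variables,
                columns=self.variables,
            )
            sub = self.target_correlation
            full.loc[sub.index, sub.columns] = sub.to_numpy(dtype=float)
            self.target_correlation = full
        self.target_correlation = repair_correlation(self.target_correlation)
        if self.group_shifts is None:
            self.group_shifts = {
                g: dict(_DEFAULT_GROUP_SHIFTS.get(g, {})) for g in GROUPS
            }
        if self.planted_network is None:
            self.planted_network = pd.DataFrame(
                np.zeros((len(self.genes), len(self.genes))),
                index=self.genes,
                columns=self.genes,
            )
        if np.any(np.diag(self.planted_network.to_numpy(dtype=float)) != 0):
            raise ValueError("planted network must have a zero diagonal")
        if self.surgery_effect is None:
            self.surgery_effect = dict(_DEFAULT_SURGERY_EFFECT)
        if self.delta_sd is None:
            self.delta_sd = dict(_DEFAULT_DELTA_SD)
        if self.paired_baseline_shift is None:
            self.paired_baseline_shift = dict(_DEFAULT_PAIRED_BASELINE)

    def _delta_sd_for(self, var: str) -> float:
        if var in self.delta_sd:
            return self.delta_sd[var]
        return _DEFAULT_GENE_DELTA_SD if var in self.genes else 0.0


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generator, for recovery testing."""

    adjacency: pd.DataFrame
    correlation_targets: pd.DataFrame
    group_effects: dict[str, dict[str, float]]
    surgery_effects: dict[str, float]
    seed: int

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "adjacency": self.adjacency.to_dict(),
                "correlation_targets": self.correlation_targets.round(12).to_dict(),
                "group_effects": self.group_effects,
                "surgery_effects": self.surgery_effects,
                "seed": self.seed,
            },
            sort_keys=True,
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _latent_samples(
    config: SyntheticConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    chol = np.linalg.cholesky(
        config.target_correlation.to_numpy(dtype=float)
        + np.eye(len(config.variables)) * 1e-12
    )
    return rng.standard_normal((n, len(config.variables))) @ chol.T


def _to_natural(config: SyntheticConfig, latent: np.ndarray) -> pd.DataFrame:
    """Map latent unit-variance values onto natural scales per variable."""
    out = {}
    for k, var in enumerate(config.variables):
        col = latent[:, k]
        if var in config.covariate_scales:
            mean, sd = config.covariate_scales[var]
            out[var] = np.maximum(mean + sd * col, _MIN_EXPRESSION)
        else:
            out[var] = np.exp(config.noise_sd * col)
    return pd.DataFrame(out)


def _truth(config: SyntheticConfig) -> PlantedTruth:
    return PlantedTruth(
        adjacency=config.planted_network.copy(),
        correlation_targets=config.target_correlation.copy(),
        group_effects={g: dict(s) for g, s in config.group_shifts.items()},
        surgery_effects=dict(config.surgery_effect),
        seed=config.seed,
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate the BMI-stratified cross-sectional cohort.

    Returns ``(expression, clinical, truth)``: a wide expression table
    (sample_id, group[, depot], one strictly positive column per gene) and a
    clinical table on natural scales.  Identical config + seed gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    sizes = [config.n_lean, config.n_overweight, config.n_obese]
    n = sum(sizes)
    if n == 0:
        raise ValueError("cohort is empty")
    groups = np.repeat(list(GROUPS), sizes)
    latent = _latent_samples(config, n, rng)
    shift = np.zeros_like(latent)
    for gi, group in enumerate(GROUPS):
        mask = groups == group
        for k, var in enumerate(config.variables):
            shift[mask, k] = config.group_shifts.get(group, {}).get(var, 0.0)
    natural = _to_natural(config, latent + shift)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    meta = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    if config.include_depot:
        meta["depot"] = np.where(rng.random(n) < 0.5, "Sc", "Om")
    expression = pd.concat(
        [meta.reset_index(drop=True), natural[config.genes]], axis=1
    )
    clinical = pd.concat(
        [meta[["sample_id", "group"]], natural[config.covariate_names]], axis=1
    )
    return expression, clinical, _truth(config)


def generate_paired(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate the paired pre/post-surgery subcohort.

    Returns ``(clinical, expression, truth)`` with 2 x n_paired rows keyed
    by ``subject_id`` and ``timepoint`` in {pre, post}.  Post-minus-pre
    changes have mean ``surgery_effect`` per variable and are coupled across
    variables through ``target_correlation`` on the delta scale.
    """
    if config.n_paired < 3:
        raise ValueError("paired analysis requires n_paired >= 3")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_paired
    k = len(config.variables)
    baseline_latent = _latent_samples(config, n, rng)
    base_shift = np.array(
        [config.paired_baseline_shift.get(v, 0.0) for v in config.variables]
    )
    pre = _to_natural(config, baseline_latent + base_shift)
    delta_z = _latent_samples(config, n, rng)
    effect = np.array([config.surgery_effect.get(v, 0.0) for v in config.variables])
    sds = np.array([config._delta_sd_for(v) for v in config.variables])
    post_vals = pre.to_numpy() + effect + delta_z * sds
    post = pd.DataFrame(
        np.maximum(post_vals, _MIN_EXPRESSION), columns=config.variables
    )
    subjects = [f"P{i + 1:03d}" for i in range(n)]
    frames = []
    for tp, table in (("pre", pre), ("post", post)):
        block = table.copy()
        block.insert(0, "timepoint", tp)
        block.insert(0, "subject_id", subjects)
        frames.append(block)
    long = pd.concat(frames, ignore_index=True)
    clinical = long[["subject_id", "timepoint"] + config.covariate_names]
    expression = long[["subject_id", "timepoint"] + config.genes]
    return clinical, expression, _truth(config)


def generate_ct_plates(
    config: SyntheticConfig,
    expression: pd.DataFrame,
    housekeeping: str = "L19",
    id_cols: tuple[str, ...] = ("sample_id",),
) -> pd.DataFrame:
    """Simulate duplicate-well qPCR plates from an expression table.

    Housekeeping Ct varies per sample; each gene's replicate Ct values are
    Ct_housekeeping - log2(expression) plus replicate noise of sd
    ``ct_noise_sd`` cycles, so collapsing duplicates and quantifying with
    2^-dCt recovers the input expression (exactly when ``ct_noise_sd`` is 0).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gene_cols = [
        c
        for c in expression.columns
        if c not in id_cols and pd.api.types.is_numeric_dtype(expression[c])
    ]
    if not gene_cols:
        raise ValueError("expression table has no numeric gene columns")
    values = expression[gene_cols].to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("expression values must be strictly positive")
    ids = expression[list(id_cols)].astype(str).agg("_".join, axis=1)
    if ids.duplicated().any():
        raise ValueError("duplicate sample identifiers in expression table")
    rows = []
    for s, sid in enumerate(ids):
        hk_base = config.ct_housekeeping_mean + config.ct_housekeeping_sd * (
            rng.standard_normal()
        )
        for rep in (1, 2):
            noise = config.ct_noise_sd * rng.standard_normal()
            rows.append((sid, housekeeping, rep, hk_base + noise))
        for g, gene in enumerate(gene_cols):
            base = hk_base - np.log2(values[s, g])
            for rep in (1, 2):
                noise = config.ct_noise_sd * rng.standard_normal()
                rows.append((sid, gene, rep, base + noise))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "replicate", "ct"])
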