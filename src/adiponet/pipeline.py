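"""End-to-end orchestration: configuration, stage ordering, and file plumbing.

A single structured config (YAML, JSON-compatible) declares either a
synthetic-cohort block or input file paths, stage toggles, the network
inference settings, an output directory and a mandatory seed.  Stages run
in dependency order (qpcr -> metrics -> stats/correlations -> anni) and a
manifest records the config hash, seed, every file written and all
warnings, so identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anni, association, clinical, cohort_stats, qpcr, synthetic

__all__ = ["RunConfig", "run_pipeline", "validate_tables", "load_table"]

logger = logging.getLogger("adiponet")

_STAGES = ("qpcr", "metrics", "stats", "correlations", "anni")

_VALID_GROUPS = {"lean", "overweight", "obese", "pre", "post"}


class RunConfig:
    """Validated pipeline configuration."""

    def __init__(self, raw: dict):
        self.raw = raw
        if "seed" not in raw:
            raise ValueError("config must declare a seed")
        self.seed = int(raw["seed"])
        self.output_dir = Path(raw.get("output_dir", "adiponet_out"))
        self.log_level = str(raw.get("log_level", "INFO"))
        has_synth = "synthetic" in raw
        has_inputs = "inputs" in raw
        if has_synth == has_inputs:
            raise ValueError(
                "config must declare exactly one of 'synthetic' or 'inputs'"
            )
        self.synthetic = raw.get("synthetic")
        self.inputs = raw.get("inputs")
        stages = raw.get("stages", {s: True for s in _STAGES})
        unknown = set(stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = {s: bool(stages.get(s, False)) for s in _STAGES}
        self.ann = raw.get("anni", {})

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def config_hash(self) -> str:
        # hash only analysis-relevant keys, so the same analysis written to a
        # different directory still reproduces byte-identical outputs
        canon = json.dumps(
            {
                k: v
                for k, v in self.raw.items()
                if k not in ("output_dir", "log_level")
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def synthetic_config(self) -> synthetic.SyntheticConfig:
        block = dict(self.synthetic or {})
        block.setdefault("seed", self.seed)
        return synthetic.SyntheticConfig(**block)

    def ann_config(self) -> anni.AnnConfig:
        block = dict(self.ann)
        block.setdefault("seed", self.seed)
        if "split_fractions" in block:
            block["split_fractions"] = tuple(block["split_fractions"])
        return anni.AnnConfig(**block)


def load_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping provenance comment lines."""
    return pd.read_csv(path, comment="#")


def validate_tables(expr: pd.DataFrame, clin: pd.DataFrame) -> list[dict]:
    """Report-only consistency checks between expression and clinical tables.

    Checks sample-ID join completeness in both directions, strict positivity
    of gene columns, the group-label vocabulary, and duplicate sample IDs.
    """
    violations: list[dict] = []
    key = "sample_id" if "sample_id" in expr.columns else "subject_id"
    for name, table in (("expression", expr), ("clinical", clin)):
        if key not in table.columns:
            violations.append(
                {"kind": "missing_key", "table": name, "detail": key}
            )
            return violations
        dup = table[key][table[key].duplicated()]
        sub_key = [key, "timepoint"] if "timepoint" in table.columns else [key]
        dup = table.loc[table.duplicated(subset=sub_key), key]
        for d in dup:
            violations.append({"kind": "duplicate_id", "table": name, "detail": d})
    expr_ids, clin_ids = set(expr[key]), set(clin[key])
    for sid in sorted(expr_ids - clin_ids):
        violations.append({"kind": "join", "table": "clinical", "detail": sid})
    for sid in sorted(clin_ids - expr_ids):
        violations.append({"kind": "join", "table": "expression", "detail": sid})
    meta = {key, "group", "depot", "timepoint"}
    for col in expr.columns:
        if col in meta or not pd.api.types.is_numeric_dtype(expr[col]):
            continue
        bad = expr.loc[expr[col] <= 0, key]
        for sid in bad:
            violations.append(
                {"kind": "positivity", "table": "expression", "detail": f"{sid}:{col}"}
            )
    for name, table in (("expression", expr), ("clinical", clin)):
        if "group" in table.columns:
            bad = set(table["group"]) - _VALID_GROUPS
            for label in sorted(bad):
                violations.append(
                    {"kind": "group_label", "table": name, "detail": label}
                )
    return violations


class _Writer:
    """Writes outputs with a provenance header and records them for the manifest."""

    def __init__(self, outdir: Path, seed: int, config_hash: str):
        self.outdir = outdir
        self.header = f"# adiponet seed={seed} config={config_hash}\n"
        self.files: dict[str, str] = {}

    def csv(self, name: str, frame: pd.DataFrame, index: bool = False) -> Path:
        path = self.outdir / name
        with open(path, "w") as fh:
            fh.write(self.header)
            frame.to_csv(fh, index=index)
        self._record(path)
        return path

    def json(self, name: str, payload) -> Path:
        path = self.outdir / name
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1, default=_jsonable)
        self._record(path)
        return path

    def text(self, path: Path) -> None:
        self._record(path)

    def _record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[str(path.relative_to(self.outdir))] = digest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _stage_data(config: RunConfig, writer: _Writer) -> dict[str, pd.DataFrame]:
    if config.synthetic is not None:
        sc = config.synthetic_config()
        expr, clin, truth = synthetic.generate_cohort(sc)
        paired_clin, paired_expr, _ = synthetic.generate_paired(sc)
        ct = synthetic.generate_ct_plates(sc, expr)
        writer.csv("cohort_expression.csv", expr)
        writer.csv("cohort_clinical.csv", clin)
        writer.csv("paired_clinical.csv", paired_clin)
        writer.csv("paired_expression.csv", paired_expr)
        writer.csv("ct_plates.csv", ct)
        truth_path = writer.outdir / "planted_truth.json"
        truth.to_json(truth_path)
        writer.text(truth_path)
        return {
            "expression": expr,
            "clinical": clin,
            "paired_clinical": paired_clin,
            "paired_expression": paired_expr,
            "ct": ct,
        }
    tables: dict[str, pd.DataFrame] = {}
    for name, path in config.inputs.items():
        tables[name] = load_table(path)
    if "expression" not in tables and "ct" not in tables:
        raise ValueError("inputs must provide 'expression' and/or 'ct'")
    return tables


def _gene_columns(expr: pd.DataFrame) -> list[str]:
    meta = {"sample_id", "subject_id", "group", "depot", "timepoint"}
    return [
        c
        for c in expr.columns
        if c not in meta and pd.api.types.is_numeric_dtype(expr[c])
    ]


def _stage_qpcr(tables, writer: _Writer) -> None:
    if "ct" not in tables:
        return
    expr_q = qpcr.quantify(tables["ct"])
    writer.csv("qpcr_expression.csv", expr_q)
    tables.setdefault("expression", expr_q)


def _stage_metrics(tables, writer: _Writer) -> None:
    if "clinical" in tables:
        derived = clinical.derive_clinical_columns(tables["clinical"])
        writer.csv("clinical_derived.csv", derived)
    p_clin = tables.get("paired_clinical")
    if p_clin is not None and {"weight", "ideal_weight"}.issubset(p_clin.columns):
        wide = p_clin.pivot(index="subject_id", columns="timepoint")
        frame = pd.DataFrame(
            {
                "weight_pre": wide[("weight", "pre")],
                "weight_post": wide[("weight", "post")],
                "ideal_weight": wide[("ideal_weight", "pre")],
            }
        ).reset_index()
        writer.csv("paired_metrics.csv", clinical.derive_clinical_columns(frame))


def _stage_stats(tables, writer: _Writer) -> None:
    results = []
    expr = tables.get("expression")
    clin = tables.get("clinical")
    if expr is not None and "group" in expr.columns:
        for gene in _gene_columns(expr):
            res = cohort_stats.compare_groups(expr[gene], expr["group"])
            results.append({"variable": gene, **res.to_dict()})
    if clin is not None and "group" in clin.columns:
        for var in _gene_columns(clin):
            res = cohort_stats.compare_groups(clin[var], clin["group"])
            results.append({"variable": var, **res.to_dict()})
    paired_frames = [
        tables.get("paired_clinical"), tables.get("paired_expression")
    ]
    paired_results = []
    for frame in paired_frames:
        if frame is None or "timepoint" not in frame.columns:
            continue
        wide = frame.pivot(index="subject_id", columns="timepoint")
        for var in _gene_columns(frame):
            pre = wide[(var, "pre")].to_numpy()
            post = wide[(var, "post")].to_numpy()
            res = cohort_stats.compare_paired(pre, post)
            paired_results.append({"variable": var, **res.to_dict()})
    writer.json("stats_groups.json", results)
    writer.json("stats_paired.json", paired_results)
    flat = pd.DataFrame(
        [
            {
                "variable": r["variable"],
                "test": r["test_name"],
                "branch": r["branch"],
                "statistic": r["statistic"],
                "p_value": r["p_value"],
            }
            for r in results + paired_results
        ]
    )
    writer.csv("stats_summary.csv", flat)


def _stage_correlations(tables, writer: _Writer) -> None:
    expr = tables.get("expression")
    clin = tables.get("clinical")
    if expr is not None:
        genes = _gene_columns(expr)
        bat = [g for g in genes if g in synthetic.BAT_PANEL] or genes
        infl = [g for g in genes if g in synthetic.INFLAMMATORY_PANEL] or genes
        merged = expr
        if clin is not None and "sample_id" in clin.columns:
            merged = expr.merge(
                clin.drop(columns=[c for c in ("group",) if c in clin.columns]),
                on="sample_id",
                how="inner",
            )
        matrix = association.correlation_matrix(merged, bat, infl)
        writer.csv(
            "correlations_matrix.csv",
            association.correlation_matrix_to_frame(matrix),
        )
        covars = [c for c in ("bmi", "endotoxin") if c in merged.columns]
        if covars:
            with_cov = association.correlation_matrix(merged, bat, covars)
            writer.csv(
                "correlations_covariates.csv",
                association.correlation_matrix_to_frame(with_cov),
            )
    p_clin = tables.get("paired_clinical")
    p_expr = tables.get("paired_expression")
    if (
        p_clin is not None
        and p_expr is not None
        and "endotoxin" in p_clin.columns
    ):
        paired = p_clin.merge(p_expr, on=["subject_id", "timepoint"])
        rows = []
        for gene in _gene_columns(p_expr):
            try:
                res = association.delta_correlation(paired, "endotoxin", gene)
            except ValueError as exc:
                logger.warning("delta correlation for %s skipped: %s", gene, exc)
                continue
            rows.append(res.to_dict())
        writer.csv("correlations_delta.csv", pd.DataFrame(rows))


def _stage_anni(config: RunConfig, tables, writer: _Writer) -> None:
    expr = tables.get("expression")
    if expr is None:
        raise ValueError("anni stage needs an expression table")
    im = anni.interaction_matrix(expr, config.ann_config(), genes=_gene_columns(expr))
    writer.csv("interaction_matrix.csv", im.W, index=True)
    writer.csv("interaction_dispersion.csv", im.dispersion, index=True)
    writer.csv("influence_summary.csv", anni.collapse_influence(im), index=True)
    n_edges = len(im.genes) * (len(im.genes) - 1)
    edges = anni.rank_interactions(im, top_k=n_edges)
    for path in anni.export_network(edges, str(writer.outdir / "network"), "SIF"):
        writer.text(Path(path))
    for path in anni.export_network(edges, str(writer.outdir / "network"), "GraphML"):
        writer.text(Path(path))


def run_pipeline(config: RunConfig | dict | str | Path) -> dict:
    """Run the enabled stages in dependency order and write a manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory); its ``manifest_hash`` is a digest over the config
    hash and every output file's content hash, so reruns are verifiable.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_file(config)
    elif isinstance(config, dict):
        config = RunConfig(config)
    logging.basicConfig(level=config.log_level)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    writer = _Writer(config.output_dir, config.seed, config.config_hash())
    captured: list[str] = []

    def _fail(stage: str, exc: Exception):
        partial = config.output_dir / "manifest.partial.json"
        with open(partial, "w") as fh:
            json.dump(
                {"failed_stage": stage, "outputs": writer.files},
                fh,
                sort_keys=True,
                indent=1,
            )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            tables = _stage_data(config, writer)
        except Exception as exc:  # noqa: BLE001 - named-stage abort
            _fail("data", exc)
        for stage, runner in (
            ("qpcr", lambda: _stage_qpcr(tables, writer)),
            ("metrics", lambda: _stage_metrics(tables, writer)),
            ("stats", lambda: _stage_stats(tables, writer)),
            ("correlations", lambda: _stage_correlations(tables, writer)),
            ("anni", lambda: _stage_anni(config, tables, writer)),
        ):
            if not config.stages[stage]:
                continue
            try:
                runner()
            except Exception as exc:  # noqa: BLE001 - named-stage abort
                _fail(stage, exc)
        captured = sorted({str(w.message) for w in wlist})
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {s: v for s, v in config.stages.items()},
        "outputs": dict(sorted(writer.files.items())),
        "warnings": captured,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    path = config.output_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
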