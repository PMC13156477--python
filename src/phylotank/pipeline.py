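"""End-to-end orchestration: filters -> scales -> metrics -> nulls ->
models -> response indices -> phylogenetic signal.

`run_all` takes a phylogeny, the three dataset roles (community table +
bromeliad metadata each), and a configuration, and produces

* ``metrics``  — per (role, scale, weighting, bromeliad, metric) SES rows;
* ``models``   — per (role, scale, metric, term) model-selection rows with
  estimate, partial R², sign, inclusion and significance flags (the
  machine-readable analogue of a heatmap of term contributions);
* ``indices``  — species response indices from the experiments;
* ``signal``   — phylogenetic-signal tests of those indices per scale;
* ``manifest`` — config hash, seeds, per-stage row counts, warnings, and
  sha256 checksums of every written file, so a rerun with the same config
  and seed reproduces outputs bit-identically.

Term significance inside chosen models is reported from t-tests at
alpha = 0.05 (a reporting convention; selection itself is by AICc).
Degenerate SES cells (richness < 2, or null SD zero) propagate as missing
responses and are dropped from model fits with a logged count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    SCALES, BromeliadMeta, CommunityTable, DegeneratePoolError, Phylogeny,
    apply_survey_filters, subset_taxonomic_scale,
)
from .metrics import ROLE_WEIGHTING, UNWEIGHTED, Weighting, ses_metrics, richness
from .models import ModelSelectionResult, fit_candidates, standardize, transform_response
from .nulls import build_pool
from .responses import compute_response_indices
from .signal import signal_by_scale

logger = logging.getLogger("phylotank")

ALPHA_TERMS = 0.05
METRIC_LABELS = {"richness": "SR", "mpd": "NRI", "mntd": "NTI"}


@dataclass
class PipelineConfig:
    seed: int = 0
    n_runs: int = 999
    scales: tuple[str, ...] = SCALES
    weightings: tuple[str, ...] = ("weighted", "unweighted")
    primary_weighting: str = "weighted"
    transform: str = "auto"
    n_perm_signal: int = 999
    survey_exclude_species: tuple[str, ...] = ()
    use_microhabitat_flag: bool = True


@dataclass
class RunResults:
    metrics: pd.DataFrame
    models: pd.DataFrame
    indices: pd.DataFrame
    signal: pd.DataFrame
    heatmap: pd.DataFrame
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {k: list(v) if isinstance(v, tuple) else v
         for k, v in config.__dict__.items()},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _model_rows(
    role: str, scale: str, metric: str, result: ModelSelectionResult
) -> list[dict]:
    rows = []
    for term, pr2 in result.partial_r2.items():
        coef = result.coefficients.get(term, np.nan)
        pval = result.term_pvalues.get(term, np.nan)
        rows.append({
            "role": role, "scale": scale, "metric": METRIC_LABELS.get(metric, metric),
            "term": term, "estimate": coef, "partial_r2": pr2,
            "sign": "+" if coef > 0 else "-",
            "in_best_model": True,
            "ns_flag": bool(pval >= ALPHA_TERMS) if np.isfinite(pval) else True,
            "p_value": pval, "n": result.n,
        })
    return rows


def run_all(
    tree: Phylogeny,
    datasets: dict[str, tuple[CommunityTable, BromeliadMeta]],
    config: PipelineConfig | None = None,
) -> RunResults:
    """Run the full analysis over every (role x scale x metric x weighting).

    ``datasets`` maps role ("survey" / "colonization" / "extinction") to a
    (CommunityTable, BromeliadMeta) pair; any subset of roles is accepted.
    """
    if config is None:
        config = PipelineConfig()
    rng = np.random.default_rng(config.seed)
    warnings_log: list[str] = []
    metric_rows: list[pd.DataFrame] = []
    model_rows: list[dict] = []

    for role, (table, meta) in datasets.items():
        if role == "survey":
            table, filt_log = apply_survey_filters(
                table, meta,
                exclude_species=config.survey_exclude_species,
                use_microhabitat_flag=config.use_microhabitat_flag,
            )
            meta = BromeliadMeta(meta.table.loc[table.bromeliads].copy())
            warnings_log += [f"survey: {entry}" for entry in filt_log]
        pool_all = build_pool(table)
        for scale in config.scales:
            try:
                sub_table, sub_tree = subset_taxonomic_scale(table, tree, scale)
            except DegeneratePoolError as exc:
                warnings_log.append(f"{role}/{scale}: {exc}")
                continue
            pool = [s for s in pool_all if s in set(sub_table.species)]
            if len(pool) < 2:
                warnings_log.append(f"{role}/{scale}: pool < 2 species")
                continue
            dist = sub_tree.patristic_matrix()
            ses_frames = {}
            for wname in config.weightings:
                weighting = (
                    ROLE_WEIGHTING[role] if wname == "weighted" else UNWEIGHTED
                )
                ses = ses_metrics(
                    sub_table, dist, pool, weighting=weighting,
                    n_runs=config.n_runs, rng=rng,
                )
                ses["role"], ses["scale"], ses["weighting"] = role, scale, wname
                ses_frames[wname] = ses
                metric_rows.append(ses)
            n_degenerate = int(ses_frames[config.primary_weighting]["degenerate"].sum())
            if n_degenerate:
                warnings_log.append(
                    f"{role}/{scale}: {n_degenerate} degenerate SES cells dropped"
                )
            # model selection per metric on the primary weighting
            from .models import build_design

            design = build_design(meta, role)
            primary = ses_frames[config.primary_weighting]
            responses = {
                "richness": np.array(
                    [richness(sub_table.counts.loc[b]) for b in sub_table.bromeliads],
                    dtype=float,
                ),
            }
            for m in ("mpd", "mntd"):
                sel = primary[primary["metric"] == m].set_index("bromeliad")
                responses[m] = sel["nri_or_nti"].reindex(
                    sub_table.bromeliads
                ).to_numpy(dtype=float)
            for metric, y in responses.items():
                mask = np.isfinite(y)
                if mask.sum() < 8 or np.nanstd(y) == 0:
                    warnings_log.append(
                        f"{role}/{scale}/{metric}: too few usable communities"
                    )
                    continue
                ydes = design.loc[mask]
                tr = transform_response(y[mask], ydes, method=config.transform)
                ystd = standardize(tr.y)
                result = fit_candidates(ydes, ystd, role=role)
                model_rows += _model_rows(role, scale, metric, result)

    # response indices and their phylogenetic signal
    indices = pd.DataFrame()
    signal = pd.DataFrame()
    exp_args = {}
    if "colonization" in datasets:
        exp_args["colonization"] = datasets["colonization"]
    if "extinction" in datasets:
        exp_args["extinction"] = datasets["extinction"]
    if exp_args:
        indices = compute_response_indices(**exp_args, rng=rng)
        signal = signal_by_scale(
            tree, indices, scales=config.scales,
            n_perm=config.n_perm_signal, rng=rng,
        )

    metrics = (
        pd.concat(metric_rows, ignore_index=True) if metric_rows else pd.DataFrame()
    )
    models = pd.DataFrame(model_rows)
    heatmap = summarize_heatmap(models)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "roles": sorted(datasets),
        "scales": list(config.scales),
        "row_counts": {
            "metrics": len(metrics), "models": len(models),
            "indices": len(indices), "signal": len(signal),
        },
        "warnings": warnings_log,
    }
    return RunResults(metrics, models, indices, signal, heatmap, manifest)


def summarize_heatmap(models: pd.DataFrame) -> pd.DataFrame:
    """Long-format summary: one row per (role, scale, metric, term) with
    partial R², effect direction, inclusion and significance flags.  Terms
    absent from a chosen model appear with ``in_best_model=False`` and an
    empty effect, so every panel cell is represented."""
    if models.empty:
        logger.warning("summarize_heatmap: no model results")
        return pd.DataFrame(
            columns=["role", "scale", "metric", "term", "partial_r2",
                     "sign", "in_best_model", "ns_flag"]
        )
    all_terms = ("size", "size2", "predator", "size_x_predator", "detritus")
    rows = []
    for (role, scale, metric), grp in models.groupby(["role", "scale", "metric"]):
        present = set(grp["term"])
        terms = all_terms if role == "survey" else all_terms[:4]
        for term in terms:
            if term in present:
                r = grp[grp["term"] == term].iloc[0]
                rows.append({
                    "role": role, "scale": scale, "metric": metric, "term": term,
                    "partial_r2": r["partial_r2"], "sign": r["sign"],
                    "in_best_model": True, "ns_flag": r["ns_flag"],
                })
            else:
                rows.append({
                    "role": role, "scale": scale, "metric": metric, "term": term,
                    "partial_r2": np.nan, "sign": "",
                    "in_best_model": False, "ns_flag": False,
                })
    return pd.DataFrame(rows)


def plot_heatmap(heatmap: pd.DataFrame, path: str | Path) -> None:
    """Bubble-matrix rendering of the summary table (circle area = partial
    R², color = effect direction)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roles = sorted(heatmap["role"].unique())
    fig, axes = plt.subplots(1, len(roles), figsize=(4 * len(roles), 4),
                             squeeze=False)
    for ax, role in zip(axes[0], roles):
        sub = heatmap[heatmap["role"] == role]
        cols = sorted(sub["term"].unique())
        rows = sorted(set(zip(sub["scale"], sub["metric"])))
        for i, (scale, metric) in enumerate(rows):
            for j, term in enumerate(cols):
                cell = sub[(sub["scale"] == scale) & (sub["metric"] == metric)
                           & (sub["term"] == term)]
                if cell.empty or not cell.iloc[0]["in_best_model"]:
                    continue
                r2 = cell.iloc[0]["partial_r2"]
                color = "#c0392b" if cell.iloc[0]["sign"] == "+" else "#2980b9"
                ax.scatter(j, i, s=2000 * max(r2, 0.01), c=color, alpha=0.7)
                if cell.iloc[0]["ns_flag"]:
                    ax.text(j, i, "ns", ha="center", va="center", fontsize=7)
        ax.set_xticks(range(len(cols)), cols, rotation=45, ha="right")
        ax.set_yticks(range(len(rows)), [f"{s}:{m}" for s, m in rows])
        ax.set_title(role)
        ax.set_xlim(-0.5, len(cols) - 0.5)
        ax.set_ylim(len(rows) - 0.5, -0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_outputs(results: RunResults, outdir: str | Path) -> dict:
    """Write all result tables plus the manifest; returns the manifest with
    per-file sha256 checksums filled in."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "metrics.csv": results.metrics,
        "models.csv": results.models,
        "indices.csv": results.indices,
        "signal.csv": results.signal,
        "heatmap.csv": results.heatmap,
    }
    checksums = {}
    for name, df in files.items():
        path = outdir / name
        df.to_csv(path, index=False)
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = dict(results.manifest, checksums=checksums)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
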