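"""Volcano/score plots, report tables, and the end-to-end pipeline runner.

The volcano plot places each metabolite at (median oriented loading, median
VIP): right of zero means elevated during crisis, left means depressed, and
everything above the VIP guide line is part of the discriminant signature.
Bubble colours follow the panel's biochemical classes (amino acids green,
biogenic amines light green, carnitines brown, lysoPC light/dark blue by
acyl chain length below/above 22 carbons, PC orange, SM yellow, hexose
gray).  Score plots show samples in the LV1/LV2 (or PC1/PC2) plane, crisis
red and steady-state blue.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .ensemble import (
    EnsembleConfig,
    EnsembleResult,
    class_breakdown,
    run_ensemble,
    select_discriminant,
)
from .mstats import pca_outliers, pca_scores
from .panel import PairedDataset, PanelSpec, default_panel, load_concentrations, load_panel, write_dataset
from .qc import apply_quantitation_filter, surviving_share_percent
from .simulate import SimulationConfig, demo_config, generate_dataset

log = logging.getLogger("pairedpls")

FIGSIZE = (7.0, 5.5)
_SVG_META = {"Date": None}  # deterministic, diffable SVG output

_CLASS_COLORS = {
    "hexose": "#808080",
    "amino_acid": "#1a9641",
    "biogenic_amine": "#a6d96a",
    "free_carnitine": "#8c510a",
    "acylcarnitine": "#8c510a",
    "PC_aa": "#ff7f00",
    "PC_ae": "#ff7f00",
    "sphingomyelin": "#ffd92f",
}
_LPC_SHORT = "#9ecae1"  # acyl chain < 22 carbons
_LPC_LONG = "#08519c"   # acyl chain > 22 carbons


def class_color(class_label: str, acyl_carbons: int | None = None) -> str:
    if class_label == "lysoPC":
        return _LPC_LONG if (acyl_carbons or 0) > 22 else _LPC_SHORT
    return _CLASS_COLORS[class_label]


def volcano_records(
    result: EnsembleResult, panel: PanelSpec, vip_threshold: float = 1.0
) -> pd.DataFrame:
    """One row per metabolite: class, median VIP/loading, selected flag and
    direction — the table behind the volcano plot and the report footer."""
    entries = [panel.entry(m) for m in result.metabolites]
    df = pd.DataFrame(
        {
            "metabolite_id": result.metabolites,
            "class_label": [e.class_label for e in entries],
            "acyl_carbons": [e.acyl_carbons for e in entries],
            "median_vip": result.median_vip.to_numpy(),
            "median_loading": result.median_loading.to_numpy(),
        }
    )
    df["selected"] = df["median_vip"] >= vip_threshold
    df["direction"] = np.where(df["median_loading"] > 0, "increased", "decreased")
    return df


def volcano_plot(
    records: pd.DataFrame, threshold: float, out_path: str | Path
) -> Path:
    """Median loading vs median VIP; only selected metabolites are labelled."""
    if records.empty:
        raise ValueError("no records to plot")
    fig, ax = plt.subplots(figsize=FIGSIZE)
    colors = [
        class_color(c, a if pd.notna(a) else None)
        for c, a in zip(records["class_label"], records.get("acyl_carbons", np.nan))
    ]
    ax.scatter(
        records["median_loading"], records["median_vip"],
        c=colors, s=36, alpha=0.85, edgecolors="none",
    )
    ax.axhline(threshold, color="0.4", linestyle="--", linewidth=1)
    for _, r in records[records["median_vip"] >= threshold].iterrows():
        ax.annotate(
            r["metabolite_id"], (r["median_loading"], r["median_vip"]),
            fontsize=6, xytext=(2, 2), textcoords="offset points",
        )
    ax.set_xlabel("median loading (positive = elevated in crisis)")
    ax.set_ylabel("median VIP")
    ax.set_title("Discriminant metabolites: loading vs VIP")
    out_path = Path(out_path)
    _save(fig, out_path)
    return out_path


def misallocation_count(lv1: np.ndarray, states: list[str]) -> int:
    """Samples on the wrong side of the LV1 = 0 boundary (crisis side is
    positive): predicted IC iff LV1 > 0."""
    lv1 = np.asarray(lv1, float)
    pred_ic = lv1 > 0
    actual_ic = np.array([s == "IC" for s in states])
    return int((pred_ic != actual_ic).sum())


def score_plot(
    coords: np.ndarray | pd.DataFrame,
    states: list[str],
    out_path: str | Path,
    axis_prefix: str = "LV",
    annotate_misallocation: bool = False,
) -> Path:
    """Two-component sample scatter, IC red / OC blue.  The same renderer
    serves PLS (LV1/LV2) and PCA (PC1/PC2) via ``axis_prefix``."""
    coords = np.asarray(coords, float)
    if coords.shape[0] != len(states):
        raise ValueError("one coordinate pair per sample required")
    fig, ax = plt.subplots(figsize=FIGSIZE)
    states_arr = np.array(states)
    for state, color in (("IC", "#d62728"), ("OC", "#1f77b4")):
        rows = states_arr == state
        ax.scatter(coords[rows, 0], coords[rows, 1], c=color, s=40, label=state,
                   alpha=0.85, edgecolors="none")
    ax.axhline(0, color="0.85", linewidth=0.8)
    ax.axvline(0, color="0.85", linewidth=0.8)
    ax.set_xlabel(f"{axis_prefix}1")
    ax.set_ylabel(f"{axis_prefix}2")
    ax.legend(title="state")
    if annotate_misallocation:
        n_mis = misallocation_count(coords[:, 0], states)
        ax.set_title(f"{n_mis} sample(s) misallocated")
    out_path = Path(out_path)
    _save(fig, out_path)
    return out_path


def _save(fig: matplotlib.figure.Figure, out_path: Path) -> None:
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if out_path.suffix == ".svg":
        fig.savefig(out_path, metadata=_SVG_META)
    else:
        fig.savefig(out_path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "simulate": {"kind": "strong", "n_pairs": 40, "seed": 0, "matrix": "plasma"},
    "filter": {"threshold": 0.20, "alpha": 0.05},
    "ensemble": {
        "inner_train_size": 20,
        "stride": None,
        "target_n_models": 2000,
        "bm_threshold": 0.95,
        "vip_threshold": 1.0,
        "seed": 1,
        "multilevel": True,
        "n_components": 2,
    },
    "plots": True,
}

_KNOWN_KEYS = {"simulate", "dataset", "panel", "filter", "ensemble", "plots"}


def _load_config(config: dict | str | Path) -> dict:
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    merged = json.loads(json.dumps(_DEFAULT_CONFIG))  # deep copy
    for key in ("simulate", "filter", "ensemble"):
        if key in config:
            section = dict(merged[key])
            section.update(config[key] or {})
            merged[key] = section
    for key in ("dataset", "panel", "plots"):
        if key in config:
            merged[key] = config[key]
    if "dataset" in merged and "simulate" in config:
        raise ValueError("config must name either a dataset file or a simulate block")
    return merged


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """simulate (optional) → quantitation filter → ensemble → reports.

    Writes all artifacts plus a manifest recording versions, seeds, the
    config hash, and every output path; returns the summary dict.  Any stage
    failure is re-raised with the stage name.
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # -- inputs -------------------------------------------------------------
    if "dataset" in cfg:
        panel = load_panel(cfg["panel"]) if "panel" in cfg else default_panel()
        dataset = _stage("load", lambda: load_concentrations(cfg["dataset"], panel))
        truth = None
    else:
        sim = cfg["simulate"]
        panel = load_panel(cfg["panel"]) if "panel" in cfg else default_panel()

        def _simulate():
            sim_cfg, _ = demo_config(
                kind=sim["kind"], n_pairs=sim["n_pairs"], seed=sim["seed"],
                panel=panel, matrix=sim.get("matrix", "plasma"),
            )
            return generate_dataset(sim_cfg)

        dataset, truth = _stage("simulate", _simulate)
        write_dataset(dataset, out_dir / "dataset.csv")
        truth.to_frame().to_csv(out_dir / "ground_truth.csv", index=False)
        outputs["dataset"] = str(out_dir / "dataset.csv")
        outputs["ground_truth"] = str(out_dir / "ground_truth.csv")

    # -- QC filter ----------------------------------------------------------
    flt = cfg["filter"]
    filtered, qc_report = _stage(
        "filter",
        lambda: apply_quantitation_filter(
            dataset, panel, threshold=flt["threshold"], alpha=flt["alpha"]
        ),
    )
    qc_report.to_csv(out_dir / "filter_report.tsv", sep="\t", index=False)
    outputs["filter_report"] = str(out_dir / "filter_report.tsv")
    write_dataset(filtered, out_dir / "filtered.csv")
    outputs["filtered_dataset"] = str(out_dir / "filtered.csv")

    # -- PCA check ----------------------------------------------------------
    coords_pca, explained = _stage("pca", lambda: pca_scores(filtered.values))
    outliers = pca_outliers(coords_pca)

    # -- ensemble -----------------------------------------------------------
    ens = dict(cfg["ensemble"])
    vip_threshold = ens.pop("vip_threshold")
    config_obj = EnsembleConfig(**ens)
    result = _stage("ensemble", lambda: run_ensemble(filtered, config_obj))
    result.models.to_csv(out_dir / "models.tsv", sep="\t", index=False)
    outputs["models"] = str(out_dir / "models.tsv")

    records = volcano_records(result, panel, vip_threshold)
    records.to_csv(out_dir / "aggregates.tsv", sep="\t", index=False)
    outputs["aggregates"] = str(out_dir / "aggregates.tsv")

    coord_table = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in result.trainval_samples],
            "state": [s.state for s in result.trainval_samples],
        }
    ).join(result.median_coords)
    coord_table.to_csv(out_dir / "coordinates.tsv", sep="\t", index=False)
    outputs["coordinates"] = str(out_dir / "coordinates.tsv")

    selection = select_discriminant(result, panel, vip_threshold)
    summary = result.summary()
    summary.update(
        {
            "n_metabolites_input": dataset.n_metabolites,
            "n_metabolites_kept": filtered.n_metabolites,
            "surviving_share_percent": surviving_share_percent(
                filtered.n_metabolites, dataset.n_metabolites
            ),
            "n_selected": int(len(selection)),
            "selected_class_counts": class_breakdown(selection),
            "pca_explained_variance": [float(v) for v in explained],
            "pca_outlier_rows": [int(i) for i in outliers],
        }
    )
    if truth is not None:
        planted = truth.discriminant_set & set(result.metabolites)
        chosen = set(selection["metabolite_id"])
        nulls = set(result.metabolites) - truth.discriminant_set
        summary["sensitivity"] = len(chosen & planted) / len(planted) if planted else float("nan")
        summary["false_selection_rate"] = len(chosen & nulls) / len(nulls) if nulls else 0.0
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["summary"] = str(out_dir / "summary.json")

    # -- figures ------------------------------------------------------------
    if cfg.get("plots", True):
        def _figures():
            for ext in ("svg", "png"):
                outputs[f"volcano_{ext}"] = str(
                    volcano_plot(records, vip_threshold, out_dir / f"volcano.{ext}")
                )
                outputs[f"scores_{ext}"] = str(
                    score_plot(
                        result.median_coords.to_numpy(),
                        [s.state for s in result.trainval_samples],
                        out_dir / f"scores.{ext}",
                        annotate_misallocation=True,
                    )
                )
                outputs[f"pca_{ext}"] = str(
                    score_plot(
                        coords_pca,
                        [s.state for s in filtered.samples],
                        out_dir / f"pca.{ext}",
                        axis_prefix="PC",
                    )
                )
        _stage("figures", _figures)

    manifest = {
        "pairedpls_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "matplotlib": matplotlib.__version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run_pipeline out_dir=%s passed=%s n_bm=%d", out_dir, summary["passed"], result.n_bm)
    return summary
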