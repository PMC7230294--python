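"""Quantitation-range filter with chi-squared rescue.

Targeted assays only quantify reliably between the LLOQ and ULOQ.  A
metabolite with more than 20% of its concentrations outside that window is
excluded — unless the out-of-range pattern itself tracks crisis status, in
which case censoring is informative and dropping the metabolite would throw
away a discriminant feature.  That association is tested with a Pearson
chi-squared on the 2×2 table (within/out of range) × (IC/OC); a significant
test rescues the metabolite.

Out-of-range values in retained metabolites are imputed deterministically:
BELOW_LLOQ → lloq/2, ABOVE_ULOQ → uloq.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .panel import CensorFlag, PairedDataset, PanelSpec

log = logging.getLogger("pairedpls")

KEPT = "KEPT"
KEPT_BY_RESCUE = "KEPT_BY_RESCUE"
DROPPED = "DROPPED"

#: FilterReport column order (one row per metabolite).
REPORT_COLUMNS = [
    "metabolite_id", "n_below_lloq", "n_above_uloq", "n_ok",
    "oor_fraction", "rescue_stat", "rescue_p", "decision",
]


def out_of_range_summary(dataset: PairedDataset) -> pd.DataFrame:
    """Per-metabolite censoring counts; a pure function of the flag grid."""
    below = (dataset.flags == CensorFlag.BELOW_LLOQ).sum(axis=0)
    above = (dataset.flags == CensorFlag.ABOVE_ULOQ).sum(axis=0)
    n = dataset.n_samples
    return pd.DataFrame(
        {
            "metabolite_id": dataset.metabolites,
            "n_below_lloq": below,
            "n_above_uloq": above,
            "n_ok": n - below - above,
            "oor_fraction": (below + above) / n,
        }
    )


def chi_squared_rescue(
    n_oor_ic: int, n_ok_ic: int, n_oor_oc: int, n_ok_oc: int
) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on the 2×2
    out-of-range × crisis-status table.

    A zero margin makes the test degenerate; that case returns (0, 1) with a
    log note rather than an error.
    """
    table = np.array([[n_oor_ic, n_ok_ic], [n_oor_oc, n_ok_oc]], float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.info("chi_squared_rescue degenerate=zero_margin stat=0 p=1")
        return 0.0, 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        log.warning("chi_squared_rescue small_expected_cell min=%.2f", expected.min())
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, max(p, np.finfo(float).tiny)


def apply_quantitation_filter(
    dataset: PairedDataset,
    panel: PanelSpec,
    threshold: float = 0.20,
    alpha: float = 0.05,
) -> tuple[PairedDataset, pd.DataFrame]:
    """Drop metabolites with strictly more than ``threshold`` of their values
    out of the quantitation range, unless the chi-squared rescue finds the
    censoring pattern associated with crisis status (p < ``alpha``).

    Returns the filtered dataset (kept metabolites only, out-of-range cells
    imputed lloq/2 / uloq) and the per-metabolite FilterReport table.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    summary = out_of_range_summary(dataset)
    ic_rows = dataset.y == 1.0
    oor = dataset.flags != CensorFlag.OK

    stats_col: list[float | None] = []
    p_col: list[float | None] = []
    decisions: list[str] = []
    for j, frac in enumerate(summary["oor_fraction"]):
        if frac <= threshold:
            stats_col.append(None)
            p_col.append(None)
            decisions.append(KEPT)
            continue
        n_oor_ic = int(oor[ic_rows, j].sum())
        n_oor_oc = int(oor[~ic_rows, j].sum())
        n_ic, n_oc = int(ic_rows.sum()), int((~ic_rows).sum())
        stat, p = chi_squared_rescue(n_oor_ic, n_ic - n_oor_ic, n_oor_oc, n_oc - n_oor_oc)
        stats_col.append(stat)
        p_col.append(p)
        decisions.append(KEPT_BY_RESCUE if p < alpha else DROPPED)

    report = summary.assign(rescue_stat=stats_col, rescue_p=p_col, decision=decisions)
    report = report[REPORT_COLUMNS]

    keep_ids = [m for m, d in zip(dataset.metabolites, decisions) if d != DROPPED]
    filtered = dataset.subset_metabolites(keep_ids)
    lloq, uloq = panel.bounds(keep_ids)
    below = filtered.flags == CensorFlag.BELOW_LLOQ
    above = filtered.flags == CensorFlag.ABOVE_ULOQ
    n_imputed = int(below.sum() + above.sum())
    filtered.values[below] = (lloq / 2.0 * np.ones_like(filtered.values))[below]
    filtered.values[above] = (uloq * np.ones_like(filtered.values))[above]
    log.info(
        "apply_quantitation_filter kept=%d rescued=%d dropped=%d imputed_cells=%d",
        decisions.count(KEPT), decisions.count(KEPT_BY_RESCUE),
        decisions.count(DROPPED), n_imputed,
    )
    return filtered, report


def surviving_share_percent(n_kept: int, n_total: int) -> int:
    """Kept-metabolite share as the rounded percentage reported in QC text
    (e.g., 153 of 188 → 81)."""
    return int(round(100.0 * n_kept / n_total))
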