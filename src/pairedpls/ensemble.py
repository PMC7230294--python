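"""Systematic train/validation resampling ensemble with best-model selection.

The discrimination procedure never relies on a single train/validation
split.  With 30 patient pairs in the training-validation set and inner
training sets of 20 pairs there are C(30,20) = 30,045,015 possible splits;
conceptually these form a 20 × 30,045,015 matrix of combinations, which is
sampled every ``stride`` columns (stride 1287 yields exactly 23,345 models,
since 1287 × 23,345 = 30,045,015).  The matrix is never materialized:
combinations are produced on demand by lexicographic unranking.

Each sampled model is a paired PLS-DA fitted on its 20 training pairs
(multilevel decomposition and unit-variance scaling fitted on the training
samples only) and scored on the 10 held-out validation pairs by AUROC and
its p-value.  Models with validation AUROC ≥ 0.95 are the *best models*
(BMs); only BMs are re-scored on the outer test pairs and contribute to the
median aggregates: per-metabolite median VIP and oriented loading, and
per-sample median latent coordinates.  The ensemble passes when the median
test AUROC is at least 0.8 with median p-value at most 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil, comb

import numpy as np
import pandas as pd

from .mstats import Evaluation, auroc_pvalue
from .panel import PairedDataset, PanelSpec
from .pls import (
    PLSModel,
    apply_scaler,
    fit_plsda,
    fit_scaler,
    predict,
    project,
    vip,
    within_pair_deviations,
)

log = logging.getLogger("pairedpls")

PROGRESS_EVERY = 1000


class EnsembleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Combinatorics
# ---------------------------------------------------------------------------

def count_combinations(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k); arbitrary precision."""
    if n < 0 or k < 0 or k > n:
        raise EnsembleError(f"require 0 <= k <= n, got n={n}, k={k}")
    return comb(n, k)


def unrank_combination(rank: int, n: int, k: int) -> list[int]:
    """The ``rank``-th k-subset of {0..n−1} in lexicographic order.

    Bijective over ranks 0..C(n,k)−1: rank 0 is {0..k−1}, the last rank is
    {n−k..n−1}.
    """
    total = count_combinations(n, k)
    if not 0 <= rank < total:
        raise EnsembleError(f"rank {rank} out of range [0, {total})")
    out: list[int] = []
    x = 0
    r = rank
    for remaining in range(k, 0, -1):
        while True:
            block = comb(n - x - 1, remaining - 1)
            if r < block:
                break
            r -= block
            x += 1
        out.append(x)
        x += 1
    return out


def stride_indices(total: int, stride: int, offset: int = 0) -> list[int]:
    """Ranks offset, offset+stride, … below ``total``."""
    if total < 1 or stride < 1:
        raise EnsembleError("total and stride must be >= 1")
    if offset >= total:
        log.warning("stride_indices empty offset=%d total=%d", offset, total)
        return []
    return list(range(offset, total, stride))


# ---------------------------------------------------------------------------
# Outer split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedSplit:
    """Outer partition of patient pairs; pairs are never split across sets."""

    trainval_pairs: tuple[str, ...]
    test_pairs: tuple[str, ...]


def make_outer_split(pairs: list[str], seed: int = 0) -> PairedSplit:
    """Seeded shuffle of patient pairs into training-validation and test.

    The training-validation set gets min(30, ⌈3n/4⌉) pairs, so the two study
    arms come out as 30/10 (40 pairs) and 30/9 (39 pairs).
    """
    n = len(pairs)
    if n < 8:
        raise EnsembleError(f"need at least 8 pairs for an outer split, got {n}")
    if len(set(pairs)) != n:
        raise EnsembleError("duplicate patient ids")
    n_trainval = min(30, ceil(3 * n / 4))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [pairs[i] for i in order]
    return PairedSplit(
        trainval_pairs=tuple(sorted(shuffled[:n_trainval])),
        test_pairs=tuple(sorted(shuffled[n_trainval:])),
    )


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class EnsembleConfig:
    inner_train_size: int = 20
    stride: int | None = None      # None -> auto: max(1, C(n,k)//target_n_models)
    target_n_models: int = 23_345
    bm_threshold: float = 0.95
    vip_threshold: float = 1.0
    seed: int = 0
    multilevel: bool = True
    n_components: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.bm_threshold <= 1.0):
            raise EnsembleError("bm_threshold must lie in (0, 1]")
        if self.stride is not None and self.stride < 1:
            raise EnsembleError("stride must be >= 1")
        if self.target_n_models < 1:
            raise EnsembleError("target_n_models must be >= 1")


@dataclass
class _BMRecord:
    rank: int
    x_loadings: np.ndarray       # p × A
    oriented_loading: np.ndarray  # p
    vip: np.ndarray              # p
    coords: np.ndarray           # n_trainval_samples × A


@dataclass
class EnsembleResult:
    models: pd.DataFrame          # rank, val_auroc, val_p, is_bm, test_auroc, test_p
    split: PairedSplit
    metabolites: list[str]
    trainval_samples: list        # SampleKey per aggregated coordinate row
    median_vip: pd.Series
    median_loading: pd.Series
    median_coords: pd.DataFrame   # columns LV1..LVA, indexed like trainval_samples
    n_models: int
    n_bm: int
    n_models_auroc_ge_08: int
    median_val_auroc: float
    median_val_p: float
    median_test_auroc: float
    median_test_p: float
    passed: bool

    @property
    def bm_fraction(self) -> float:
        return self.n_bm / self.n_models if self.n_models else 0.0

    def summary(self) -> dict:
        return {
            "n_models": self.n_models,
            "n_bm": self.n_bm,
            "bm_fraction": self.bm_fraction,
            "n_models_auroc_ge_0.8": self.n_models_auroc_ge_08,
            "median_val_auroc": self.median_val_auroc,
            "median_val_p": self.median_val_p,
            "median_test_auroc": self.median_test_auroc,
            "median_test_p": self.median_test_p,
            "passed": bool(self.passed),
            "trainval_pairs": list(self.split.trainval_pairs),
            "test_pairs": list(self.split.test_pairs),
        }


# ---------------------------------------------------------------------------
# Fitting helpers
# ---------------------------------------------------------------------------

def _fit_one(
    dataset: PairedDataset,
    train_pairs: list[str],
    config: EnsembleConfig,
) -> tuple[PLSModel, np.ndarray | None]:
    rows = dataset.rows_for_patients(train_pairs)
    X_raw = dataset.values[rows]
    y = dataset.y[rows]
    grand = None
    if config.multilevel:
        grand = X_raw.mean(axis=0)
        X_raw = within_pair_deviations(X_raw, dataset.pair_ids[rows], grand_mean=grand)
    scaler = fit_scaler(X_raw, names=dataset.metabolites, allow_constant=True)
    model = fit_plsda(
        apply_scaler(scaler, X_raw),
        y,
        n_components=config.n_components,
        scaler=scaler,
        metabolites=dataset.metabolites,
        grand_mean=grand,
    )
    return model, grand


def _transform(
    model: PLSModel, dataset: PairedDataset, patient_ids: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(scaled X, y, rows) for held-out pairs using training-time parameters."""
    rows = dataset.rows_for_patients(patient_ids)
    X_raw = dataset.values[rows]
    if model.grand_mean is not None:
        X_raw = within_pair_deviations(
            X_raw, dataset.pair_ids[rows], grand_mean=model.grand_mean
        )
    return apply_scaler(model.scaler, X_raw), dataset.y[rows], rows


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_medians(
    bms: list[_BMRecord], metabolites: list[str]
) -> tuple[pd.Series, pd.Series, np.ndarray]:
    """Marginal medians over best models.

    Before aggregating coordinates, every BM's components are sign-aligned to
    the lowest-rank BM by the sign of the loading-vector inner product —
    without this, medians over sign-indeterminate latent axes are
    meaningless.  VIP is sign-free and oriented loadings already carry the
    positive-in-crisis convention, so they are aggregated directly.
    """
    if not bms:
        raise EnsembleError("empty best-model set")
    ref = bms[0]
    coords = []
    for bm in bms:
        signs = np.sign((bm.x_loadings * ref.x_loadings).sum(axis=0))
        signs[signs == 0] = 1.0
        coords.append(bm.coords * signs)
    median_vip = pd.Series(
        np.median([bm.vip for bm in bms], axis=0), index=metabolites, name="median_vip"
    )
    median_loading = pd.Series(
        np.median([bm.oriented_loading for bm in bms], axis=0),
        index=metabolites,
        name="median_loading",
    )
    return median_vip, median_loading, np.median(coords, axis=0)


# ---------------------------------------------------------------------------
# Main procedure
# ---------------------------------------------------------------------------

def run_ensemble(dataset: PairedDataset, config: EnsembleConfig) -> EnsembleResult:
    """Run the full systematic-resampling ensemble on a filtered dataset."""
    pairs = dataset.patients
    split = make_outer_split(pairs, seed=config.seed)
    tv = list(split.trainval_pairs)
    k = config.inner_train_size
    if not 1 <= k < len(tv):
        raise EnsembleError(
            f"inner_train_size must lie in [1, {len(tv) - 1}], got {k}"
        )
    total = count_combinations(len(tv), k)
    stride = config.stride or max(1, total // config.target_n_models)
    ranks = stride_indices(total, stride)
    log.info(
        "run_ensemble n_pairs=%d trainval=%d test=%d C(n,k)=%d stride=%d n_models=%d",
        len(pairs), len(tv), len(split.test_pairs), total, stride, len(ranks),
    )

    tv_rows = dataset.rows_for_patients(tv)
    tv_samples = [dataset.samples[i] for i in tv_rows]

    records = []
    bms: list[_BMRecord] = []
    test_evals: list[Evaluation] = []
    for i, rank in enumerate(ranks):
        train_pairs = [tv[j] for j in unrank_combination(rank, len(tv), k)]
        val_pairs = [p for p in tv if p not in set(train_pairs)]
        model, _ = _fit_one(dataset, train_pairs, config)
        Xv, yv, _ = _transform(model, dataset, val_pairs)
        ev = auroc_pvalue(
            predict(model, Xv), yv,
            seed=(config.seed * 1_000_003 + rank) % 2**31,
        )
        is_bm = ev.auroc >= config.bm_threshold
        rec = {
            "rank": rank,
            "val_auroc": ev.auroc,
            "val_p": ev.p_value,
            "is_bm": is_bm,
            "test_auroc": np.nan,
            "test_p": np.nan,
        }
        if is_bm:
            Xt, yt, _ = _transform(model, dataset, list(split.test_pairs))
            tev = auroc_pvalue(
                predict(model, Xt), yt,
                seed=(config.seed * 1_000_003 + rank + 1) % 2**31,
            )
            rec["test_auroc"], rec["test_p"] = tev.auroc, tev.p_value
            test_evals.append(tev)
            Xtv, _, _ = _transform(model, dataset, tv)
            bms.append(
                _BMRecord(
                    rank=rank,
                    x_loadings=model.x_loadings,
                    oriented_loading=model.oriented_loading,
                    vip=vip(model),
                    coords=project(model, Xtv),
                )
            )
        records.append(rec)
        if (i + 1) % PROGRESS_EVERY == 0:
            log.info("run_ensemble progress=%d/%d n_bm=%d", i + 1, len(ranks), len(bms))

    models = pd.DataFrame.from_records(records)
    n_bm = len(bms)
    if n_bm:
        median_vip, median_loading, med_coords = aggregate_medians(bms, dataset.metabolites)
        median_test_auroc = float(np.median([e.auroc for e in test_evals]))
        median_test_p = float(np.median([e.p_value for e in test_evals]))
    else:
        log.warning("run_ensemble zero_best_models threshold=%.2f", config.bm_threshold)
        median_vip = pd.Series(np.nan, index=dataset.metabolites, name="median_vip")
        median_loading = pd.Series(np.nan, index=dataset.metabolites, name="median_loading")
        med_coords = np.full((len(tv_samples), config.n_components), np.nan)
        median_test_auroc = float("nan")
        median_test_p = float("nan")

    passed = bool(n_bm and median_test_auroc >= 0.8 and median_test_p <= 0.05)
    median_coords = pd.DataFrame(
        med_coords, columns=[f"LV{a + 1}" for a in range(med_coords.shape[1])]
    )
    return EnsembleResult(
        models=models,
        split=split,
        metabolites=list(dataset.metabolites),
        trainval_samples=tv_samples,
        median_vip=median_vip,
        median_loading=median_loading,
        median_coords=median_coords,
        n_models=len(models),
        n_bm=n_bm,
        n_models_auroc_ge_08=int((models["val_auroc"] >= 0.8).sum()),
        median_val_auroc=float(models["val_auroc"].median()),
        median_val_p=float(models["val_p"].median()),
        median_test_auroc=median_test_auroc,
        median_test_p=median_test_p,
        passed=passed,
    )


def select_discriminant(
    result: EnsembleResult,
    panel: PanelSpec,
    vip_threshold: float = 1.0,
) -> pd.DataFrame:
    """Discriminant metabolites: median VIP ≥ threshold, sorted by VIP
    descending; direction 'increased' when the median oriented loading is
    positive (elevated in crisis), else 'decreased'."""
    table = pd.DataFrame(
        {
            "metabolite_id": result.metabolites,
            "class_label": [panel.entry(m).class_label for m in result.metabolites],
            "median_vip": result.median_vip.to_numpy(),
            "median_loading": result.median_loading.to_numpy(),
        }
    )
    table = table[table["median_vip"] >= vip_threshold].copy()
    table["direction"] = np.where(table["median_loading"] > 0, "increased", "decreased")
    return table.sort_values("median_vip", ascending=False).reset_index(drop=True)


def class_breakdown(selection: pd.DataFrame) -> dict[str, int]:
    """Per-class counts of a discriminant selection (report footer); the
    counts always sum to the number of selected metabolites."""
    return selection["class_label"].value_counts().to_dict()
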