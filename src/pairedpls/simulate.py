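"""Synthetic paired two-state metabolomics generator.

Emulates the crisis/steady-state paired design: each virtual patient
contributes one in-crisis (IC) and one out-of-crisis (OC) sample.  Per
metabolite, log-concentrations are bivariate normal across a patient's two
states with a configurable within-patient correlation (a shared patient
intercept on the log scale); crisis shifts the mean log-concentration by a
planted log-fold effect.  Concentrations are the exponentials, hence
lognormal and strictly positive.

Randomness is counter-split: each metabolite has its own substream derived
from the master seed, so adding or reordering metabolites never reshuffles
the draws of the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    CensorFlag,
    PairedDataset,
    PanelSpec,
    SampleKey,
    default_panel,
)

log = logging.getLogger("pairedpls")

_METAB_STREAM = 7  # spawn-key namespace for per-metabolite substreams


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSpec:
    """Planted crisis effect: difference of mean log-concentration IC − OC."""

    metabolite_id: str
    log_fold_effect: float


@dataclass
class SimulationConfig:
    n_pairs: int
    panel: PanelSpec
    effects: list[EffectSpec] = field(default_factory=list)
    within_patient_corr: float = 0.5
    baseline_log_mean: np.ndarray | None = None  # per metabolite, panel order
    baseline_log_sd: np.ndarray | None = None
    matrix: str = "plasma"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 4:
            raise SimulationError("n_pairs must be >= 4 (too small for any split)")
        if not (0.0 <= self.within_patient_corr < 1.0):
            raise SimulationError("within_patient_corr must lie in [0, 1)")
        ids = [e.metabolite_id for e in self.effects]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate metabolite in effects")
        unknown = set(ids) - set(self.panel.ids)
        if unknown:
            raise SimulationError(f"effect metabolites not in panel: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What was planted: the discriminant set and each true log-fold effect."""

    effects: dict[str, float]  # metabolite -> log-fold effect (0 omitted)

    @property
    def discriminant_set(self) -> set[str]:
        return {m for m, e in self.effects.items() if e != 0.0}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metabolite_id": list(self.effects), "log_fold_effect": list(self.effects.values())}
        )


def default_baselines(
    panel: PanelSpec,
    seed: int = 0,
    n_low_quant: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Draw per-metabolite baseline log-mean/log-sd from documented ranges.

    Baselines sit well inside each metabolite's quantitation window
    (log-uniform over its central 40%); log-sd is uniform on [0.2, 0.6],
    i.e., biological coefficients of variation of roughly 20–65%.  A chosen
    ``n_low_quant`` metabolites are instead placed *below* their LLOQ so that
    most of their values censor — these emulate poorly quantified analytes
    that the quantitation-range filter should discard.

    Returns (log_mean, log_sd, low_quant_ids).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    lloq, uloq = panel.bounds(panel.ids)
    lloq = np.where(lloq <= 0, uloq / 400.0, lloq)  # zero-LLOQ sentinel
    w = np.log(uloq) - np.log(lloq)
    log_mean = np.log(lloq) + rng.uniform(0.3, 0.7, len(panel)) * w
    log_sd = rng.uniform(0.2, 0.6, len(panel))
    low_ids: list[str] = []
    if n_low_quant:
        low_idx = rng.choice(len(panel), size=n_low_quant, replace=False)
        # mean below LLOQ -> 66–88% of draws fall under the limit
        z = rng.uniform(0.4, 1.2, n_low_quant)
        log_mean[low_idx] = np.log(lloq[low_idx]) - z * log_sd[low_idx]
        low_ids = [panel.ids[i] for i in sorted(low_idx)]
    return log_mean, log_sd, low_ids


def generate_dataset(config: SimulationConfig) -> tuple[PairedDataset, GroundTruth]:
    """Simulate a paired dataset; deterministic for a fixed config and seed."""
    panel = config.panel
    n, p = config.n_pairs, len(panel)
    if config.baseline_log_mean is None or config.baseline_log_sd is None:
        mu, sd, _ = default_baselines(panel, seed=config.seed)
        mu = config.baseline_log_mean if config.baseline_log_mean is not None else mu
        sd = config.baseline_log_sd if config.baseline_log_sd is not None else sd
    else:
        mu, sd = np.asarray(config.baseline_log_mean, float), np.asarray(config.baseline_log_sd, float)
    if len(mu) != p or len(sd) != p:
        raise SimulationError("baseline parameter length must match panel size")

    effect = np.zeros(p)
    for e in config.effects:
        effect[panel.ids.index(e.metabolite_id)] = e.log_fold_effect

    rho = config.within_patient_corr
    logx = np.empty((2 * n, p))
    for j in range(p):
        rng_j = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(_METAB_STREAM, j))
        )
        b = rng_j.normal(0.0, sd[j] * np.sqrt(rho), n)          # patient intercept
        eps = rng_j.normal(0.0, sd[j] * np.sqrt(1.0 - rho), (n, 2))
        logx[0::2, j] = mu[j] + effect[j] + b + eps[:, 0]        # IC rows
        logx[1::2, j] = mu[j] + b + eps[:, 1]                    # OC rows

    samples: list[SampleKey] = []
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        samples.append(SampleKey(pid, "IC", config.matrix))
        samples.append(SampleKey(pid, "OC", config.matrix))

    ds = PairedDataset(samples=samples, metabolites=list(panel.ids), values=np.exp(logx))
    ds = apply_loq_censoring(ds, panel)
    truth = GroundTruth(
        {e.metabolite_id: e.log_fold_effect for e in config.effects if e.log_fold_effect != 0.0}
    )
    log.info(
        "generate_dataset n_pairs=%d n_metabolites=%d n_effects=%d seed=%d",
        n, p, len(truth.effects), config.seed,
    )
    return ds, truth


def apply_loq_censoring(dataset: PairedDataset, panel: PanelSpec) -> PairedDataset:
    """Set censoring flags against the panel's LLOQ/ULOQ; values unchanged."""
    missing = set(dataset.metabolites) - set(panel.ids)
    if missing:
        raise SimulationError(f"metabolites absent from panel: {sorted(missing)}")
    lloq, uloq = panel.bounds(dataset.metabolites)
    flags = np.zeros(dataset.values.shape, dtype=np.int8)
    flags[dataset.values < lloq] = CensorFlag.BELOW_LLOQ
    flags[dataset.values > uloq] = CensorFlag.ABOVE_ULOQ
    return PairedDataset(
        samples=list(dataset.samples),
        metabolites=list(dataset.metabolites),
        values=dataset.values.copy(),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Demo scenarios mirroring the study shape
# ---------------------------------------------------------------------------

def demo_config(
    kind: str = "strong",
    n_pairs: int = 40,
    seed: int = 0,
    panel: PanelSpec | None = None,
    matrix: str = "plasma",
) -> tuple[SimulationConfig, list[str]]:
    """Build a study-shaped scenario over the default 188-metabolite panel.

    ``strong``  — 60 planted effects with |log-fold effect| uniform on
                  [0.5, 0.9] and random sign, placed only on well-quantified
                  metabolites; 35 poorly quantified metabolites (as in the
                  plasma arm, where 35 of 188 analytes failed the
                  quantitation-range screen).
    ``default`` — same layout with gentler effects, |effect| in [0.2, 0.8].
    ``null``    — no effects at all (label-independent data).

    Returns (config, low_quant_ids); the latter lists the metabolites planted
    below their LLOQ, for QC-filter checks.
    """
    if panel is None:
        panel = default_panel()
    if kind not in {"strong", "default", "null"}:
        raise SimulationError(f"unknown scenario kind {kind!r}")
    n_low = 35
    mu, sd, low_ids = default_baselines(panel, seed=seed, n_low_quant=n_low)
    effects: list[EffectSpec] = []
    if kind != "null":
        lo, hi = (0.5, 0.9) if kind == "strong" else (0.2, 0.8)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(23,)))
        eligible = [m for m in panel.ids if m not in set(low_ids)]
        chosen = rng.choice(len(eligible), size=60, replace=False)
        sizes = rng.uniform(lo, hi, 60) * rng.choice([-1.0, 1.0], 60)
        effects = [EffectSpec(eligible[i], float(s)) for i, s in zip(chosen, sizes)]
    cfg = SimulationConfig(
        n_pairs=n_pairs,
        panel=panel,
        effects=effects,
        within_patient_corr=0.5,
        baseline_log_mean=mu,
        baseline_log_sd=sd,
        matrix=matrix,
        seed=seed,
    )
    return cfg, low_ids
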