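"""Paired PLS-DA: scaling, within-patient decomposition, NIPALS, VIP.

The classifier is PLS1 regression of a binary class code (IC=1, OC=0) on the
unit-variance-scaled metabolite matrix, fitted by the NIPALS sequence

    w_a ∝ X_a' y   (unit norm),   t_a = X_a w_a,
    p_a = X_a' t_a / (t_a' t_a),  q_a = y' t_a / (t_a' t_a),
    X_{a+1} = X_a − t_a p_a'                       (deflation),

with two components by default (score plots live in the LV1/LV2 plane).

"Paired" enters twice: resampling never splits a patient's IC/OC pair
(handled by the ensemble), and optionally the model is fitted on
within-patient deviations (multilevel decomposition: each value is replaced
by value − patient mean + grand mean), which removes the between-patient
variance component before scaling.

VIP_j = sqrt( p · Σ_a q_a²(t_a't_a) w_ja² / Σ_a q_a²(t_a't_a) ), so that
Σ_j VIP_j² = p; VIP ≥ 1 marks variables that matter for the discrimination.
The reported ``oriented_loading`` is the first-component X-loading signed so
that positive means elevated in crisis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel import PairedDataset

log = logging.getLogger("pairedpls")

DEFLATION_TOL = 1e-12  # stop when t't falls below this


class PLSError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingParams:
    """Per-column mean and sample sd (n−1 denominator) from a training set."""

    mean: np.ndarray
    sd: np.ndarray


def fit_scaler(
    X: np.ndarray,
    names: list[str] | None = None,
    allow_constant: bool = False,
) -> ScalingParams:
    """Fit unit-variance scaling.  A constant column is an error by default
    (it should have been filtered); with ``allow_constant`` it is scaled to
    all-zeros instead — inside the resampling ensemble a column can lose its
    variance within one training subset (e.g., every pair censored and
    imputed identically) even though the dataset-wide filter passed, and a
    zero column simply contributes nothing to the fit."""
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise PLSError("need at least 2 training samples to fit a scaler")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.where(sd <= 0)[0]
    if bad.size:
        labels = [names[j] for j in bad] if names else list(bad)
        if not allow_constant:
            raise PLSError(f"constant columns cannot be unit-variance scaled: {labels}")
        log.info("fit_scaler constant_columns_zeroed=%s", labels)
        sd = sd.copy()
        sd[bad] = 1.0
    return ScalingParams(mean=mean, sd=sd)


def apply_scaler(params: ScalingParams, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, float) - params.mean) / params.sd


# ---------------------------------------------------------------------------
# Multilevel (within-patient) decomposition
# ---------------------------------------------------------------------------

def within_pair_deviations(
    X: np.ndarray, pair_ids: np.ndarray, grand_mean: np.ndarray | None = None
) -> np.ndarray:
    """Replace each value by value − patient mean + grand mean.

    For a complete pair (a, b) with grand mean g this yields
    (g + (a−b)/2, g − (a−b)/2): the between-patient level is removed and the
    two states are symmetric about g.  ``grand_mean`` defaults to the column
    means of ``X`` itself; pass the training-set means when transforming
    held-out samples so nothing leaks.
    """
    X = np.asarray(X, float)
    pair_ids = np.asarray(pair_ids)
    if grand_mean is None:
        grand_mean = X.mean(axis=0)
    out = np.empty_like(X)
    for pid in np.unique(pair_ids):
        rows = pair_ids == pid
        if rows.sum() != 2:
            raise PLSError(f"patient {pid!r} does not form a complete pair")
        out[rows] = X[rows] - X[rows].mean(axis=0) + grand_mean
    return out


def multilevel_decompose(dataset: PairedDataset) -> PairedDataset:
    """Dataset-level within-patient decomposition (flags carried through)."""
    values = within_pair_deviations(dataset.values, dataset.pair_ids)
    return PairedDataset(
        samples=list(dataset.samples),
        metabolites=list(dataset.metabolites),
        values=values,
        flags=dataset.flags.copy(),
    )


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted paired PLS-DA model.

    Weights/loadings are column-stacked per component; ``scores`` are the
    training-score vectors.  ``scaler`` (and, with multilevel on,
    ``grand_mean``) reproduce the training-time preprocessing for new data.
    """

    weights: np.ndarray       # p × A, unit-norm columns
    x_loadings: np.ndarray    # p × A
    y_loadings: np.ndarray    # A
    scores: np.ndarray        # n × A
    y_mean: float
    scaler: ScalingParams
    metabolites: list[str] = field(default_factory=list)
    grand_mean: np.ndarray | None = None  # set when multilevel was applied

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def vip(self) -> np.ndarray:
        return vip(self)

    @property
    def oriented_loading(self) -> np.ndarray:
        """First-component X-loading, sign-oriented so positive ⇔ elevated in
        crisis (the first y-loading is made non-negative)."""
        sign = 1.0 if self.y_loadings[0] >= 0 else -1.0
        return sign * self.x_loadings[:, 0]

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "y_mean": self.y_mean,
            "scaler_mean": self.scaler.mean.tolist(),
            "scaler_sd": self.scaler.sd.tolist(),
            "metabolites": self.metabolites,
            "grand_mean": None if self.grand_mean is None else self.grand_mean.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(d["weights"]),
            x_loadings=np.array(d["x_loadings"]),
            y_loadings=np.array(d["y_loadings"]),
            scores=np.array(d["scores"]),
            y_mean=float(d["y_mean"]),
            scaler=ScalingParams(np.array(d["scaler_mean"]), np.array(d["scaler_sd"])),
            metabolites=list(d["metabolites"]),
            grand_mean=None if d["grand_mean"] is None else np.array(d["grand_mean"]),
        )


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 2,
    scaler: ScalingParams | None = None,
    metabolites: list[str] | None = None,
    grand_mean: np.ndarray | None = None,
) -> PLSModel:
    """Fit PLS1 on an already unit-variance-scaled matrix ``X`` and class
    codes ``y`` (IC=1/OC=0; centered internally).

    Sign convention: each weight vector is flipped so its largest-|entry|
    coordinate is positive (removes NIPALS sign indeterminacy); the
    y-loading carries the compensating sign.  Deflation stops early, with a
    log note, if a component's score norm t't falls below tolerance.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if len(y) != n:
        raise PLSError("X and y length mismatch")
    classes = np.unique(y)
    if len(classes) != 2 or min(np.sum(y == c) for c in classes) < 2:
        raise PLSError("need at least 2 samples per class")
    if not 1 <= n_components <= min(n - 1, p):
        raise PLSError(f"n_components must lie in [1, min(n-1, p)], got {n_components}")

    y_mean = float(y.mean())
    Xa = X.copy()
    ya = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    fitted = 0
    for a in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < DEFLATION_TOL:
            log.info("fit_plsda early_stop=zero_covariance component=%d", a + 1)
            break
        w /= norm
        if w[np.argmax(np.abs(w))] < 0:  # fix sign indeterminacy
            w = -w
        t = Xa @ w
        tt = float(t @ t)
        if tt < DEFLATION_TOL:
            log.info("fit_plsda early_stop=degenerate_scores component=%d", a + 1)
            break
        W[:, a] = w
        T[:, a] = t
        P[:, a] = Xa.T @ t / tt
        q[a] = float(ya @ t / tt)
        Xa = Xa - np.outer(t, P[:, a])
        fitted = a + 1
    if fitted == 0:
        raise PLSError("no PLS component could be extracted (X'y vanished)")
    if scaler is None:
        scaler = ScalingParams(mean=np.zeros(p), sd=np.ones(p))
    return PLSModel(
        weights=W[:, :fitted],
        x_loadings=P[:, :fitted],
        y_loadings=q[:fitted],
        scores=T[:, :fitted],
        y_mean=y_mean,
        scaler=scaler,
        metabolites=metabolites or [],
        grand_mean=grand_mean,
    )


def project(model: PLSModel, X_scaled: np.ndarray) -> np.ndarray:
    """Latent-variable coordinates (n × A) of already-scaled samples,
    computed with the training weights and deflation loadings."""
    X_scaled = np.asarray(X_scaled, float)
    if X_scaled.shape[1] != model.weights.shape[0]:
        raise PLSError(
            f"metabolite mismatch: model has {model.weights.shape[0]} columns, "
            f"input has {X_scaled.shape[1]}"
        )
    Xa = X_scaled.copy()
    T = np.zeros((Xa.shape[0], model.n_components))
    for a in range(model.n_components):
        T[:, a] = Xa @ model.weights[:, a]
        Xa = Xa - np.outer(T[:, a], model.x_loadings[:, a])
    return T


def predict(model: PLSModel, X_scaled: np.ndarray) -> np.ndarray:
    """Continuous class score ŷ = ȳ + Σ_a q_a t_a for scaled samples; higher
    means more crisis-like."""
    return model.y_mean + project(model, X_scaled) @ model.y_loadings


def regression_vector(model: PLSModel) -> np.ndarray:
    """B = W (P'W)^{-1} q, so that ŷ = ȳ + X_scaled · B (algebraic identity
    with :func:`predict`)."""
    W, P, q = model.weights, model.x_loadings, model.y_loadings
    return W @ np.linalg.solve(P.T @ W, q)


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection; Σ_j VIP_j² equals the number of
    metabolites."""
    p = model.weights.shape[0]
    ssy = model.y_loadings**2 * (model.scores**2).sum(axis=0)  # q_a² t_a't_a
    total = ssy.sum()
    if total <= 0:
        raise PLSError("model explains no y-variance; VIP undefined")
    return np.sqrt(p * (model.weights**2 @ ssy) / total)
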