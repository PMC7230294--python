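"""Classifier scoring: AUROC, its significance, and the PCA sanity check.

AUROC is computed in Mann–Whitney form — the fraction of (positive,
negative) score pairs where the positive outranks the negative, ties
counting one half — so it equals U/(n₊·n₋).  The p-value tests AUROC = 0.5
(i.e., classifier no better than random) two-sided:

* **exact** — the full permutation distribution of U, computed by dynamic
  programming over rank sums, when both class counts are ≤ 12 and the scores
  are tie-free (validation sets here are 10 vs 10);
* **mc_permutation** — seeded Monte-Carlo label permutation (10,000 draws)
  when ties make the rank-sum distribution inapplicable;
* **normal_approx** — tie- and continuity-corrected normal approximation for
  larger sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

log = logging.getLogger("pairedpls")

EXACT_MAX_N = 12
MC_DRAWS = 10_000


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class Evaluation:
    auroc: float
    p_value: float
    n_pos: int
    n_neg: int
    method: str  # exact | mc_permutation | normal_approx


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ScoringError("both classes must be present")
    return pos, neg


def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC with ties counted 0.5, positives = label 1."""
    pos, neg = _split(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


@lru_cache(maxsize=None)
def _exact_u_counts(n_pos: int, n_neg: int) -> np.ndarray:
    """Counts of each U value (0..n_pos·n_neg) over all C(n,+) equally likely
    tie-free labelings; recurrence N(u;a,b) = N(u−b;a−1,b) + N(u;a,b−1)."""
    max_u = n_pos * n_neg
    table = [[None] * (n_neg + 1) for _ in range(n_pos + 1)]
    for b in range(n_neg + 1):
        arr = np.zeros(max_u + 1, dtype=float)
        arr[0] = 1.0
        table[0][b] = arr
    for a in range(1, n_pos + 1):
        arr = np.zeros(max_u + 1, dtype=float)
        arr[0] = 1.0
        table[a][0] = arr
        for b in range(1, n_neg + 1):
            shifted = np.zeros(max_u + 1, dtype=float)
            shifted[b:] = table[a - 1][b][: max_u + 1 - b]
            table[a][b] = shifted + table[a][b - 1]
    return table[n_pos][n_neg]


def _exact_two_sided_p(u: float, n_pos: int, n_neg: int) -> float:
    counts = _exact_u_counts(n_pos, n_neg)
    mu = n_pos * n_neg / 2.0
    dev = abs(u - mu)
    support = np.arange(len(counts))
    mask = np.abs(support - mu) >= dev - 1e-9
    return float(counts[mask].sum() / counts.sum())


def auroc_pvalue(scores, labels, seed: int = 0) -> Evaluation:
    """Two-sided test of AUROC = 0.5 via the Mann–Whitney U statistic."""
    pos, neg = _split(scores, labels)
    n_pos, n_neg = len(pos), len(neg)
    a = auroc(scores, labels)
    u = a * n_pos * n_neg
    pooled = np.concatenate([pos, neg])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if max(n_pos, n_neg) <= EXACT_MAX_N and not has_ties:
        p = _exact_two_sided_p(u, n_pos, n_neg)
        method = "exact"
    elif max(n_pos, n_neg) <= EXACT_MAX_N:
        rng = np.random.default_rng(seed)
        mu = n_pos * n_neg / 2.0
        dev = abs(u - mu)
        hits = 0
        lab = np.array([1] * n_pos + [0] * n_neg)
        for _ in range(MC_DRAWS):
            perm = rng.permutation(lab)
            u_perm = auroc(pooled, perm) * n_pos * n_neg
            if abs(u_perm - mu) >= dev - 1e-9:
                hits += 1
        p = (hits + 1) / (MC_DRAWS + 1)
        method = "mc_permutation"
    else:
        n = n_pos + n_neg
        mu = n_pos * n_neg / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
        var = n_pos * n_neg / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)  # continuity corr.
            p = float(2.0 * stats.norm.sf(z))
        method = "normal_approx"
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return Evaluation(auroc=a, p_value=p, n_pos=n_pos, n_neg=n_neg, method=method)


# ---------------------------------------------------------------------------
# PCA check
# ---------------------------------------------------------------------------

def pca_scores(
    X: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """PCA coordinates of the column-centered, unit-variance-scaled table.

    Returns (coordinates n × A, explained-variance fractions).  Requested
    components beyond the matrix rank are truncated with a log note.
    """
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ScoringError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if len(S) else 0
    if n_components > rank:
        log.info("pca_scores truncated n_components=%d rank=%d", n_components, rank)
        n_components = rank
    coords = U[:, :n_components] * S[:n_components]
    explained = S**2 / (S**2).sum()
    return coords, explained[:n_components]


def pca_outliers(coords: np.ndarray, n_sd: float = 3.0) -> list[int]:
    """Indices of samples beyond ``n_sd`` standard deviations on any
    component; reported only, never auto-removed."""
    coords = np.asarray(coords, float)
    sd = coords.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    mask = (np.abs(coords / sd) > n_sd).any(axis=1)
    return list(np.where(mask)[0])
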