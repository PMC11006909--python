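"""Candidate-feature assembly: interaction expansion, stepwise selection, consensus.

Feature selection runs once per cross-validation training set; features kept
are those a bidirectional AIC-guided stepwise linear regression retains from
the level-1 features plus all their pairwise products. Aggregating the
per-run selections and keeping features chosen at least ``cutoff`` times
implements the consensus filter whose cutoff is itself a tuned
hyperparameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERACTION_SEP = " x "


def interaction_name(a: str, b: str) -> str:
    return INTERACTION_SEP.join(sorted((a, b)))


def expand_interactions(features: pd.DataFrame) -> pd.DataFrame:
    """Add all pairwise products of the current features as named candidates.

    Product columns are named "A x B" with the factor names sorted, so the
    candidate set is order-independent.
    """
    names = list(features.columns)
    out = features.copy()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[interaction_name(a, b)] = features[a] * features[b]
    return out


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood AIC up to a constant; k counts slope terms,
    # intercept and error variance add a fixed offset shared by all models
    return n * np.log(max(rss, 1e-300) / n) + 2.0 * (k + 2)


def _rss_of(G, g, yty, idx, ridge):
    if not idx:
        return yty
    Gi = G[np.ix_(idx, idx)] + ridge * np.eye(len(idx))
    coef = np.linalg.solve(Gi, g[idx])
    return max(yty - float(g[idx] @ coef), 0.0)


def stepwise_select(X: pd.DataFrame, y, max_steps: int = 200) -> list[str]:
    """Bidirectional stepwise linear regression minimizing AIC.

    Starts from the intercept-only model; each iteration makes the best
    forward addition, then prunes any included feature whose removal lowers
    AIC. All candidate evaluations per step reduce to one triangular solve on
    the centered Gram matrix. Deterministic: ties are broken by candidate
    name. Exact duplicate columns are dropped with a warning (collinearity
    itself is allowed).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= 3:
        raise ValueError("need more than 3 observations")
    # drop exact duplicates, keeping the first by name order
    seen: dict[bytes, str] = {}
    keep = []
    for name in sorted(X.columns):
        key = np.ascontiguousarray(X[name].to_numpy(dtype=float)).tobytes()
        if key in seen:
            warnings.warn(f"duplicate candidate {name!r} dropped "
                          f"(identical to {seen[key]!r})")
        else:
            seen[key] = name
            keep.append(name)
    names = keep
    m = len(names)
    if m == 0:
        return []
    # center columns and the response: the intercept is implicit
    A = X[names].to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    yc = y - y.mean()
    G = A.T @ A
    g = A.T @ yc
    yty = float(yc @ yc)
    ridge = 1e-10 * max(float(np.diag(G).mean()), 1.0)

    selected: list[int] = []
    current_aic = _aic(yty, n, 0)
    for _ in range(max_steps):
        changed = False
        # forward sweep: evaluate every addition at once
        avail = [j for j in range(m) if j not in selected]
        if avail:
            if selected:
                idx = selected
                Gi = G[np.ix_(idx, idx)] + ridge * np.eye(len(idx))
                L = np.linalg.cholesky(Gi)
                W = np.linalg.solve(L, G[np.ix_(idx, avail)])
                Ly = np.linalg.solve(L, g[idx])
                denom = np.diag(G)[avail] - (W ** 2).sum(axis=0)
                numer = g[avail] - W.T @ Ly
                base_rss = max(yty - float(Ly @ Ly), 0.0)
            else:
                denom = np.diag(G)[avail].copy()
                numer = g[avail]
                base_rss = yty
            with np.errstate(divide="ignore", invalid="ignore"):
                gain = np.where(denom > 1e-12, numer ** 2 / denom, 0.0)
            rss_new = np.maximum(base_rss - gain, 0.0)
            aics = np.array([_aic(r, n, len(selected) + 1) for r in rss_new])
            j_best = int(np.argmin(aics))
            if aics[j_best] < current_aic - 1e-10:
                selected.append(avail[j_best])
                current_aic = float(aics[j_best])
                changed = True
        # backward: prune while it helps
        while selected:
            best_j, best_aic = None, current_aic
            for j in selected:
                rest = [i for i in selected if i != j]
                a = _aic(_rss_of(G, g, yty, rest, ridge), n, len(rest))
                if a < best_aic - 1e-10:
                    best_j, best_aic = j, a
            if best_j is None:
                break
            selected.remove(best_j)
            current_aic = best_aic
            changed = True
        if not changed:
            break
    return sorted(names[j] for j in selected)


@dataclass(frozen=True)
class SelectionRecord:
    """Features retained by one stepwise run (one inner cross-validation fold)."""

    run_id: str
    selected: frozenset = field(default_factory=frozenset)


def consensus_select(records: list[SelectionRecord],
                     cutoff: int) -> list[str]:
    """Features selected in at least ``cutoff`` of the given runs."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    if cutoff > len(records):
        warnings.warn(f"cutoff {cutoff} exceeds the {len(records)} available "
                      "runs; no feature can qualify")
        return []
    counts: dict[str, int] = {}
    for r in records:
        for f in r.selected:
            counts[f] = counts.get(f, 0) + 1
    return sorted(f for f, c in counts.items() if c >= cutoff)


def selection_counts(records: list[SelectionRecord]) -> pd.DataFrame:
    """Per-feature selection frequency over all runs (pipelines x folds)."""
    counts: dict[str, int] = {}
    for r in records:
        for f in r.selected:
            counts[f] = counts.get(f, 0) + 1
    df = pd.DataFrame(sorted(counts.items()), columns=["feature", "count"])
    return df.sort_values(["count", "feature"],
                          ascending=[False, True]).reset_index(drop=True)
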