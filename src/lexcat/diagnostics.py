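"""Responder classification, confusion diagnostics, and auxiliary statistics.

A participant is an *observed responder* when the measured training effect is
strictly positive; a *predicted responder* when the predicted benefit reaches
the decision threshold (boundary inclusive). The threshold is chosen to
balance sensitivity and specificity by maximizing Youden's J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold_pct: float = float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        d = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def n_selected(self) -> int:
        return self.tp + self.fp

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "threshold_pct": self.threshold_pct,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy, "precision": self.precision,
                "n_selected": self.n_selected}


def classify(predicted_pct, threshold_pct: float) -> np.ndarray:
    """Predicted responder iff predicted benefit >= threshold (inclusive)."""
    if not math.isfinite(threshold_pct) and not math.isinf(threshold_pct):
        raise ValueError("threshold must not be NaN")
    return (np.asarray(predicted_pct, dtype=float) >= threshold_pct
            ).astype(int)


def confusion(predicted_labels, observed_effects,
              threshold_pct: float = float("nan")) -> ConfusionSummary:
    """Confusion counts against observed responders (training effect > 0)."""
    pl = np.asarray(predicted_labels, dtype=int)
    obs = np.asarray(observed_effects, dtype=float) > 0
    if pl.size != obs.size:
        raise ValueError("length mismatch")
    return ConfusionSummary(
        tp=int(np.sum(pl & obs)), fp=int(np.sum(pl & ~obs)),
        tn=int(np.sum(~pl.astype(bool) & ~obs)),
        fn=int(np.sum(~pl.astype(bool) & obs)),
        threshold_pct=threshold_pct)


def optimize_threshold(predicted, observed_effects) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between sorted unique predictions plus the
    two open extremes; ties go to higher accuracy, then the smaller value.
    """
    p = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed_effects, dtype=float) > 0
    if obs.all() or (~obs).all():
        raise ValueError("need both responders and non-responders")
    uniq = np.unique(p)
    candidates = [-math.inf]
    candidates += [(a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])]
    candidates += [math.inf]
    best = None
    for th in candidates:
        c = confusion(classify(p, th), observed_effects, threshold_pct=th)
        key = (round(c.youden_j, 12), round(c.accuracy, 12), -th)
        if best is None or key > best[0]:
            best = (key, th)
    return float(best[1])


def selection_benefit(observed_effects, predicted_labels) -> dict:
    """Mean observed training effect, all participants vs predicted responders."""
    obs = np.asarray(observed_effects, dtype=float)
    lab = np.asarray(predicted_labels, dtype=int).astype(bool)
    if not lab.any():
        raise ValueError("no participant selected")
    return {"mean_all": float(obs.mean()),
            "mean_selected": float(obs[lab].mean()),
            "n_all": int(obs.size), "n_selected": int(lab.sum())}


def feature_relevance(fold_t_values: list[dict]) -> pd.DataFrame:
    """Signed median and SD of per-feature regression t values across folds.

    Features absent from some folds aggregate over the folds where present;
    |median t| > 2 is flagged as significant.
    """
    names = sorted({k for d in fold_t_values for k in d})
    rows = []
    for name in names:
        vals = np.array([d[name] for d in fold_t_values if name in d])
        med = float(np.median(vals))
        rows.append({"feature": name, "median_t": med,
                     "sd_t": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                     "n_folds": int(vals.size),
                     "significant": abs(med) > 2.0})
    return pd.DataFrame(rows).sort_values(
        "median_t", key=lambda s: -s.abs()).reset_index(drop=True)


def power_one_sample_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided one-sample t test via the noncentral t.

    ncp = d * sqrt(n), df = n - 1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    ncp = d * math.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = (stats.nct.sf(tcrit, df, ncp)
             + stats.nct.cdf(-tcrit, df, ncp))
    return float(power)
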