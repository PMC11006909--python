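"""Trial filtering, reading-speed harmonization, and pre/post outcome statistics."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RT_MIN_MS = 300.0
RT_MAX_MS = 4000.0


def filter_trials(trials: pd.DataFrame, rt_min: float = RT_MIN_MS,
                  rt_max: float = RT_MAX_MS) -> pd.DataFrame:
    """Keep trials with rt_min <= rt_ms <= rt_max (bounds inclusive).

    Response times below 300 ms (anticipatory guesses) and above 4000 ms are
    excluded before model fitting. Idempotent.
    """
    if trials.empty:
        return trials.copy()
    keep = (trials["rt_ms"] >= rt_min) & (trials["rt_ms"] <= rt_max)
    n_fast = int((trials["rt_ms"] < rt_min).sum())
    n_slow = int((trials["rt_ms"] > rt_max).sum())
    logger.info("filter_trials: removed %d fast and %d slow of %d trials",
                n_fast, n_slow, len(trials))
    out = trials.loc[keep].copy()
    out.attrs["filter_report"] = {"n_input": len(trials), "n_fast": n_fast,
                                  "n_slow": n_slow, "n_kept": len(out)}
    return out


def log_rt(trials: pd.DataFrame, column: str = "rt_ms") -> pd.Series:
    """Natural-log response times (the mixed models fit log RT)."""
    return np.log(trials[column].astype(float))


def harmonize_sls(count_correct: int, version_duration_s: int,
                  multiplier: float = 1.0) -> int:
    """Put reading-speed counts from 90 s and 180 s test versions on one scale.

    Counts from the short (90 s) version are duplicated; ``multiplier`` allows
    dataset-specific corrections (e.g., scaling down a score from an
    administration that ran over time).
    """
    if version_duration_s == 90:
        count = 2 * count_correct
    elif version_duration_s == 180:
        count = count_correct
    else:
        raise ValueError(f"unknown SLS version duration {version_duration_s}")
    return int(round(count * multiplier))


def training_effect(pre: float, post: float) -> float:
    """Percent change in correctly processed sentences, pre to post."""
    if pre <= 0:
        raise ValueError("training effect undefined for pre <= 0")
    return 100.0 * (post - pre) / pre


def outlier_flag(effects, k: float = 2.0) -> np.ndarray:
    """Flag values outside mean +/- k sample standard deviations (ddof=1)."""
    x = np.asarray(effects, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - x.mean()) > k * sd


def one_sample_t(effects) -> dict:
    """Two-sided one-sample t-test of the training effects against zero."""
    x = np.asarray(effects, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    n = x.size
    if sd == 0:
        t = math.copysign(math.inf, m) if m != 0 else float("nan")
        return {"M": m, "SD": sd, "t": t, "df": n - 1, "p": 0.0 if m else
                float("nan"), "degenerate": True}
    t = m / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return {"M": m, "SD": sd, "t": t, "df": n - 1, "p": float(p),
            "degenerate": False}


def t_from_summary(mean: float, sd: float, n: int) -> dict:
    """One-sample t statistic recomputed from reported (M, SD, n)."""
    if sd <= 0 or n < 2:
        raise ValueError("need sd > 0 and n >= 2")
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return {"t": float(t), "df": n - 1, "p": float(p)}


def participant_outcomes(participants: pd.DataFrame,
                         outlier_k: float | None = None) -> pd.DataFrame:
    """Harmonized pre/post counts, percent training effect, and outlier flags."""
    df = participants.copy()
    df["sls_pre_h"] = [harmonize_sls(int(c), int(d)) for c, d in
                       zip(df["sls_pre"], df["sls_version_duration_s"])]
    df["sls_post_h"] = [harmonize_sls(int(c), int(d)) for c, d in
                        zip(df["sls_post"], df["sls_version_duration_s"])]
    df["training_effect_pct"] = [training_effect(a, b) for a, b in
                                 zip(df["sls_pre_h"], df["sls_post_h"])]
    if outlier_k is not None:
        df["outlier_flag"] = outlier_flag(df["training_effect_pct"],
                                          k=outlier_k)
    else:
        df["outlier_flag"] = False
    return df
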