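"""Consensus-nested leave-one-out cross-validated prediction of training benefit.

The pipeline grid crosses three hyperparameters: the feature-extraction mixed
model (which random-slope features exist), the consensus cutoff of the
stepwise feature selection, and the regression learner (multiple regression,
linear- and radial-kernel support vector machines, random forest). The outer
leave-one-out loop yields one unbiased prediction per participant; the inner
leave-one-out loop, run on each outer training set, picks per inner fold the
grid point with the smallest squared error on the inner held-out participant,
and the *modal* grid point across inner folds — the consensus — is applied to
the outer fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from .features import (SelectionRecord, consensus_select, expand_interactions,
                       stepwise_select)
from .lmm import (ModelSpec, build_design, extract_participant_features,
                  factorial_terms, fit_lmm, participant_metadata,
                  predict_participant_blups, winning_model_spec)

LEARNERS = ("multiple_regression", "svm_linear", "svm_radial", "random_forest")

DEFAULT_CUTOFFS = (5, 10, 15, 20, 30, 40, 50, 60, 70)

DEFAULT_LEARNER_SETTINGS = {
    "svm_cost": 1.0,
    "svm_epsilon": 0.1,
    "rf_n_trees": 500,
}


@dataclass(frozen=True)
class PipelineConfig:
    """One point of the (extraction model x cutoff x learner) grid."""

    extraction_model_id: str
    selection_cutoff: int
    learner: str
    learner_settings: tuple = ()

    def key(self) -> tuple:
        return (self.extraction_model_id, self.selection_cutoff, self.learner)

    def label(self) -> str:
        return f"{self.extraction_model_id}|cutoff={self.selection_cutoff}" \
               f"|{self.learner}"


@dataclass
class PipelineGrid:
    """The hyperparameter grid searched by the nested cross-validation."""

    extraction_models: dict
    cutoffs: tuple = DEFAULT_CUTOFFS
    learners: tuple = LEARNERS
    learner_settings: dict = field(
        default_factory=lambda: dict(DEFAULT_LEARNER_SETTINGS))

    def configs(self) -> list[PipelineConfig]:
        settings = tuple(sorted(self.learner_settings.items()))
        return [PipelineConfig(m, c, l, settings)
                for m in sorted(self.extraction_models)
                for c in self.cutoffs
                for l in self.learners]

    def size(self) -> int:
        return (len(self.extraction_models) * len(self.cutoffs)
                * len(self.learners))

    def max_selection_frequency(self, n_outer_folds: int) -> int:
        """Ceiling of the feature selection count over extraction models x
        selection procedures x outer folds (learners share selections)."""
        return (len(self.extraction_models) * len(self.cutoffs)
                * n_outer_folds)


def default_extraction_models() -> dict:
    """Twenty extraction mixed models of graded complexity.

    Five core structures for the uncertainty/word-likeness/sequence terms
    crossed with four covariate sets; the most complex entry is the winning
    full-factorial formula.
    """
    u, o, s = "lcm_uncertainty", "old20", "log_seq_index"
    cores = [
        ((u,),),
        ((u,), (o,), (s,)),
        tuple(factorial_terms(u, o)) + ((s,),),
        tuple(factorial_terms(u, s)) + ((o,),),
        tuple(factorial_terms(u, o, s)),
    ]
    covsets = [(), (("lexicality",),),
               (("lexicality",), ("log_freq",)),
               (("lexicality",), ("log_freq",), ("error",))]
    models = {}
    i = 0
    for core in cores:
        for cov in covsets:
            i += 1
            within = tuple(core) + cov
            fixed = within + (("sls_pre",), ("week",))
            models[f"m{i:02d}"] = ModelSpec(
                fixed_terms=fixed, participant_slope_terms=within)
    assert models["m20"] == winning_model_spec()
    return models


def default_grid() -> PipelineGrid:
    return PipelineGrid(extraction_models=default_extraction_models())


class PrecomputedFeatures:
    """Feature source backed by ready-made participant-level tables.

    Used when the features do not depend on the training split (they are
    outcome-free), e.g. truth-derived features in recovery simulations. Keeps
    a lineage log of the training sets requested, for leakage auditing.
    """

    def __init__(self, features_by_model: dict | pd.DataFrame):
        if isinstance(features_by_model, pd.DataFrame):
            features_by_model = {"m01": features_by_model}
        self.features_by_model = features_by_model
        self.model_ids = sorted(features_by_model)
        self.lineage: list[tuple[str, frozenset]] = []

    def extract(self, model_id: str, train_ids) -> pd.DataFrame:
        self.lineage.append((model_id, frozenset(train_ids)))
        return self.features_by_model[model_id]


class LMMFeatureExtractor:
    """Per-fold mixed-model feature extraction.

    For a given training set, the extraction model is fitted by REML on the
    training participants' session-1 trials only; the held-out participant's
    random-slope features are the conditional modes given that fit, so their
    trials and outcome enter no estimation. Fits are cached per
    (model, training set).
    """

    def __init__(self, trials: pd.DataFrame, participants: pd.DataFrame,
                 models: dict, session: int = 1):
        t = trials[trials["session"] == session].copy()
        cols = ["id", "week", "sls_pre"]
        if "sls_pre_h" in participants.columns:
            pmap = participants[["id", "week", "sls_pre_h"]].rename(
                columns={"sls_pre_h": "sls_pre"})
        else:
            pmap = participants[cols]
        t = t.drop(columns=[c for c in ("week", "sls_pre") if c in t]) \
            .merge(pmap, left_on="participant_id", right_on="id", how="left") \
            .drop(columns=["id"])
        self.trials = t
        self.metadata = participant_metadata(trials, participants)
        self.models = models
        self._cache: dict = {}
        self._theta_cache: dict = {}
        self.lineage: list[tuple[str, frozenset]] = []

    def extract(self, model_id: str, train_ids) -> pd.DataFrame:
        train_ids = frozenset(train_ids)
        self.lineage.append((model_id, train_ids))
        key = (model_id, train_ids)
        if key in self._cache:
            return self._cache[key]
        spec = self.models[model_id]
        mask = self.trials["participant_id"].isin(train_ids)
        design = build_design(self.trials[mask], spec)
        theta0 = self._theta_cache.get((model_id, tuple(design.block_names)))
        fit = fit_lmm(design, tol=1e-7, gtol=1e-5, theta0=theta0)
        self._theta_cache[(model_id, tuple(design.block_names))] = np.array(
            list(fit.theta.values()))
        feats = extract_participant_features(
            fit, self.metadata.loc[sorted(train_ids)])
        held_out = sorted(set(self.trials["participant_id"]) - train_ids)
        rows = []
        for pid in held_out:
            blups = predict_participant_blups(
                fit, self.trials[self.trials["participant_id"] == pid])
            row = {f"blup_{k}": v for k, v in blups.items()}
            for col in self.metadata.columns:
                row[col] = float(self.metadata.loc[pid, col])
            rows.append(pd.Series(row, name=pid))
        if rows:
            extra = pd.DataFrame(rows)
            extra.index.name = "participant_id"
            feats = pd.concat([feats, extra]).sort_index()
        feats = feats.fillna(0.0)
        self._cache[key] = feats
        return feats


@dataclass
class Predictor:
    """A trained regression-mode learner with fold-internal standardization."""

    kind: str
    feature_names: list
    _mean: np.ndarray
    _scale: np.ndarray
    _model: object = None
    _coef: np.ndarray = None
    coef_t_values: dict = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not self.feature_names:
            return np.full(len(X), float(self._coef[0]))
        A = X[self.feature_names].to_numpy(dtype=float)
        A = (A - self._mean) / self._scale
        if self.kind == "multiple_regression":
            return self._coef[0] + A @ self._coef[1:]
        return self._model.predict(A)


def fit_predictor(X: pd.DataFrame, y, config: PipelineConfig,
                  seed: int = 0) -> Predictor:
    """Train one learner on (already selected) features.

    Features are standardized with training statistics; multiple regression
    uses the pseudo-inverse, so rank deficiency degrades gracefully. The
    random forest is seeded for exact repeatability.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    settings = dict(config.learner_settings)
    if names:
        A = X[names].to_numpy(dtype=float)
        mean = A.mean(axis=0)
        scale = A.std(axis=0)
        scale[scale < 1e-12] = 1.0
        A = (A - mean) / scale
    else:
        A = np.empty((len(y), 0))
        mean = np.zeros(0)
        scale = np.ones(0)

    if config.learner == "multiple_regression" or not names:
        D = np.column_stack([np.ones(len(y)), A])
        coef = np.linalg.pinv(D) @ y
        resid = y - D @ coef
        dof = len(y) - D.shape[1]
        tvals = {}
        if dof > 0 and names:
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.pinv(D.T @ D)
            se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
            for j, nm in enumerate(names):
                tvals[nm] = float(coef[j + 1] / se[j + 1])
        return Predictor("multiple_regression", names, mean, scale,
                         _coef=coef, coef_t_values=tvals)
    if config.learner == "svm_linear":
        model = SVR(kernel="linear", C=settings.get("svm_cost", 1.0),
                    epsilon=settings.get("svm_epsilon", 0.1))
    elif config.learner == "svm_radial":
        model = SVR(kernel="rbf", C=settings.get("svm_cost", 1.0),
                    epsilon=settings.get("svm_epsilon", 0.1),
                    gamma=1.0 / max(len(names), 1))
    elif config.learner == "random_forest":
        model = RandomForestRegressor(
            n_estimators=settings.get("rf_n_trees", 500),
            max_features=max(1, math.ceil(len(names) / 3)),
            random_state=seed % (2 ** 31))
    else:
        raise ValueError(f"unknown learner {config.learner!r}")
    model.fit(A, y)
    return Predictor(config.learner, names, mean, scale, _model=model)


def evaluate(predicted, observed) -> dict:
    """Pearson r, its t statistic, MSE, R², and the Fisher-z 95% CI."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size != o.size or p.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if p.std() < 1e-300 or o.std() < 1e-300:
        raise ValueError("zero variance: correlation undefined")
    n = p.size
    r = float(np.corrcoef(p, o)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) < 1.0:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    else:
        t = math.copysign(math.inf, r)
    mse = float(np.mean((p - o) ** 2))
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (float("nan"), float("nan"))
    return {"pearson_r": r, "t_value": float(t), "df": n - 2, "mse": mse,
            "r_squared": r * r, "fisher_ci": ci, "n": n}


@dataclass
class CVResult:
    """Outer-loop predictions and summary metrics."""

    per_participant: pd.DataFrame
    metrics: dict
    selection_records: list
    fold_t_values: list

    def to_json_dict(self) -> dict:
        return {
            "metrics": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in self.metrics.items()},
            "per_participant": self.per_participant.to_dict(orient="records"),
        }


def _fold_selection_records(feats: pd.DataFrame, y: pd.Series,
                            model_id: str) -> list[SelectionRecord]:
    """Stepwise runs over the inner leave-one-out training sets (n-2 each)."""
    expanded = expand_interactions(feats)
    records = []
    for j in y.index:
        rest = [i for i in y.index if i != j]
        sel = stepwise_select(expanded.loc[rest], y.loc[rest])
        records.append(SelectionRecord(run_id=f"{model_id}|minus:{j}",
                                       selected=frozenset(sel)))
    return records


def inner_consensus_tune(feats_by_model: dict, y_train: pd.Series,
                         grid: PipelineGrid, seed: int = 0,
                         records_by_model: dict | None = None):
    """Pick the modal best grid point across the inner leave-one-out folds.

    Per inner fold, every grid point is trained on the remaining n-2
    participants and scored by squared error on the inner held-out one; the
    configuration winning most folds is returned (ties: lowest mean inner
    error, then lexicographic order). Failed fits score +infinity.
    """
    inner_ids = list(y_train.index)
    if records_by_model is None:
        records_by_model = {
            m: _fold_selection_records(feats_by_model[m], y_train, m)
            for m in feats_by_model}
    consensus = {}
    for m in feats_by_model:
        for c in grid.cutoffs:
            consensus[(m, c)] = consensus_select(records_by_model[m], c)

    configs = grid.configs()
    expanded = {m: expand_interactions(feats_by_model[m])
                for m in feats_by_model}
    errors = {cfg.key(): [] for cfg in configs}
    winners = []
    for j in inner_ids:
        rest = [i for i in inner_ids if i != j]
        best_key, best_err = None, math.inf
        for cfg in configs:
            sel = consensus[(cfg.extraction_model_id, cfg.selection_cutoff)]
            Xm = expanded[cfg.extraction_model_id]
            try:
                pred = fit_predictor(Xm.loc[rest, sel], y_train.loc[rest],
                                     cfg, seed=seed).predict(Xm.loc[[j]])[0]
                err = float((pred - y_train.loc[j]) ** 2)
            except Exception:
                err = math.inf
            errors[cfg.key()].append(err)
            if err < best_err - 1e-12 or (best_key is None):
                best_key, best_err = cfg.key(), err
        winners.append(best_key)

    tally: dict[tuple, int] = {}
    for k in winners:
        tally[k] = tally.get(k, 0) + 1
    top = max(tally.values())
    tied = [k for k, v in tally.items() if v == top]
    if len(tied) > 1:
        mean_err = {k: float(np.mean(errors[k])) for k in tied}
        lowest = min(mean_err.values())
        tied = sorted(k for k in tied if mean_err[k] <= lowest + 1e-12)
    win_key = sorted(tied)[0]
    settings = tuple(sorted(grid.learner_settings.items()))
    winning = PipelineConfig(*win_key, learner_settings=settings)
    return winning, consensus, records_by_model, winners


def outer_loocv(features_source, outcomes: pd.Series, grid: PipelineGrid,
                nested: bool = True, seed: int = 0) -> CVResult:
    """Leave-one-out predictions with (optionally) consensus-nested tuning.

    ``features_source`` is an object with ``extract(model_id, train_ids)``
    returning a participant-indexed feature table fitted on the training ids
    only (:class:`LMMFeatureExtractor` or :class:`PrecomputedFeatures`).
    Without nesting the grid must contain a single configuration, which is
    applied to every fold with the fold's own consensus feature selection.
    """
    ids = list(outcomes.index)
    if len(ids) < 4:
        raise ValueError("need at least 4 participants")
    configs = grid.configs()
    if not nested and len(configs) != 1:
        raise ValueError("non-nested run requires a grid of size 1")

    rows, all_records, fold_ts = [], [], []
    for pid in ids:
        train_ids = [i for i in ids if i != pid]
        y_train = outcomes.loc[train_ids]
        feats_by_model = {m: features_source.extract(m, train_ids)
                          for m in grid.extraction_models}
        if nested:
            records_by_model = {
                m: _fold_selection_records(feats_by_model[m].loc[train_ids],
                                           y_train, m)
                for m in feats_by_model}
            cfg, consensus, _, _ = inner_consensus_tune(
                {m: f.loc[train_ids] for m, f in feats_by_model.items()},
                y_train, grid, seed=seed, records_by_model=records_by_model)
            sel = consensus[(cfg.extraction_model_id, cfg.selection_cutoff)]
            all_records.extend(records_by_model[cfg.extraction_model_id])
        else:
            # no inner loop: one stepwise selection on the training fold
            cfg = configs[0]
            m = cfg.extraction_model_id
            sel = stepwise_select(
                expand_interactions(feats_by_model[m].loc[train_ids]),
                y_train)
            all_records.append(SelectionRecord(
                run_id=f"{m}|fold:{pid}", selected=frozenset(sel)))
        Xm = expand_interactions(feats_by_model[cfg.extraction_model_id])
        predictor = fit_predictor(Xm.loc[train_ids, sel], y_train, cfg,
                                  seed=seed)
        pred = float(predictor.predict(Xm.loc[[pid]])[0])
        fold_ts.append(predictor.coef_t_values or {})
        rows.append({"participant_id": pid, "predicted": pred,
                     "observed": float(outcomes.loc[pid]),
                     "config": cfg.label(), "n_selected": len(sel),
                     "selected": ";".join(sel)})
    per = pd.DataFrame(rows)
    metrics = evaluate(per["predicted"], per["observed"])
    return CVResult(per_participant=per, metrics=metrics,
                    selection_records=all_records, fold_t_values=fold_ts)


def run_pipeline_grid(features_source, outcomes: pd.Series,
                      grid: PipelineGrid, seed: int = 0) -> dict:
    """Fixed-configuration LOOCV predictions for every grid point.

    Shares the per-fold feature extraction and stepwise selection records
    across configurations, so the full grid costs one extraction and one set
    of stepwise runs per (fold, model).
    """
    ids = list(outcomes.index)
    configs = grid.configs()
    preds = {cfg.key(): {} for cfg in configs}
    all_records = []
    for pid in ids:
        train_ids = [i for i in ids if i != pid]
        y_train = outcomes.loc[train_ids]
        feats_by_model = {m: features_source.extract(m, train_ids)
                          for m in grid.extraction_models}
        records_by_model = {
            m: _fold_selection_records(feats_by_model[m].loc[train_ids],
                                       y_train, m)
            for m in feats_by_model}
        for m in records_by_model:
            all_records.extend(records_by_model[m])
        expanded = {m: expand_interactions(f)
                    for m, f in feats_by_model.items()}
        for cfg in configs:
            sel = consensus_select(
                records_by_model[cfg.extraction_model_id],
                cfg.selection_cutoff)
            Xm = expanded[cfg.extraction_model_id]
            try:
                predictor = fit_predictor(Xm.loc[train_ids, sel], y_train,
                                          cfg, seed=seed)
                preds[cfg.key()][pid] = float(
                    predictor.predict(Xm.loc[[pid]])[0])
            except Exception:
                preds[cfg.key()][pid] = float("nan")
    return {"predictions": preds, "selection_records": all_records,
            "outcomes": outcomes}


def aggregate_pipelines(grid_run: dict) -> dict:
    """Summaries over a completed grid: per-pipeline correlations, the
    per-participant median prediction and its correlation, and feature
    selection counts."""
    outcomes = grid_run["outcomes"]
    ids = list(outcomes.index)
    corr = {}
    pred_matrix = {}
    for key, d in grid_run["predictions"].items():
        p = np.array([d[i] for i in ids], dtype=float)
        pred_matrix[key] = p
        ok = np.isfinite(p)
        if ok.sum() >= 3 and p[ok].std() > 0:
            corr[key] = float(np.corrcoef(p[ok], outcomes.to_numpy()[ok])[0, 1])
        else:
            corr[key] = float("nan")
    P = np.vstack([pred_matrix[k] for k in sorted(pred_matrix)])
    median_pred = np.nanmedian(P, axis=0)
    med = evaluate(median_pred, outcomes.to_numpy())
    from .features import selection_counts
    return {
        "per_pipeline_r": corr,
        "r_values": np.array(sorted(corr.values())),
        "median_prediction": pd.Series(median_pred, index=ids),
        "median_metrics": med,
        "selection_counts": selection_counts(grid_run["selection_records"]),
    }
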