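"""Crossed-random-effects linear mixed models on log response times.

Fits log RT with fixed effects over stimulus- and trial-level predictors and
random effects for participants (intercept plus slopes, diagonal covariance)
crossed with stimulus intercepts, by profiled REML on the penalized
least-squares normal equations. The per-participant conditional modes (BLUPs)
of the random slopes are the individual-difference features used downstream:
shrinkage pulls noisy per-participant effects toward the population mean,
which is exactly why they make stable features at small sample sizes.

Estimation follows the standard profiled formulation: with relative
standard-deviation parameters theta (one per variance block), scaled random
columns Z* = Z Lambda(theta), and the bordered system

    [[Z*'Z* + I, Z*'X], [X'Z*, X'X]] [u; beta] = [Z*'y; X'y],

the REML criterion is log|Z*'Z*+I| + log|X' P X| + (n-p)(1 + log(2 pi
pwrss/(n-p))), where pwrss is the penalized residual sum of squares. theta is
optimized with L-BFGS-B under nonnegativity bounds; the profiled objective
decreases monotonically over accepted iterates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse

logger = logging.getLogger(__name__)

#: z-standardized continuous predictors
CONTINUOUS_VARS = ("lcm_uncertainty", "old20", "log_seq_index", "log_freq",
                   "sls_pre")
#: centered numeric codes
CENTERED_VARS = ("session",)
#: deviation-coded binaries (reference value subtracted)
BINARY_CODES = {"lexicality": 0.5, "error": 0.5, "week": 1.5}


def term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


def factorial_terms(*names: str) -> list[tuple[str, ...]]:
    """All main effects and interactions of the given variables."""
    from itertools import combinations
    out: list[tuple[str, ...]] = []
    for k in range(1, len(names) + 1):
        out.extend(combinations(names, k))
    return out


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect terms and the random-effect structure of one LMM.

    Terms are tuples of base predictor names; interactions are products of the
    standardized mains. ``participant_slope_terms`` must be a subset of
    ``fixed_terms``.
    """

    fixed_terms: tuple[tuple[str, ...], ...]
    participant_slope_terms: tuple[tuple[str, ...], ...] = ()
    include_stimulus_intercept: bool = True
    include_font_intercept: bool = False

    def __post_init__(self) -> None:
        if not self.fixed_terms:
            raise ValueError("at least one fixed term required")
        missing = set(self.participant_slope_terms) - set(self.fixed_terms)
        if missing:
            raise ValueError(f"slope terms not in fixed terms: {missing}")


def winning_model_spec() -> ModelSpec:
    """The best-performing extraction model: uncertainty x OLD20 x log
    sequence index (full factorial) + frequency + lexicality + errors + SLS +
    week, with participant slopes for all within-participant effects."""
    fact = tuple(factorial_terms("lcm_uncertainty", "old20", "log_seq_index"))
    within = fact + (("lexicality",), ("log_freq",), ("error",))
    fixed = within + (("sls_pre",), ("week",))
    return ModelSpec(fixed_terms=fixed, participant_slope_terms=within)


def group_model_spec(has_week: bool = True,
                     has_font: bool = False) -> ModelSpec:
    """The group-level training model: uncertainty x OLD20 x session (full
    factorial) + frequency + lexicality + errors + log sequence index."""
    fact = tuple(factorial_terms("lcm_uncertainty", "old20", "session"))
    fixed = fact + (("log_freq",), ("lexicality",), ("error",),
                    ("log_seq_index",))
    if has_week:
        fixed = fixed + (("week",),)
    slopes = (("lcm_uncertainty",), ("session",),
              ("lcm_uncertainty", "session"))
    return ModelSpec(fixed_terms=fixed, participant_slope_terms=slopes,
                     include_font_intercept=has_font)


def _derive_columns(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials.copy()
    if "log_seq_index" not in df and "seq_index" in df:
        df["log_seq_index"] = np.log(df["seq_index"].astype(float))
    if "error" not in df and "correct" in df:
        df["error"] = 1 - df["correct"].astype(int)
    if "log_rt" not in df and "rt_ms" in df:
        df["log_rt"] = np.log(df["rt_ms"].astype(float))
    return df


@dataclass
class DesignBundle:
    """Fixed and random design matrices plus the coding transforms."""

    X: np.ndarray
    xnames: list[str]
    Z: sparse.csc_matrix
    y: np.ndarray
    block_names: list[str]
    block_slices: list[slice]
    participant_ids: list[str]
    stimulus_ids: list[str]
    spec: ModelSpec
    transforms: dict
    n_participants: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_participants = len(self.participant_ids)


def _transform_column(df: pd.DataFrame, var: str, transforms: dict,
                      fit_transforms: bool) -> np.ndarray | None:
    v = df[var].to_numpy(dtype=float)
    if var in BINARY_CODES:
        return v - BINARY_CODES[var]
    if var in CENTERED_VARS:
        if fit_transforms:
            transforms[var] = ("center", float(v.mean()))
        kind, m = transforms[var]
        return v - m
    # continuous: z-standardize with (training) dataset statistics
    if fit_transforms:
        sd = float(v.std())
        if sd < 1e-12:
            return None
        transforms[var] = ("zscore", float(v.mean()), sd)
    if var not in transforms:
        return None
    _, m, sd = transforms[var]
    return (v - m) / sd


def build_design(trials: pd.DataFrame, spec: ModelSpec,
                 transforms: dict | None = None,
                 response: str = "log_rt") -> DesignBundle:
    """Assemble the fixed-effect matrix and sparse random-effect structure.

    Continuous predictors are z-standardized, binary predictors deviation
    coded, session centered; interaction columns are elementwise products of
    the transformed mains. Constant predictors are dropped with a warning.
    Passing ``transforms`` from a previous fit reuses that coding (needed to
    score a held-out participant on the training fold's scale).
    """
    df = _derive_columns(trials)
    if df.empty:
        raise ValueError("no trials")
    fit_tr = transforms is None
    transforms = {} if fit_tr else dict(transforms)

    base_vars = sorted({v for t in spec.fixed_terms for v in t})
    cols: dict[str, np.ndarray] = {}
    dropped: set[str] = set()
    for var in base_vars:
        if var not in df.columns:
            raise KeyError(f"predictor {var!r} missing from trials")
        c = _transform_column(df, var, transforms, fit_tr)
        if c is None or (fit_tr and np.ptp(c) < 1e-12):
            warnings.warn(f"constant predictor {var!r} dropped from design")
            dropped.add(var)
        else:
            cols[var] = c

    n = len(df)
    xnames = ["intercept"]
    xcols = [np.ones(n)]
    kept_terms = []
    for t in spec.fixed_terms:
        if any(v in dropped for v in t):
            continue
        col = np.ones(n)
        for v in t:
            col = col * cols[v]
        kept_terms.append(t)
        xnames.append(term_name(t))
        xcols.append(col)
    X = np.column_stack(xcols)

    part = pd.Categorical(df["participant_id"].astype(str))
    pids = list(part.categories)
    pcodes = np.asarray(part.codes, dtype=np.int64)
    npart = len(pids)

    rows, zcols, vals = [], [], []
    block_names, block_slices = [], []
    offset = 0
    row_idx = np.arange(n)

    def add_participant_block(name: str, values: np.ndarray) -> None:
        nonlocal offset
        rows.append(row_idx)
        zcols.append(offset + pcodes)
        vals.append(values)
        block_names.append(name)
        block_slices.append(slice(offset, offset + npart))
        offset += npart

    add_participant_block("participant:intercept", np.ones(n))
    for t in spec.participant_slope_terms:
        if any(v in dropped for v in t) or t not in kept_terms:
            continue
        col = np.ones(n)
        for v in t:
            col = col * cols[v]
        add_participant_block(f"participant:{term_name(t)}", col)

    stim_ids: list[str] = []
    if spec.include_stimulus_intercept:
        stim = pd.Categorical(df["stimulus"].astype(str))
        stim_ids = list(stim.categories)
        rows.append(row_idx)
        zcols.append(offset + np.asarray(stim.codes, dtype=np.int64))
        vals.append(np.ones(n))
        block_names.append("stimulus:intercept")
        block_slices.append(slice(offset, offset + len(stim_ids)))
        offset += len(stim_ids)

    if spec.include_font_intercept and "font_block" in df.columns:
        font = pd.Categorical(df["font_block"])
        rows.append(row_idx)
        zcols.append(offset + np.asarray(font.codes, dtype=np.int64))
        vals.append(np.ones(n))
        block_names.append("font:intercept")
        block_slices.append(slice(offset, offset + len(font.categories)))
        offset += len(font.categories)

    Z = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(zcols))),
        shape=(n, offset)).tocsc()
    y = df[response].to_numpy(dtype=float)
    return DesignBundle(X=X, xnames=xnames, Z=Z, y=y,
                        block_names=block_names, block_slices=block_slices,
                        participant_ids=pids, stimulus_ids=stim_ids,
                        spec=spec, transforms=transforms)


@dataclass
class FitResult:
    """REML estimates: fixed effects, variance components, and BLUPs."""

    beta: dict
    se: dict
    t_value: dict
    variance_components: dict
    participant_blups: dict
    stimulus_blups: dict
    converged: bool
    n_obs: int
    sigma2: float
    theta: dict
    objective_history: list
    spec: ModelSpec
    transforms: dict
    _beta_vec: np.ndarray = None
    _xnames: list = None

    def coefficient_table(self) -> pd.DataFrame:
        rows = [{"term": k, "FE": self.beta[k], "SE": self.se[k],
                 "t": self.t_value[k]} for k in self.beta]
        return pd.DataFrame(rows)


def fit_lmm(design: DesignBundle, maxiter: int = 500,
            tol: float = 1e-8, theta0: np.ndarray | None = None,
            gtol: float = 1e-6) -> FitResult:
    """Profiled REML fit of the crossed-random-effects model.

    ``theta0`` warm-starts the variance-ratio search (useful when refitting
    the same model on overlapping data, as in cross-validation folds).
    """
    X, y = design.X, design.y
    n, p = X.shape
    q = design.Z.shape[1]
    K = len(design.block_names)
    if n <= p:
        raise ValueError("more fixed-effect terms than observations")

    ZtZ = (design.Z.T @ design.Z).toarray()
    ZtX = design.Z.T @ X
    Zty = design.Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    block_of_col = np.empty(q, dtype=int)
    for k, sl in enumerate(design.block_slices):
        block_of_col[sl] = k

    history: list[float] = []

    def solve_at(theta: np.ndarray):
        lam = theta[block_of_col]
        A11 = (lam[:, None] * ZtZ) * lam[None, :]
        A11[np.diag_indices_from(A11)] += 1.0
        A12 = lam[:, None] * ZtX
        M = np.block([[A11, A12], [A12.T, XtX]])
        rhs = np.concatenate([lam * Zty, Xty])
        c, low = linalg.cho_factor(M, lower=True, check_finite=False)
        sol = linalg.cho_solve((c, low), rhs, check_finite=False)
        pwrss = max(yty - float(rhs @ sol), 1e-300)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        crit = logdet + (n - p) * (
            1.0 + np.log(2.0 * np.pi * pwrss / (n - p)))
        return crit, sol, pwrss, lam

    def objective(theta: np.ndarray) -> float:
        try:
            crit, *_ = solve_at(theta)
        except linalg.LinAlgError:
            return 1e12
        return crit

    converged = True
    if K > 0:
        x0 = np.ones(K) if theta0 is None else np.asarray(theta0, dtype=float)
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[(0.0, None)] * K,
            callback=lambda xk: history.append(objective(xk)),
            options={"maxiter": maxiter, "ftol": tol, "gtol": gtol})
        theta = np.maximum(res.x, 0.0)
        converged = bool(res.success)
        if not converged:
            logger.warning("REML optimizer did not converge: %s", res.message)
        if np.any(theta < 1e-6):
            warnings.warn("singular fit: variance component(s) pinned at 0")
            theta = np.where(theta < 1e-6, 0.0, theta)
    else:
        theta = np.zeros(0)

    if K > 0:
        crit, sol, pwrss, lam = solve_at(theta)
        u = sol[:q]
        beta_vec = sol[q:]
        b = lam * u
        A11 = (lam[:, None] * ZtZ) * lam[None, :]
        A11[np.diag_indices_from(A11)] += 1.0
        A12 = lam[:, None] * ZtX
        schur = XtX - A12.T @ linalg.solve(A11, A12, assume_a="pos")
    else:
        beta_vec = linalg.lstsq(X, y)[0]
        resid = y - X @ beta_vec
        pwrss = float(resid @ resid)
        b = np.zeros(0)
        schur = XtX

    sigma2 = pwrss / (n - p)
    cov_beta = sigma2 * linalg.inv(schur)
    se_vec = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vec = np.where(se_vec > 0, beta_vec / se_vec, np.nan)

    beta = dict(zip(design.xnames, beta_vec))
    se = dict(zip(design.xnames, se_vec))
    t_value = dict(zip(design.xnames, t_vec))

    variance = {name: sigma2 * float(theta[k]) ** 2
                for k, name in enumerate(design.block_names)}
    variance["residual"] = sigma2

    participant_blups: dict[str, dict[str, float]] = {
        pid: {} for pid in design.participant_ids}
    stimulus_blups: dict[str, float] = {}
    for k, (name, sl) in enumerate(zip(design.block_names,
                                       design.block_slices)):
        vals = b[sl]
        if name.startswith("participant:"):
            short = name.removeprefix("participant:")
            for pid, v in zip(design.participant_ids, vals):
                participant_blups[pid][short] = float(v)
        elif name == "stimulus:intercept":
            stimulus_blups = dict(zip(design.stimulus_ids,
                                      (float(v) for v in vals)))

    return FitResult(
        beta=beta, se=se, t_value=t_value, variance_components=variance,
        participant_blups=participant_blups, stimulus_blups=stimulus_blups,
        converged=converged, n_obs=n, sigma2=sigma2,
        theta=dict(zip(design.block_names, theta)),
        objective_history=history, spec=design.spec,
        transforms=design.transforms, _beta_vec=beta_vec,
        _xnames=design.xnames)


def predict_participant_blups(fit: FitResult,
                              trials_new: pd.DataFrame) -> dict:
    """Conditional-mode random effects for a participant absent from the fit.

    Uses the fitted fixed effects, variance ratios, stimulus intercepts, and
    the training coding transforms; the new participant's trials enter no
    refitting, only the closed-form conditional mode given the fit.
    """
    bundle = build_design(trials_new, fit.spec, transforms=fit.transforms)
    Xn = bundle.X
    # align columns: terms dropped in the new data keep their fitted name order
    beta_map = fit.beta
    xb = np.zeros(len(Xn))
    for j, name in enumerate(bundle.xnames):
        if name in beta_map:
            xb += beta_map[name] * Xn[:, j]
    stim_b = np.array([fit.stimulus_blups.get(s, 0.0)
                       for s in trials_new["stimulus"].astype(str)])
    y = bundle.y
    r = y - xb - stim_b

    part_blocks = [(name, sl) for name, sl in
                   zip(bundle.block_names, bundle.block_slices)
                   if name.startswith("participant:")]
    m = len(r)
    Zp = np.zeros((m, len(part_blocks)))
    lam = np.zeros(len(part_blocks))
    names = []
    Z = bundle.Z.toarray()
    for j, (name, sl) in enumerate(part_blocks):
        Zp[:, j] = Z[:, sl].sum(axis=1)   # single participant: one column
        lam[j] = fit.theta.get(name, 0.0)
        names.append(name.removeprefix("participant:"))
    Mi = (lam[:, None] * (Zp.T @ Zp)) * lam[None, :] + np.eye(len(lam))
    u = linalg.solve(Mi, lam * (Zp.T @ r), assume_a="pos")
    return dict(zip(names, lam * u))


def extract_participant_features(fit: FitResult,
                                 metadata: pd.DataFrame) -> pd.DataFrame:
    """One feature row per participant: random-slope BLUPs plus metadata.

    ``metadata`` is indexed by participant id and contributes incoming reading
    speed (SLS), training week, and the session-1 error count.
    """
    rows = {}
    for pid, blups in fit.participant_blups.items():
        if pid not in metadata.index:
            raise KeyError(f"participant {pid} absent from metadata")
        rows[pid] = {f"blup_{k}": v for k, v in blups.items()}
    feats = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    feats.index.name = "participant_id"
    meta = metadata.loc[feats.index]
    for col in meta.columns:
        feats[col] = meta[col].astype(float)
    return feats


def participant_metadata(trials: pd.DataFrame,
                         participants: pd.DataFrame) -> pd.DataFrame:
    """Assemble SLS, week, and session-1 error-count metadata features."""
    s1 = trials[trials["session"] == 1]
    errors = (1 - s1.groupby("participant_id")["correct"].mean()) * \
        s1.groupby("participant_id")["correct"].size()
    meta = participants.set_index("id")[["week"]].copy()
    if "sls_pre_h" in participants.columns:
        meta["sls"] = participants.set_index("id")["sls_pre_h"]
    else:
        meta["sls"] = participants.set_index("id")["sls_pre"]
    meta["session1_errors"] = errors.reindex(meta.index).fillna(0.0)
    meta.index.name = "participant_id"
    return meta


def group_training_analysis(trials: pd.DataFrame,
                            spec: ModelSpec | None = None) -> pd.DataFrame:
    """Fit the group model across sessions and return the FE/SE/t table."""
    df = _derive_columns(trials)
    if df["session"].nunique() < 2:
        raise ValueError("group analysis needs at least 2 sessions")
    if spec is None:
        spec = group_model_spec(
            has_week="week" in df.columns and df["week"].nunique() > 1,
            has_font="font_block" in df.columns)
    design = build_design(df, spec)
    fit = fit_lmm(design)
    return fit.coefficient_table()
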