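"""Synthetic lexical-decision training studies with a planted responder signal.

The generator mirrors the structure of a three-session lexical-categorization
training study: a lexicon of fixed-length strings with Zipf frequencies, a
2:1:1 word/pseudoword/consonant-string stimulus set, trial-level lexical
decisions whose log response times follow a crossed-random-effects linear
model (participant intercept + slopes, stimulus intercept), and pre/post
reading-speed scores whose percent change — the training benefit — is a known
linear function of each participant's true uncertainty slope, incoming reading
speed, and training week. Because the benefit coefficients are known, recovery
of the signal by the analysis pipeline can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .lexicon import (CONSONANTS, VOWELS, Lexicon, generate_consonant_string,
                      generate_pseudoword, score_stimuli)

# trial predictors entering the generative log-RT model, z-scored over the
# stimulus set / trial sequence so coefficients are on the standardized scale
# that the fitted mixed models also use
_TRIAL_TERMS = ("lcm_uncertainty", "old20", "log_seq_index", "session",
                "log_freq", "lexicality")


def _default_fixed_effects() -> dict:
    # log-RT scale; uncertainty +0.12 and session -0.03 follow the magnitudes
    # reported for the preregistered lexical-categorization experiment
    return {
        "intercept": 7.0,           # exp() ~ 1100 ms: language-learner pace,
                                    # keeps the 300/4000 ms trim bounds > 3 SD
                                    # from the latent log-RT distribution
        "lcm_uncertainty": 0.12,
        "old20": 0.02,
        "log_seq_index": -0.02,     # within-session learning
        "session": -0.03,           # across-session learning
        "log_freq": -0.02,
        "lexicality": -0.03,        # words faster than nonwords
        "lcm_uncertainty:session": 0.0,
    }


def _default_random_sd() -> dict:
    return {
        "participant_intercept": 0.25,
        "participant_lcm_uncertainty": 0.05,
        "participant_old20": 0.02,
        "participant_log_seq_index": 0.02,
        "stimulus_intercept": 0.05,
    }


def _default_accuracy_coefs() -> dict:
    # logistic scale: ~92% correct at zero uncertainty, degrading as the
    # categorization becomes uncertain
    return {"intercept": 2.5, "lcm_uncertainty": -1.5, "lexicality": 0.0}


def _default_benefit_coefs() -> dict:
    # percent reading-speed change: mean ~23%, higher for participants with a
    # stronger uncertainty slope, lower for fast incoming readers and for the
    # second training week
    return {
        "intercept": 23.0,
        "slope_lcm_weight": 150.0,  # per log-RT unit of true uncertainty slope
        "sls_weight": -8.0,         # per SD of incoming reading speed
        "week_weight": -15.0,       # week 2 offset
        "noise_sd": 25.0,
    }


@dataclass
class GenerativeConfig:
    """Study-design and generative parameters.

    Trial counts follow the study design (1600 five-letter stimuli per
    session, three sessions); reduced-scale runs override them.
    """

    n_participants: int = 30
    n_trials_per_session: int = 1600
    n_sessions: int = 3
    lexicon_size: int = 3110
    word_length: int = 5
    condition: str = "LC"                 # LC | phonics | LC_font
    fixed_effects: dict = field(default_factory=_default_fixed_effects)
    random_sd: dict = field(default_factory=_default_random_sd)
    residual_sd: float = 0.30
    accuracy_coefs: dict = field(default_factory=_default_accuracy_coefs)
    benefit_coefs: dict = field(default_factory=_default_benefit_coefs)
    fast_guess_rate: float = 0.02         # contaminant uniform(100,300) ms
    error_rt_offset: float = 0.08         # log-RT inflation on error trials
    timeout_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_session % 4:
            raise ValueError("n_trials_per_session must be divisible by 4 "
                             "(2:1:1 word:pseudoword:consonant-string design)")
        if any(v < 0 for v in self.random_sd.values()) or self.residual_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.condition not in ("LC", "phonics", "LC_font"):
            raise ValueError(f"unknown condition {self.condition!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ParticipantTruth:
    """Ground-truth per-participant quantities for recovery tests."""

    id: str
    true_random_effects: dict
    sls_pre: int
    sls_version_duration_s: int
    week: int
    condition: str
    true_benefit_pct: float = float("nan")


def simulate_lexicon(config: GenerativeConfig,
                     rng: np.random.Generator) -> Lexicon:
    """Unique fixed-length strings with consonant-vowel alternation bias and
    Zipf (rank^-1) frequencies scaled to per-million counts."""
    size, length = config.lexicon_size, config.word_length
    if size < 50:
        raise ValueError("lexicon_size must be at least 50")
    # crude capacity check: alternating-CV strings dominate the pool
    capacity = (len(CONSONANTS) * len(VOWELS)) ** (length // 2) * \
        len(CONSONANTS) ** (length % 2)
    if size > capacity // 2:
        raise ValueError("alphabet too small for the requested lexicon size")
    # Zipf-biased letter frequencies: like a natural lexicon, a few letters
    # dominate, which clusters words in edit-distance space and makes the
    # uniform-vowel pseudoword substitution drift away from that cluster
    def zipf_probs(k: int) -> np.ndarray:
        p = 1.0 / np.arange(1, k + 1)
        return p / p.sum()

    vowel_p = zipf_probs(len(VOWELS))
    cons_p = zipf_probs(len(CONSONANTS))
    words: set[str] = set()
    ordered: list[str] = []
    while len(ordered) < size:
        letters = []
        for i in range(length):
            want_vowel = i % 2 == 1
            if rng.random() < 0.15:     # occasional CV violation
                want_vowel = not want_vowel
            if want_vowel:
                letters.append(VOWELS[rng.choice(len(VOWELS), p=vowel_p)])
            else:
                letters.append(
                    CONSONANTS[rng.choice(len(CONSONANTS), p=cons_p)])
        w = "".join(letters)
        if w not in words:
            words.add(w)
            ordered.append(w)
    ranks = np.arange(1, size + 1, dtype=float)
    freqs = 1000.0 / ranks              # rank-1 word at 1000 per million
    return Lexicon(tuple(ordered), tuple(freqs))


def simulate_stimuli(lexicon: Lexicon, n_trials: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Scored 2:1:1 stimulus set: n/2 words drawn from the lexicon, n/4
    pseudowords and n/4 consonant strings derived from those words."""
    if n_trials % 4:
        raise ValueError("n_trials must be divisible by 4")
    n_words = n_trials // 2
    n_each = n_trials // 4
    if n_words > len(lexicon):
        raise ValueError("lexicon too small for the requested word count")
    word_idx = rng.choice(len(lexicon), size=n_words, replace=False)
    words = [lexicon.words[i] for i in word_idx]
    # nonwords are derived only from base words that contain a vowel
    bases = [w for w in words if any(c in VOWELS for c in w)]
    if len(bases) < 2 * n_each:
        bases = (bases * (2 * n_each // max(len(bases), 1) + 1))[:2 * n_each]
    pseudo, seen = [], set()
    for w in bases[:n_each]:
        for _ in range(100):
            c = generate_pseudoword(w, rng, lexicon)
            if c not in seen:
                break
        seen.add(c)
        pseudo.append(c)
    cons = []
    for w in bases[n_each:2 * n_each]:
        for _ in range(100):
            c = generate_consonant_string(w, rng, lexicon)
            if c not in seen:
                break
        seen.add(c)
        cons.append(c)
    items = pd.DataFrame({
        "letters": words + pseudo + cons,
        "condition": (["word"] * n_words + ["pseudoword"] * n_each
                      + ["consonant_string"] * n_each),
    })
    return score_stimuli(items, lexicon)


def _standardized_stimulus_terms(stimuli: pd.DataFrame) -> pd.DataFrame:
    """z-score the stimulus-level predictors used by the generative model."""
    out = pd.DataFrame(index=stimuli.index)
    for col in ("lcm_uncertainty", "old20", "log_freq"):
        v = stimuli[col].to_numpy(dtype=float)
        sd = v.std()
        out[col] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    out["lexicality"] = stimuli["lexicality"].to_numpy(dtype=float) - 0.5
    return out


def draw_participant_truth(config: GenerativeConfig, rng: np.random.Generator,
                           pid: str) -> ParticipantTruth:
    re = {name.removeprefix("participant_"): rng.normal(0.0, sd)
          for name, sd in config.random_sd.items()
          if name.startswith("participant_")}
    sls_pre = int(max(5, round(rng.normal(30, 8))))
    duration = int(rng.choice([90, 180]))
    week = int(rng.integers(1, 3))
    return ParticipantTruth(id=pid, true_random_effects=re, sls_pre=sls_pre,
                            sls_version_duration_s=duration, week=week,
                            condition=config.condition)


def simulate_trials(truth: ParticipantTruth, stimuli: pd.DataFrame,
                    session: int, config: GenerativeConfig,
                    rng: np.random.Generator,
                    stimulus_intercepts: np.ndarray | None = None
                    ) -> pd.DataFrame:
    """One participant-session of lexical decisions.

    log RT = fixed effects + participant random intercept/slopes + stimulus
    intercept + N(0, residual_sd); stimulus order is freshly randomized per
    participant and session; the phonics arm carries no uncertainty effect.
    """
    if not 1 <= session <= config.n_sessions:
        raise ValueError("session out of range")
    n = len(stimuli)
    order = rng.permutation(n)
    stim = stimuli.iloc[order].reset_index(drop=True)
    z = _standardized_stimulus_terms(stim)
    seq = np.arange(1, n + 1, dtype=float)
    log_seq = np.log(seq)
    zlseq = (log_seq - log_seq.mean()) / log_seq.std()
    zsess = float(session) - (config.n_sessions + 1) / 2.0

    fe = dict(config.fixed_effects)
    if truth.condition == "phonics":
        fe["lcm_uncertainty"] = 0.0     # no lexical-categorization effect
        fe["lcm_uncertainty:session"] = 0.0

    eta = np.full(n, fe.get("intercept", 0.0))
    term_values = {
        "lcm_uncertainty": z["lcm_uncertainty"].to_numpy(),
        "old20": z["old20"].to_numpy(),
        "log_freq": z["log_freq"].to_numpy(),
        "lexicality": z["lexicality"].to_numpy(),
        "log_seq_index": zlseq,
        "session": np.full(n, zsess),
    }
    term_values["lcm_uncertainty:session"] = (
        term_values["lcm_uncertainty"] * zsess)
    for name, beta in fe.items():
        if name == "intercept":
            continue
        eta = eta + beta * term_values[name]
    re = truth.true_random_effects
    eta = eta + re.get("intercept", 0.0)
    for name, b in re.items():
        if name != "intercept" and name in term_values:
            eta = eta + b * term_values[name]
    if stimulus_intercepts is not None:
        eta = eta + stimulus_intercepts[order]

    # accuracy from a logistic model on the same standardized predictors
    acc = config.accuracy_coefs
    acc_eta = acc.get("intercept", 2.5)
    for name, beta in acc.items():
        if name != "intercept":
            acc_eta = acc_eta + beta * term_values[name]
    p_correct = 1.0 / (1.0 + np.exp(-acc_eta))
    correct = (rng.random(n) < p_correct).astype(int)

    eta = eta + config.error_rt_offset * (1 - correct)
    log_rt = eta + rng.normal(0.0, config.residual_sd, size=n)
    rt = np.exp(log_rt)
    # physiologically implausible model RTs are redrawn
    for _ in range(10):
        low = rt < 150
        if not low.any():
            break
        rt[low] = np.exp(eta[low] + rng.normal(0.0, config.residual_sd,
                                               size=int(low.sum())))
    rt = np.clip(rt, 150.0, None)
    # contaminant fast guesses: uniform(100, 300) ms, below the analysis trim
    guess = rng.random(n) < config.fast_guess_rate
    rt[guess] = rng.uniform(100.0, 300.0 - 1e-9, size=int(guess.sum()))
    timeout_ms = config.timeout_s * 1000.0
    timed_out = rt > timeout_ms
    rt = np.minimum(rt, timeout_ms)
    correct[timed_out] = 0

    out = pd.DataFrame({
        "participant_id": truth.id,
        "week": truth.week,
        "session": session,
        "seq_index": seq.astype(int),
        "stimulus": stim["letters"].to_numpy(),
        "condition": stim["condition"].to_numpy(),
        "lcm_uncertainty": stim["lcm_uncertainty"].to_numpy(),
        "old20": stim["old20"].to_numpy(),
        "log_freq": stim["log_freq"].to_numpy(),
        "lexicality": stim["lexicality"].to_numpy(),
        "rt_ms": rt,
        "correct": correct,
        "task": truth.condition,
    })
    if truth.condition == "LC_font":
        out["font_block"] = (seq - 1).astype(int) // 32
    return out


def simulate_outcome(truth: ParticipantTruth, config: GenerativeConfig,
                     rng: np.random.Generator,
                     sls_pre_mean: float = 30.0, sls_pre_sd: float = 8.0
                     ) -> tuple[int, int]:
    """Pre/post reading-speed counts with the planted percent benefit.

    benefit% = intercept + slope_lcm_weight * (true uncertainty slope)
             + sls_weight * standardized(sls_pre) + week_weight * 1{week=2}
             + N(0, noise_sd); post = round(pre * (1 + benefit/100)), >= 0.
    """
    bc = config.benefit_coefs
    slope = truth.true_random_effects.get("lcm_uncertainty", 0.0)
    z_sls = (truth.sls_pre - sls_pre_mean) / sls_pre_sd
    benefit = (bc["intercept"] + bc["slope_lcm_weight"] * slope
               + bc["sls_weight"] * z_sls
               + bc["week_weight"] * (1.0 if truth.week == 2 else 0.0)
               + rng.normal(0.0, bc["noise_sd"]))
    truth.true_benefit_pct = float(benefit)
    sls_post = max(0, int(round(truth.sls_pre * (1.0 + benefit / 100.0))))
    return truth.sls_pre, sls_post


@dataclass
class StudyData:
    """A complete simulated study."""

    config: GenerativeConfig
    lexicon: Lexicon
    stimuli: pd.DataFrame
    trials: pd.DataFrame
    participants: pd.DataFrame
    truths: list


def simulate_study(config: GenerativeConfig,
                   sessions: int | None = None) -> StudyData:
    """Generate lexicon, stimuli, all participant-session trials, and outcomes.

    ``sessions`` limits how many sessions of trials are materialized (the
    prediction pipeline needs only session 1; the group analysis needs all).
    """
    rng = np.random.default_rng(config.seed)
    lexicon = simulate_lexicon(config, rng)
    stimuli = simulate_stimuli(lexicon, config.n_trials_per_session, rng)
    stim_int = rng.normal(0.0, config.random_sd.get("stimulus_intercept", 0.0),
                          size=len(stimuli))
    n_sessions = config.n_sessions if sessions is None else sessions
    truths, trial_frames, part_rows = [], [], []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        truth = draw_participant_truth(config, rng, pid)
        for s in range(1, n_sessions + 1):
            trial_frames.append(simulate_trials(truth, stimuli, s, config,
                                                rng, stim_int))
        pre, post = simulate_outcome(truth, config, rng)
        truths.append(truth)
        part_rows.append({
            "id": pid, "condition": truth.condition, "week": truth.week,
            "sls_pre": pre, "sls_post": post,
            "sls_version_duration_s": truth.sls_version_duration_s,
            "true_benefit_pct": truth.true_benefit_pct,
            "true_lcm_slope": truth.true_random_effects.get(
                "lcm_uncertainty", 0.0),
        })
    trials = pd.concat(trial_frames, ignore_index=True)
    participants = pd.DataFrame(part_rows)
    return StudyData(config, lexicon, stimuli, trials, participants, truths)


def simulate_participants(config: GenerativeConfig) -> pd.DataFrame:
    """Participant-level draw only (truths and outcomes, no trials).

    Useful for studying the prediction machinery itself, where the features
    are the generative participant-level quantities and the expensive
    trial-level simulation is not needed.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_participants):
        truth = draw_participant_truth(config, rng, f"P{i + 1:03d}")
        pre, post = simulate_outcome(truth, config, rng)
        rows.append({
            "id": truth.id, "condition": truth.condition, "week": truth.week,
            "sls_pre": pre, "sls_post": post,
            "sls_version_duration_s": truth.sls_version_duration_s,
            "true_benefit_pct": truth.true_benefit_pct,
            "true_lcm_slope": truth.true_random_effects.get(
                "lcm_uncertainty", 0.0),
        })
    return pd.DataFrame(rows)


def planted_r_squared(config: GenerativeConfig,
                      sls_pre_sd_standardized: float = 1.0) -> float:
    """Closed-form share of benefit variance carried by the planted signal."""
    bc = config.benefit_coefs
    slope_sd = config.random_sd.get("participant_lcm_uncertainty", 0.0)
    var_signal = ((bc["slope_lcm_weight"] * slope_sd) ** 2
                  + (bc["sls_weight"] * sls_pre_sd_standardized) ** 2
                  + bc["week_weight"] ** 2 * 0.25)   # Bernoulli(1/2) week
    return var_signal / (var_signal + bc["noise_sd"] ** 2)


def config_for_planted_r2(target_r2: float, base: GenerativeConfig | None = None,
                          **overrides) -> GenerativeConfig:
    """Return a config whose benefit noise is set to hit a target signal R²."""
    cfg = base or GenerativeConfig(**overrides)
    bc = dict(cfg.benefit_coefs)
    slope_sd = cfg.random_sd.get("participant_lcm_uncertainty", 0.0)
    var_signal = ((bc["slope_lcm_weight"] * slope_sd) ** 2
                  + bc["sls_weight"] ** 2 + bc["week_weight"] ** 2 * 0.25)
    bc["noise_sd"] = float(np.sqrt(var_signal * (1 - target_r2) / target_r2))
    cfg.benefit_coefs = bc
    return cfg
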