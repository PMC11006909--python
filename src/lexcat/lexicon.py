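"""Word-likeness (OLD20), nonword construction, and lexical-categorization uncertainty.

The lexical categorization model (LCM) assumes that a reader decides whether a
letter string is meaningful from its *word-likeness*, operationalized as OLD20:
the mean Levenshtein distance from the string to its 20 nearest neighbors in a
reference lexicon. Words and nonwords occupy overlapping word-likeness
distributions; where they overlap, the posterior probability of "word" is near
0.5 and categorization is maximally uncertain. The uncertainty score is the
binary entropy of that posterior, bounded in [0, 1] bits, and has an
inverted-U relationship with word-likeness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

VOWELS = "AEIOU"
CONSONANTS = "BCDFGHJKLMNPQRSTVWXYZ"

#: pseudo-count (per million) added before taking log10 frequency; nonwords,
#: which have no corpus frequency, receive the offset-only value log10(1) = 0.
FREQ_OFFSET = 1.0

#: floor applied to class densities before forming the posterior
DENSITY_FLOOR = 1e-12


class InsufficientLexiconError(ValueError):
    """Fewer than 20 eligible neighbors available for OLD20."""


class GenerationFailureError(RuntimeError):
    """Nonword generation exhausted its retry budget."""


@dataclass(frozen=True)
class Lexicon:
    """A reference word list with per-million occurrence frequencies.

    All entries are unique uppercase strings of a common length ``L`` with
    strictly positive frequency. OLD20 needs at least 20 neighbors distinct
    from any target, hence the minimum size of 21.
    """

    words: tuple[str, ...]
    freq_per_million: tuple[float, ...]
    _index: frozenset = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.words) < 21:
            raise ValueError("lexicon needs at least 21 entries")
        if len(self.words) != len(self.freq_per_million):
            raise ValueError("words and frequencies differ in length")
        lengths = {len(w) for w in self.words}
        if len(lengths) != 1:
            raise ValueError("all lexicon entries must share one length")
        if len(set(self.words)) != len(self.words):
            raise ValueError("lexicon entries must be unique")
        if any(f <= 0 for f in self.freq_per_million):
            raise ValueError("frequencies must be positive")
        if any(not w.isalpha() or w != w.upper() for w in self.words):
            raise ValueError("entries must be uppercase alphabetic strings")
        object.__setattr__(self, "_index", frozenset(self.words))

    @property
    def word_length(self) -> int:
        return len(self.words[0])

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, s: str) -> bool:
        return s.upper() in self._index

    def log_freq(self, word: str) -> float:
        """log10(frequency + offset); offset-only value for nonwords."""
        w = word.upper()
        if w in self._index:
            f = self.freq_per_million[self.words.index(w)]
            return float(np.log10(f + FREQ_OFFSET))
        return float(np.log10(FREQ_OFFSET))

    @classmethod
    def from_table(cls, path) -> "Lexicon":
        """Read a two-column (word, frequency) TSV or CSV file."""
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         names=["word", "freq"], skipinitialspace=True)
        if df["word"].iloc[0] in ("word", "WORD"):  # tolerate a header row
            df = df.iloc[1:]
        return cls(tuple(str(w).upper() for w in df["word"]),
                   tuple(float(f) for f in df["freq"]))

    def to_table(self, path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        pd.DataFrame({"word": self.words, "freq": self.freq_per_million}
                     ).to_csv(path, sep=sep, index=False, header=False)


def levenshtein(a: str, b: str) -> int:
    """Standard edit distance with unit insert/delete/substitute costs."""
    if not a or not b:
        raise ValueError("levenshtein requires nonempty strings")
    return int(edlib.align(a.upper(), b.upper(), task="distance")["editDistance"])


def old20(target: str, lexicon: Lexicon) -> float:
    """Mean Levenshtein distance to the 20 nearest lexicon neighbors.

    The target itself is excluded from its own neighbor set when present, so
    words do not receive a spurious zero-distance neighbor.
    """
    t = target.upper()
    dists = np.array([levenshtein(t, w) for w in lexicon.words if w != t],
                     dtype=float)
    if dists.size < 20:
        raise InsufficientLexiconError(
            f"need 20 neighbors distinct from {target!r}, have {dists.size}")
    return float(np.mean(np.partition(dists, 19)[:20]))


def _substitute_vowels(word: str, rng: np.random.Generator, lexicon: Lexicon,
                       replacement_pool: str, forbid_same: bool,
                       max_retries: int) -> str:
    w = word.upper()
    vowel_pos = [i for i, c in enumerate(w) if c in VOWELS]
    if not vowel_pos:
        raise ValueError(f"{word!r} contains no vowel to substitute")
    for _ in range(max_retries):
        letters = list(w)
        for i in vowel_pos:
            choices = [c for c in replacement_pool
                       if not (forbid_same and c == w[i])]
            letters[i] = choices[rng.integers(len(choices))]
        candidate = "".join(letters)
        if candidate not in lexicon:
            return candidate
    raise GenerationFailureError(
        f"could not derive a nonword from {word!r} in {max_retries} tries")


def generate_pseudoword(word: str, rng: np.random.Generator,
                        lexicon: Lexicon, max_retries: int = 100) -> str:
    """Replace every vowel with a different vowel; result is not in the lexicon."""
    return _substitute_vowels(word, rng, lexicon, VOWELS, True, max_retries)


def generate_consonant_string(word: str, rng: np.random.Generator,
                              lexicon: Lexicon, max_retries: int = 100) -> str:
    """Replace every vowel with a consonant; result is vowel-free and not a word."""
    return _substitute_vowels(word, rng, lexicon, CONSONANTS, False, max_retries)


@dataclass(frozen=True)
class DensityPair:
    """Word and nonword word-likeness densities over a shared grid.

    Evaluation outside the grid clamps to the edge value, so the posterior at
    extreme word-likeness follows whichever class has the heavier tail at the
    grid boundary and the uncertainty is never NaN.
    """

    grid: np.ndarray
    word_vals: np.ndarray
    nonword_vals: np.ndarray
    prior_word: float

    def word_density(self, x):
        return np.interp(x, self.grid, self.word_vals)

    def nonword_density(self, x):
        return np.interp(x, self.grid, self.nonword_vals)


def _kde_on_grid(sample: np.ndarray, grid: np.ndarray,
                 min_bw: float = 1e-3) -> np.ndarray:
    sample = np.asarray(sample, dtype=float)
    if np.std(sample) < 1e-12:
        warnings.warn("degenerate (zero-variance) sample; "
                      "falling back to minimum-bandwidth kernel")
        from scipy.stats import norm
        return norm.pdf(grid, loc=sample.mean(), scale=min_bw)
    kde = gaussian_kde(sample, bw_method="silverman")
    return kde(grid)


def silverman_bandwidth(sample: np.ndarray) -> float:
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    s = np.std(sample, ddof=1)
    return float(1.06 * max(s, 1e-3) * n ** (-1 / 5)) if n > 1 else 1e-3


def fit_wordlikeness_densities(word_old20s, nonword_old20s,
                               prior_word: float = 0.5,
                               n_grid: int = 512) -> DensityPair:
    """Gaussian-kernel density estimates for both classes on a shared grid.

    The grid spans [min - 3h, max + 3h] over the pooled samples, where h is
    the larger Silverman bandwidth of the two classes.
    """
    w = np.asarray(word_old20s, dtype=float)
    n = np.asarray(nonword_old20s, dtype=float)
    if w.size < 10 or n.size < 10:
        raise ValueError("need at least 10 word-likeness values per class")
    if not 0.0 < prior_word < 1.0:
        raise ValueError("prior_word must lie in (0, 1)")
    h = max(silverman_bandwidth(w), silverman_bandwidth(n))
    lo = min(w.min(), n.min()) - 3 * h
    hi = max(w.max(), n.max()) + 3 * h
    grid = np.linspace(lo, hi, n_grid)
    return DensityPair(grid, _kde_on_grid(w, grid), _kde_on_grid(n, grid),
                       float(prior_word))


def binary_entropy(p):
    """H(p) in bits, with H(0) = H(1) = 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    inner = (p > 0) & (p < 1)
    pi = p[inner]
    out[inner] = -pi * np.log2(pi) - (1 - pi) * np.log2(1 - pi)
    return out


def lcm_uncertainty(x, densities: DensityPair):
    """Binary entropy of the posterior P(word | word-likeness x), in bits."""
    x = np.asarray(x, dtype=float)
    dw = np.maximum(densities.word_density(x), DENSITY_FLOOR)
    dn = np.maximum(densities.nonword_density(x), DENSITY_FLOOR)
    both_floored = (densities.word_density(x) < DENSITY_FLOOR) & \
                   (densities.nonword_density(x) < DENSITY_FLOOR)
    prior = densities.prior_word
    p = prior * dw / (prior * dw + (1 - prior) * dn)
    h = binary_entropy(p)
    if np.any(both_floored):
        logger.warning("both class densities below floor at %d point(s); "
                       "returning maximal uncertainty there",
                       int(np.sum(both_floored)))
        h = np.where(both_floored, 1.0, h)
    return float(h) if h.ndim == 0 else h


def score_stimuli(items: pd.DataFrame, lexicon: Lexicon,
                  prior_word: float = 0.5) -> pd.DataFrame:
    """Attach old20, log_freq, lcm_uncertainty, and lexicality to stimuli.

    ``items`` needs columns ``letters`` and ``condition`` (word, pseudoword,
    consonant_string). Densities for the uncertainty score are fitted on the
    stimulus set's own word vs nonword OLD20 distributions.
    """
    df = items.copy()
    df["old20"] = [old20(s, lexicon) for s in df["letters"]]
    df["log_freq"] = [lexicon.log_freq(s) for s in df["letters"]]
    df["lexicality"] = (df["condition"] == "word").astype(int)
    dens = fit_wordlikeness_densities(
        df.loc[df["lexicality"] == 1, "old20"].to_numpy(),
        df.loc[df["lexicality"] == 0, "old20"].to_numpy(),
        prior_word=prior_word)
    df["lcm_uncertainty"] = lcm_uncertainty(df["old20"].to_numpy(), dens)
    return df
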