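"""Priming scores, group statistics, effect sizes and brain-behaviour
correlations.

Semantic priming is the mean identification volume of new words minus
synonyms to sleep-played words (positive = synonyms identified at lower
volume, i.e. primed).  Perceptual priming is the mean 2AFC response
latency of incorrect minus correct choices (positive = faster correct
retrieval).  Group tests are two-tailed; for t-tests the effect size
r = sign(t) * sqrt(t^2 / (t^2 + df)) is reported (the sign convention is
this package's own and is documented), and between-participant
associations use Spearman rank correlations, appropriate for the small
cohort sizes involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import BehaviorTable


@dataclass
class StatResult:
    statistic: float
    df: float
    p: float
    effect_size: float | None = None


@dataclass
class PrimingScores:
    """Per-participant behavioural outcome measures."""

    participant: int
    semantic_dB: float          # NaN when undefined
    perceptual_ms: float        # NaN when no correct or no incorrect trials
    accuracy_pct: float
    flags: tuple[str, ...] = ()


def semantic_priming_score(volumes_new, volumes_syn) -> float:
    """mean(new-word volumes) - mean(synonym volumes), in dB(A).

    Only correctly identified words should be passed in.  An empty list
    yields NaN with a warning (undefined score).
    """
    new = np.asarray(volumes_new, dtype=float)
    syn = np.asarray(volumes_syn, dtype=float)
    if new.size == 0 or syn.size == 0:
        warnings.warn("semantic priming undefined: empty condition",
                      stacklevel=2)
        return float("nan")
    return float(new.mean() - syn.mean())


def perceptual_priming_score(rt_incorrect, rt_correct) -> float:
    """mean(incorrect-choice RT) - mean(correct-choice RT), in ms."""
    inc = np.asarray(rt_incorrect, dtype=float)
    cor = np.asarray(rt_correct, dtype=float)
    if inc.size == 0 or cor.size == 0:
        warnings.warn("perceptual priming undefined: participant has no "
                      "correct or no incorrect responses", stacklevel=2)
        return float("nan")
    return float(inc.mean() - cor.mean())


def choice_accuracy(correct) -> float:
    """Percentage of correct 2AFC choices."""
    c = np.asarray(correct, dtype=bool)
    if c.size == 0:
        raise ValueError("no responses")
    return 100.0 * c.mean()


def scores_from_table(beh: BehaviorTable) -> PrimingScores:
    """Compute all priming scores from one participant's tables."""
    ident = beh.identification
    ident = ident[ident["identified"].astype(bool)]
    new = ident.loc[ident["condition"] == "new", "volume_dBA"]
    syn = ident.loc[ident["condition"] == "synonym", "volume_dBA"]
    afc = beh.afc
    cor = afc.loc[afc["correct"].astype(bool), "rt_ms"]
    inc = afc.loc[~afc["correct"].astype(bool), "rt_ms"]
    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sem = semantic_priming_score(new, syn)
        perc = perceptual_priming_score(inc, cor)
    if np.isnan(sem):
        flags.append("semantic_undefined")
    if np.isnan(perc):
        flags.append("perceptual_undefined")
    return PrimingScores(participant=beh.participant, semantic_dB=sem,
                         perceptual_ms=perc,
                         accuracy_pct=choice_accuracy(afc["correct"]),
                         flags=tuple(flags))


def one_sample_t(values) -> StatResult:
    """Two-tailed one-sample t-test against zero, with effect size r."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if x.std(ddof=1) == 0:
        if x.mean() == 0:
            return StatResult(0.0, x.size - 1, 1.0, 0.0)
        raise ValueError("zero variance with nonzero mean: t undefined")
    t, p = stats.ttest_1samp(x, 0.0)
    df = x.size - 1
    return StatResult(float(t), df, float(p), effect_size_r(float(t), df))


def effect_size_r(t: float, df: int) -> float:
    """r = sign(t) * sqrt(t^2 / (t^2 + df)).

    Monotone in |t|, tending to 1 as |t| grows; carries the sign of t.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    return float(np.sign(t) * np.sqrt(t * t / (t * t + df)))


def spearman_correlation(x, y) -> StatResult:
    """Spearman rank correlation (average ranks for ties), two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: correlation undefined", stacklevel=2)
        return StatResult(float("nan"), x.size - 2, float("nan"),
                          float("nan"))
    r, p = stats.spearmanr(x, y)
    return StatResult(float(r), x.size - 2, float(p), float(r))


def entrained_frequency(peak_latencies_ms, ndigits: int | None = None
                        ) -> float:
    """Rate (Hz) implied by successive up-state latencies:
    1 / mean(successive differences in s)."""
    lat = np.asarray(peak_latencies_ms, dtype=float)
    if lat.size < 2 or np.any(np.diff(lat) <= 0):
        raise ValueError("need at least 2 strictly increasing latencies")
    f = 1000.0 / float(np.mean(np.diff(lat)))
    return round(f, ndigits) if ndigits is not None else f


def brain_behavior_correlations(
    magnitudes: dict[str, np.ndarray],
    scores: pd.DataFrame,
    covariates: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Spearman correlation table between response magnitudes, priming
    scores and covariates.

    magnitudes: per-cluster mean amplitudes, one array per label (e.g.
    ``up_state_1``), aligned with the rows of ``scores`` (columns
    semantic_dB, perceptual_ms, accuracy_pct).  Pairs with NaN in either
    member are dropped per correlation; fewer than 3 complete pairs is an
    error.
    """
    score_cols = [c for c in ("semantic_dB", "perceptual_ms",
                              "accuracy_pct") if c in scores.columns]
    predictors = dict(magnitudes)
    predictors.update(covariates or {})
    rows = []
    for name, vals in predictors.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) != len(scores):
            raise ValueError(f"{name}: length mismatch with scores")
        for col in score_cols:
            y = scores[col].to_numpy(dtype=float)
            ok = ~(np.isnan(vals) | np.isnan(y))
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for ({name}, {col})")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = spearman_correlation(vals[ok], y[ok])
            rows.append((name, col, res.statistic, res.p, int(ok.sum())))
    return pd.DataFrame(rows, columns=["x", "y", "r_s", "p", "n"])
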