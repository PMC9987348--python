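"""Age-binned fitting and developmental trend estimation.

Transcripts are grouped into fixed six-month bins of child age (0;0-0;5,
0;6-0;11, ...); each bin pools the adult utterances of its transcripts and
is fitted like a full corpus, provided it reaches a minimal token count
(default 50,000 — below that, parameter estimates are unstable and the bin
is summarized only).  Age trends in the exponent or in fit quality are
estimated with a mixed-effects regression of the per-bin response on the
bin's start age in months (centred), with a by-language random intercept
and age slope, simplifying the random structure on convergence failure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .corpus_io import Utterance
from .rankfreq import assign_ranks, build_table, summarize
from .zipf_model import fit_mle

logger = logging.getLogger(__name__)

__all__ = ["AgeBin", "AgeTrend", "bin_by_age", "fit_bins", "age_trend"]

BIN_MONTHS = 6


@dataclass(frozen=True)
class AgeBin:
    start_months: int            # multiple of 6
    utterances: tuple[Utterance, ...]

    def __post_init__(self) -> None:
        if self.start_months % BIN_MONTHS:
            raise ValueError("bin start must be a multiple of 6 months")

    @property
    def end_months(self) -> int:
        return self.start_months + BIN_MONTHS - 1

    @property
    def label(self) -> str:
        s, e = self.start_months, self.end_months
        return f"{s // 12};{s % 12}–{e // 12};{e % 12}"

    @property
    def n_tokens(self) -> int:
        return sum(len(u.tokens) for u in self.utterances)


def bin_by_age(utterances: Iterable[Utterance]) -> list[AgeBin]:
    """Partition aged utterances into six-month bins.

    Each utterance lands in the bin containing its transcript's child age;
    utterances without a parseable age are excluded and counted in the log.
    """
    binned: dict[int, list[Utterance]] = {}
    n_unaged = 0
    for utt in utterances:
        age = utt.transcript.child_age_months if utt.transcript else None
        if age is None:
            n_unaged += 1
            continue
        start = (age // BIN_MONTHS) * BIN_MONTHS
        binned.setdefault(start, []).append(utt)
    if n_unaged:
        logger.info("excluded %d utterances without child age", n_unaged)
    return [AgeBin(s, tuple(us)) for s, us in sorted(binned.items())]


def fit_bins(
    bins: Sequence[AgeBin],
    min_tokens: int = 50_000,
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Per-bin summary table in the age-range/tokens/types/alpha/beta/r layout.

    Bins at or above ``min_tokens`` are fitted (MLE plus observed-vs-expected
    Pearson evaluation); smaller bins are summarized but carry missing
    parameters, so raising the threshold never adds fitted bins.
    """
    rows = []
    for b in bins:
        tokens = np.asarray([t for u in b.utterances for t in u.tokens], dtype=object)
        if tokens.size == 0:
            continue
        table = build_table(tokens)
        summ = summarize(table)
        row = {
            "age_range": b.label,
            "start_months": b.start_months,
            "n_tokens": int(summ["n_tokens"]),
            "n_types": summ["n_types"],
            "min_count": summ["min_count"],
            "max_count": summ["max_count"],
            "alpha": np.nan, "beta": np.nan,
            "pearson_r": np.nan, "fitted": False,
        }
        if tokens.size >= min_tokens:
            fit = fit_mle(assign_ranks(table, tie_seed=tie_seed))
            row.update(alpha=fit.params.alpha, beta=fit.params.beta,
                       pearson_r=fit.pearson_linear, fitted=True)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgeTrend:
    slope: float                 # change in response per month of age
    standard_error: float
    p_value: float
    response: str                # "alpha" | "pearson_r"
    method: str                  # random structure actually used
    intercept: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")


def age_trend(
    per_bin_fits: pd.DataFrame,
    response: str = "alpha",
    language_col: str = "language",
    age_col: str = "start_months",
) -> AgeTrend:
    """Mixed-effects slope of a per-bin response on bin start age.

    Age is centred; the model starts with a by-language random intercept and
    age slope and simplifies on convergence failure (intercept-only, then
    ordinary least squares).  p-values are Wald approximations (named in
    ``method``).
    """
    df = per_bin_fits.dropna(subset=[response]).copy()
    langs = df[language_col].nunique()
    if langs < 2 or (df.groupby(language_col).size() < 2).any():
        raise ValueError("need >= 2 bins per language for >= 2 languages")
    df["age_c"] = df[age_col] - df[age_col].mean()
    df["y"] = df[response]

    ladder = [("random intercept + slope", "~age_c"), ("random intercept", None)]
    for name, re_formula in ladder:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm("y ~ age_c", df, groups=df[language_col],
                                    re_formula=re_formula)
                res = model.fit(reml=True, method="lbfgs", maxiter=500)
            if res.converged and np.isfinite(res.bse["age_c"]):
                return AgeTrend(
                    slope=float(res.params["age_c"]),
                    standard_error=float(res.bse["age_c"]),
                    p_value=float(res.pvalues["age_c"]),
                    response=response,
                    method=f"MixedLM ({name}), Wald z",
                    intercept=float(res.params["Intercept"]),
                )
        except Exception as exc:  # noqa: BLE001 - fall down the ladder
            logger.info("mixed model (%s) failed: %s", name, exc)
    # fixed-effects fallback
    X = sm.add_constant(df["age_c"])
    ols = sm.OLS(df["y"], X).fit()
    if not np.isfinite(ols.bse["age_c"]):
        raise RuntimeError("age trend unestimable even by OLS")
    logger.warning("mixed models failed to converge; reporting OLS trend")
    return AgeTrend(
        slope=float(ols.params["age_c"]),
        standard_error=float(ols.bse["age_c"]),
        p_value=float(ols.pvalues["age_c"]),
        response=response,
        method="OLS (fixed effects only), t test",
        intercept=float(ols.params["const"]),
    )
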