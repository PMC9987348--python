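"""Part-of-speech extraction and per-category distribution fitting.

Tokens are classified per occurrence by their aligned morphology-tier
category code — an ambiguous surface form ("run") counts toward whichever
category each individual occurrence was tagged with.  Mistagged types are
removed via plain-text exclusion lists (one word per line), the automated
surrogate for manual cleaning by native-speaker annotators; removed words
are *not* reassigned to their correct category.  The per-category error rate
is |excluded types| / |types extracted|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Utterance
from .rankfreq import FrequencyTable, assign_ranks, build_table, summarize
from .zipf_model import FitResult, fit_mle

logger = logging.getLogger(__name__)

__all__ = [
    "POSCategory",
    "ExclusionList",
    "DEFAULT_PROFILE",
    "extract_pos_tokens",
    "apply_exclusions",
    "load_exclusions",
    "fit_pos",
    "pos_report",
]

MIN_TYPES_FOR_FIT = 10


@dataclass(frozen=True)
class POSCategory:
    """One of the four analysed categories and its morphology-tier codes."""

    label: str
    tag_patterns: frozenset[str]


#: default CHILDES-style %mor code mapping; exact codes, no subcategory
#: absorption — edit per language as needed.
DEFAULT_PROFILE: tuple[POSCategory, ...] = (
    POSCategory("noun", frozenset({"n"})),
    POSCategory("verb", frozenset({"v"})),
    POSCategory("adjective", frozenset({"adj"})),
    POSCategory("preposition", frozenset({"prep"})),
)


@dataclass(frozen=True)
class ExclusionList:
    category: str
    excluded_types: frozenset[str]


def extract_pos_tokens(
    utterances: Iterable[Utterance],
    category: POSCategory,
) -> list[str]:
    """Tokens whose aligned morphology tag matches the category.

    Untagged utterances are skipped and counted; classification is
    per-token, so a surface form tagged both noun and verb contributes its
    occurrences to each category separately.
    """
    out: list[str] = []
    n_untagged = n_tagged = 0
    for utt in utterances:
        if utt.pos_tags is None:
            n_untagged += 1
            continue
        n_tagged += 1
        out.extend(
            tok for tok, tag in zip(utt.tokens, utt.pos_tags)
            if tag in category.tag_patterns
        )
    if n_tagged == 0:
        raise ValueError("no tagged utterances available")
    if n_untagged:
        logger.info("skipped %d untagged utterances for %s", n_untagged, category.label)
    return out


def load_exclusions(path: str | Path, category: str) -> ExclusionList:
    """One excluded word form per line; blank lines and # comments ignored."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        w = line.strip()
        if w and not w.startswith("#"):
            words.add(w)
    return ExclusionList(category=category, excluded_types=frozenset(words))


def apply_exclusions(
    table: FrequencyTable,
    exclusions: ExclusionList,
) -> tuple[FrequencyTable, float]:
    """Remove mistagged types; return the cleaned table and the error rate.

    error_rate = |excluded types present| / |types before exclusion|.
    Excluding a word absent from the table warns and is otherwise ignored.
    """
    n_before = table.n_types
    if n_before == 0:
        raise ValueError("empty frequency table")
    present = exclusions.excluded_types & set(table.counts)
    missing = exclusions.excluded_types - present
    if missing:
        logger.warning("%d excluded types not found in %s table",
                       len(missing), exclusions.category)
    cleaned = FrequencyTable({w: c for w, c in table.counts.items() if w not in present})
    return cleaned, len(present) / n_before


def fit_pos(tokens: Sequence[str], tie_seed: int = 0) -> FitResult | None:
    """Zipf-Mandelbrot fit of one category's token stream.

    Returns None (summary only) below 10 types, where exponent estimates are
    unreliable; degenerate fits report parameters but no correlations.
    """
    table = build_table(np.asarray(tokens, dtype=object))
    if table.n_types < MIN_TYPES_FOR_FIT:
        logger.warning("only %d types; too few for a reliable fit", table.n_types)
        return None
    return fit_mle(assign_ranks(table, tie_seed=tie_seed))


def pos_report(
    utterances: Iterable[Utterance],
    profile: Sequence[POSCategory] = DEFAULT_PROFILE,
    exclusions: Mapping[str, ExclusionList] | None = None,
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Per-category table: tokens, types, frequency range, error rate, fit."""
    utterances = list(utterances)
    exclusions = exclusions or {}
    rows = []
    for cat in profile:
        row = {"category": cat.label, "n_tokens": 0, "n_types": 0,
               "min_count": np.nan, "max_count": np.nan, "error_rate": np.nan,
               "alpha": np.nan, "beta": np.nan, "pearson_r": np.nan,
               "degenerate": False}
        try:
            tokens = extract_pos_tokens(utterances, cat)
        except ValueError:
            raise
        if not tokens:
            logger.warning("no tokens for category %s", cat.label)
            rows.append(row)
            continue
        table = build_table(np.asarray(tokens, dtype=object))
        rate = 0.0
        if cat.label in exclusions:
            table, rate = apply_exclusions(table, exclusions[cat.label])
        summ = summarize(table)
        row.update(n_tokens=int(summ["n_tokens"]), n_types=summ["n_types"],
                   min_count=summ["min_count"], max_count=summ["max_count"],
                   error_rate=rate)
        if table.n_types >= MIN_TYPES_FOR_FIT:
            fit = fit_mle(assign_ranks(table, tie_seed=tie_seed))
            row.update(alpha=fit.params.alpha, beta=fit.params.beta,
                       pearson_r=fit.pearson_linear, degenerate=fit.degenerate)
        rows.append(row)
    return pd.DataFrame(rows)
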