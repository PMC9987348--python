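"""Conversationally-continuous subsampling and cross-group comparison.

A "conversationally continuous" sample concatenates whole transcripts in
order until a target token count is reached: transcripts are never split
mid-file, so each sample preserves within-conversation structure.  The
module also provides the sample-size stability curve (repeatedly fitting
samples of growing size) and a one-way ANOVA comparing fitted exponents
across groups (languages or language families).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import TranscriptMeta
from .rankfreq import assign_ranks, build_table
from .zipf_model import fit_mle

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptTokens",
    "SampleSlice",
    "continuous_samples",
    "stability_curve",
    "compare_groups",
]


@dataclass(frozen=True)
class TranscriptTokens:
    """A transcript's metadata together with its adult token stream."""

    meta: TranscriptMeta
    tokens: tuple[str, ...]

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class SampleSlice:
    tokens: tuple[str, ...]
    source_transcripts: tuple[TranscriptMeta, ...]
    target_size: int

    @property
    def actual_size(self) -> int:
        return len(self.tokens)

    def __post_init__(self) -> None:
        if self.actual_size < self.target_size:
            raise ValueError("emitted slice below target size")


def continuous_samples(
    transcripts: Sequence[TranscriptTokens],
    target: int,
) -> list[SampleSlice]:
    """Greedy whole-transcript accumulation into >= target-token slices.

    Transcripts are consumed in ``ordering_key`` order; a slice is emitted
    as soon as the running total reaches the target, and the next slice
    starts from the following transcript.  A trailing remainder below the
    target is discarded with a log message.
    """
    ordered = sorted(transcripts, key=lambda t: t.meta.ordering_key)
    slices: list[SampleSlice] = []
    buf: list[str] = []
    srcs: list[TranscriptMeta] = []
    for tr in ordered:
        buf.extend(tr.tokens)
        srcs.append(tr.meta)
        if len(buf) >= target:
            slices.append(SampleSlice(tuple(buf), tuple(srcs), target))
            buf, srcs = [], []
    if buf:
        logger.info("discarded trailing remainder of %d tokens (< %d)", len(buf), target)
    if not slices:
        logger.warning("corpus smaller than target %d; no samples", target)
    return slices


def _sample_of_size(
    transcripts: Sequence[TranscriptTokens],
    size: int,
    rng: np.random.Generator,
) -> list[str]:
    """Random-start continuous sample: shuffle transcripts, read each from
    beginning to end until the requested token count is reached."""
    order = rng.permutation(len(transcripts))
    buf: list[str] = []
    for idx in order:
        need = size - len(buf)
        if need <= 0:
            break
        buf.extend(transcripts[idx].tokens[:need])
    return buf


def stability_curve(
    transcripts: Sequence[TranscriptTokens],
    sizes: Sequence[int] = tuple(range(5_000, 100_001, 5_000)),
    replicates: int = 10,
    seed: int = 0,
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Fitted exponent as a function of sample size.

    For each size, ``replicates`` random continuous samples are drawn and
    fitted; rows carry (sample_size, replicate, alpha_hat, beta_hat).  Sizes
    exceeding the corpus are skipped with a warning.  Deterministic given
    ``seed``.
    """
    total = sum(t.n_tokens for t in transcripts)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > total:
            logger.warning("size %d exceeds corpus (%d tokens); skipped", size, total)
            continue
        for rep in range(replicates):
            tokens = _sample_of_size(transcripts, size, rng)
            ranked = assign_ranks(build_table(np.asarray(tokens, dtype=object)),
                                  tie_seed=tie_seed)
            fit = fit_mle(ranked)
            rows.append({"sample_size": size, "replicate": rep,
                         "alpha_hat": fit.params.alpha, "beta_hat": fit.params.beta})
    return pd.DataFrame(rows)


def summarize_stability(curve: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the fitted exponent per sample size."""
    return (
        curve.groupby("sample_size")["alpha_hat"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "alpha_mean", "std": "alpha_sd", "count": "n"})
    )


def compare_groups(fits: pd.DataFrame, group_col: str = "group",
                   value_col: str = "alpha_hat") -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of fitted exponents across groups.

    Returns (F, (k-1, n-k), p).  Requires >= 2 groups and some within-group
    variance.
    """
    groups = [g[value_col].to_numpy() for _, g in fits.groupby(group_col)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = sum(len(g) for g in groups)
    if all(np.ptp(g) == 0 for g in groups if len(g) > 1) and not any(
        len(g) > 1 and np.ptp(g) > 0 for g in groups
    ):
        raise ValueError("zero within-group variance everywhere; F undefined")
    f_stat, p = stats.f_oneway(*groups)
    return float(f_stat), (len(groups) - 1, n - len(groups)), float(p)
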