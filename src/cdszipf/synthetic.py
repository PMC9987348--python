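"""Synthetic corpora with the statistical structure the analyses assume.

Token streams are drawn i.i.d. from a Zipf-Mandelbrot PMF over a fixed
vocabulary, then packed into CHAT transcripts with child-age headers, an
optional child speaker (to exercise adult filtering) and optional %mor
morphology tiers (to exercise part-of-speech extraction).  The rank->word
mapping is fixed and injective ("w00001" is always true rank 1), so the
generating rank is recoverable for diagnostics.

Word sampling is i.i.d.: burstiness, variation sets and discourse structure
of real child-directed speech are deliberately not modelled — the generator
exists to test distribution-level machinery, not to imitate conversation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rankfreq import assign_ranks, build_table
from .zipf_model import ZipfParams, fit_mle, zm_pmf

__all__ = [
    "PosProfile",
    "SyntheticSpec",
    "sample_zm",
    "sample_zm_ranks",
    "make_corpus",
    "write_corpus",
    "uniform_corpus",
    "recovery_experiment",
]


@dataclass(frozen=True)
class PosProfile:
    """Per-category generating parameters for tagged corpora."""

    label: str            # e.g. "noun"
    tag: str              # %mor category code, e.g. "n"
    alpha: float
    beta: float
    vocab_size: int
    token_share: float    # fraction of tokens drawn from this category


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters for one simulated corpus."""

    alpha: float = 1.38          # cross-language mean exponent in CDS
    beta: float = 9.86           # cross-language mean shift
    vocab_size: int = 10_000
    n_tokens: int = 1_000_000
    mean_utterance_length: float = 6.0   # geometric; plumbing choice
    transcript_size: int = 2_000         # tokens per transcript
    age_schedule: tuple[int, ...] = ()   # months per transcript, cycled
    pos_profile: tuple[PosProfile, ...] = ()
    child_fraction: float = 0.1
    language: str = "synthetic"
    corpus_name: str = "synthcorp"
    seed: int = 0

    def __post_init__(self) -> None:
        ZipfParams(self.alpha, self.beta)  # validate
        if self.vocab_size < 1 or self.n_tokens < 1:
            raise ValueError("vocab_size and n_tokens must be >= 1")
        if not 0 <= self.child_fraction < 1:
            raise ValueError("child_fraction must be in [0, 1)")
        if self.pos_profile:
            share = sum(p.token_share for p in self.pos_profile)
            if not np.isclose(share, 1.0):
                raise ValueError("pos_profile token shares must sum to 1")

    @property
    def params(self) -> ZipfParams:
        return ZipfParams(self.alpha, self.beta)


def _vocab(vocab_size: int, prefix: str = "w") -> np.ndarray:
    width = max(5, len(str(vocab_size)))
    return np.array([f"{prefix}{r:0{width}d}" for r in range(1, vocab_size + 1)],
                    dtype=object)


def sample_zm_ranks(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """n_tokens i.i.d. rank draws (1-based) from the generating PMF."""
    rng = rng or np.random.default_rng(spec.seed)
    p = zm_pmf(spec.params, spec.vocab_size)
    # inverse-CDF sampling: one searchsorted pass over n uniforms
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(spec.n_tokens), side="right") + 1


def sample_zm(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Token stream of word forms w00001..; deterministic given spec.seed."""
    ranks = sample_zm_ranks(spec, rng)
    return _vocab(spec.vocab_size)[ranks - 1]


def _sample_tagged(spec: SyntheticSpec, rng: np.random.Generator):
    """(words, tags) streams when a POS profile is present."""
    shares = np.array([p.token_share for p in spec.pos_profile])
    which = rng.choice(len(spec.pos_profile), size=spec.n_tokens, p=shares)
    words = np.empty(spec.n_tokens, dtype=object)
    tags = np.empty(spec.n_tokens, dtype=object)
    for i, prof in enumerate(spec.pos_profile):
        mask = which == i
        n_i = int(mask.sum())
        sub = SyntheticSpec(alpha=prof.alpha, beta=prof.beta,
                            vocab_size=prof.vocab_size, n_tokens=max(n_i, 1))
        ranks = sample_zm_ranks(sub, rng)[:n_i]
        words[mask] = _vocab(prof.vocab_size, prefix=f"{prof.tag}_w")[ranks - 1]
        tags[mask] = prof.tag
    return words, tags


def _utterance_lengths(rng: np.random.Generator, n_tokens: int, mean: float) -> list[int]:
    lengths: list[int] = []
    total = 0
    while total < n_tokens:
        # geometric on {1, 2, ...} with the configured mean
        ln = int(rng.geometric(1.0 / mean))
        ln = min(ln, n_tokens - total)
        lengths.append(ln)
        total += ln
    return lengths


def make_corpus(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """Render the sampled stream as CHAT transcripts.

    Returns (filename, chat_text) pairs.  Adult tokens are exactly the
    sampled stream; an additional ``child_fraction`` of utterances is
    emitted under the Target_Child role (drawn from the same distribution
    but *not* part of the adult stream), so adult filtering is exercised and
    the adult token count round-trips exactly.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.pos_profile:
        words, tags = _sample_tagged(spec, rng)
    else:
        words, tags = sample_zm(spec, rng), None

    ages = spec.age_schedule or (24,)
    files: list[tuple[str, str]] = []
    pos = 0
    t_index = 0
    while pos < spec.n_tokens:
        t_tokens = min(spec.transcript_size, spec.n_tokens - pos)
        age = ages[t_index % len(ages)]
        lines = [
            "@UTF8",
            "@Begin",
            f"@Languages:\t{spec.language}",
            "@Participants:\tMOT Mother, CHI Target_Child",
            f"@ID:\t{spec.language}|{spec.corpus_name}|MOT|35;00.|female|||Mother||",
            f"@ID:\t{spec.language}|{spec.corpus_name}|CHI|{age // 12};{age % 12}.|female|||Target_Child||",
        ]
        for ln in _utterance_lengths(rng, t_tokens, spec.mean_utterance_length):
            utt = words[pos:pos + ln]
            lines.append("*MOT:\t" + " ".join(utt) + " .")
            if tags is not None:
                mor = " ".join(f"{t}|{w}" for t, w in zip(tags[pos:pos + ln], utt))
                lines.append("%mor:\t" + mor + " .")
            pos += ln
            if spec.child_fraction and rng.random() < spec.child_fraction:
                c_ln = int(rng.geometric(1.0 / max(spec.mean_utterance_length / 2, 1.0)))
                c_ranks = rng.integers(1, spec.vocab_size + 1, size=c_ln)
                c_words = _vocab(spec.vocab_size)[c_ranks - 1]
                lines.append("*CHI:\t" + " ".join(c_words) + " .")
        lines.append("@End")
        files.append((f"{spec.corpus_name}_{t_index:04d}.cha", "\n".join(lines) + "\n"))
        t_index += 1
    return files


def write_corpus(spec: SyntheticSpec, directory: str | Path) -> list[Path]:
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, text in make_corpus(spec):
        p = out / name
        p.write_text(text, encoding="utf-8")
        paths.append(p)
    return paths


def uniform_corpus(vocab_size: int, n_tokens: int, seed: int = 0) -> np.ndarray:
    """Baseline stream where each type appears (near-)equally often.

    Each type appears floor(n/V) or ceil(n/V) times, order shuffled — the
    uniform-exposure condition used in lab studies of word segmentation.
    """
    if vocab_size > n_tokens:
        raise ValueError("vocab_size may not exceed n_tokens")
    base, extra = divmod(n_tokens, vocab_size)
    counts = np.full(vocab_size, base)
    counts[:extra] += 1
    stream = np.repeat(_vocab(vocab_size), counts)
    np.random.default_rng(seed).shuffle(stream)
    return stream


def recovery_experiment(
    grid: Sequence[tuple[float, float]],
    sizes: Sequence[int],
    replicates: int,
    seed: int = 0,
    vocab_size: int = 10_000,
) -> pd.DataFrame:
    """Generate -> rank -> fit over a (alpha, beta) x size grid.

    Each cell/replicate runs the full pipeline (sample_zm, assign_ranks,
    fit_mle) on an independent seeded stream.  Fit failures are recorded as
    NaN rows, not raised.  Returns tidy rows plus per-cell bias/RMSE via
    ``summarize_recovery``.
    """
    rows = []
    root = np.random.default_rng(seed)
    for alpha, beta in grid:
        for n in sizes:
            for rep in range(replicates):
                sub_seed = int(root.integers(2**31))
                spec = SyntheticSpec(alpha=alpha, beta=beta, vocab_size=vocab_size,
                                     n_tokens=n, seed=sub_seed)
                try:
                    tokens = sample_zm(spec)
                    ranked = assign_ranks(build_table(tokens), tie_seed=sub_seed)
                    fit = fit_mle(ranked)
                    a_hat, b_hat = fit.params.alpha, fit.params.beta
                except Exception:  # noqa: BLE001 - recorded, not fatal
                    a_hat = b_hat = float("nan")
                rows.append(
                    {"alpha": alpha, "beta": beta, "n_tokens": n, "replicate": rep,
                     "seed": sub_seed, "alpha_hat": a_hat, "beta_hat": b_hat}
                )
    return pd.DataFrame(rows)


def summarize_recovery(report: pd.DataFrame) -> pd.DataFrame:
    """Bias and RMSE of alpha_hat/beta_hat per (alpha, beta, n_tokens) cell."""
    df = report.assign(
        alpha_err=report["alpha_hat"] - report["alpha"],
        beta_err=report["beta_hat"] - report["beta"],
    )

    def _agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {"alpha_bias": g["alpha_err"].mean(),
             "alpha_rmse": np.sqrt((g["alpha_err"] ** 2).mean()),
             "beta_bias": g["beta_err"].mean(),
             "beta_rmse": np.sqrt((g["beta_err"] ** 2).mean()),
             "n_failed": int(g["alpha_hat"].isna().sum())}
        )

    grouped = df.groupby(["alpha", "beta", "n_tokens"])
    return grouped.apply(_agg, include_groups=False).reset_index()
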