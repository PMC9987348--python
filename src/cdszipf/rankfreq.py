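"""Word-frequency tables and rank-ordered distributions.

A :class:`FrequencyTable` maps word forms to counts; a
:class:`RankedDistribution` orders those counts by descending frequency,
assigning rank 1 to the most frequent type.  Types sharing a count are given
a random permutation of the consecutive ranks in their tie block — the
rank->frequency mapping is therefore identical for every tie-break seed, but
the word->rank mapping is not.  Counts may be fractional, because some
frequency lists report relative frequencies rather than raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyTable",
    "RankedDistribution",
    "build_table",
    "assign_ranks",
    "per_million",
    "summarize",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Association of word form -> count (count > 0, possibly fractional)."""

    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [w for w, c in self.counts.items() if not c > 0]
        if bad:
            raise ValueError(f"non-positive counts for {bad[:5]!r}")

    @property
    def total_tokens(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def n_types(self) -> int:
        return len(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class RankedDistribution:
    """Counts ordered by rank r = 1..N (non-increasing), with aligned words."""

    words: tuple[str, ...]
    frequencies: np.ndarray = field(repr=False)
    tie_seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.ndim != 1 or freqs.size != len(self.words):
            raise ValueError("words and frequencies must align 1:1")
        if freqs.size == 0:
            raise ValueError("empty distribution")
        if np.any(np.diff(freqs) > 0):
            raise ValueError("frequencies must be non-increasing in rank")

    @property
    def n_types(self) -> int:
        return self.frequencies.size

    @property
    def n_tokens(self) -> float:
        return float(self.frequencies.sum())

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, self.frequencies.size + 1)

    def to_frame(self) -> pd.DataFrame:
        """Rank/word/count/per-million table (the CSV export layout)."""
        total = self.n_tokens
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "word": list(self.words),
                "count": self.frequencies,
                "per_million": [per_million(c, total) for c in self.frequencies],
            }
        )


def build_table(tokens: Iterable[str]) -> FrequencyTable:
    """Count occurrences per distinct word form.

    The total equals the input length; an empty stream yields an empty table.
    """
    if isinstance(tokens, np.ndarray) and tokens.size > 100_000:
        counted = pd.Series(tokens).value_counts()
        return FrequencyTable(dict(zip(counted.index, counted.to_numpy(dtype=float))))
    counts: dict[str, float] = {}
    for tok in tokens:
        counts[tok] = counts.get(tok, 0.0) + 1.0
    return FrequencyTable(counts)


def assign_ranks(table: FrequencyTable, tie_seed: int = 0) -> RankedDistribution:
    """Order types by descending count, breaking ties at random.

    Words sharing a count receive a uniform random permutation of the
    consecutive ranks in their tie block, driven by ``tie_seed``.  The
    frequency vector itself is seed-invariant.
    """
    if table.n_types == 0:
        raise ValueError("cannot rank an empty frequency table")
    rng = np.random.default_rng(tie_seed)
    words = np.array(list(table.counts.keys()), dtype=object)
    freqs = np.fromiter(table.counts.values(), dtype=float, count=len(words))
    # random pre-shuffle + stable sort on -count = uniform permutation per tie block
    perm = rng.permutation(words.size)
    words, freqs = words[perm], freqs[perm]
    order = np.argsort(-freqs, kind="stable")
    return RankedDistribution(
        words=tuple(words[order]), frequencies=freqs[order], tie_seed=tie_seed
    )


def per_million(count: float, total_tokens: float) -> float:
    """Frequency per million tokens, reported to two decimals."""
    if total_tokens <= 0:
        raise ValueError("total_tokens must be positive")
    return round(1e6 * count / total_tokens, 2)


def summarize(table: FrequencyTable) -> dict[str, float]:
    """Token/type totals and raw + per-million frequency range."""
    if table.n_types == 0:
        raise ValueError("cannot summarize an empty frequency table")
    values = np.fromiter(table.counts.values(), dtype=float, count=table.n_types)
    total = float(values.sum())
    return {
        "n_tokens": total,
        "n_types": table.n_types,
        "min_count": float(values.min()),
        "max_count": float(values.max()),
        "min_per_million": per_million(float(values.min()), total),
        "max_per_million": per_million(float(values.max()), total),
    }
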