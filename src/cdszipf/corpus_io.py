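"""Reading CHAT transcripts and frequency lists.

Implements the minimal subset of the CHAT transcript format needed for
rank-frequency analysis of adult speech: ``@`` header lines (``@ID``,
``@Participants``), ``*`` main speaker tiers with tab continuation lines,
and the ``%mor`` morphology tier.  Overlap markers, timing and media links
are out of scope.

Cleaning follows the conventions of cross-linguistic CHILDES corpus work:
bracketed transcriber annotations, event/filler codes (``&=laughs``,
``&-uh``), unintelligible-speech codes (``xxx``/``yyy``/``www``), omitted
words (``0token``) and utterance punctuation are removed, and a word is its
orthographic surface form (clitic/compound separators kept).  Word forms are
lower-cased by default so that sentence-initial capitalisation does not
split types.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .rankfreq import FrequencyTable

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptMeta",
    "Utterance",
    "CorpusSelection",
    "parse_chat",
    "parse_age",
    "clean_tokens",
    "filter_adult",
    "read_frequency_list",
    "read_chat_file",
    "read_chat_dir",
    "write_token_stream",
    "adult_tokens",
]

#: speaker roles treated as the child whose input we measure
CHILD_ROLES = frozenset({"Target_Child", "Child"})
#: other young interlocutors, excluded by default (configurable)
YOUNG_ROLES = frozenset({"Sibling", "Playmate", "Brother", "Sister", "Cousin"})

_UNINTELLIGIBLE = frozenset({"xxx", "yyy", "www"})
_AGE_RE = re.compile(r"^(\d+);(\d+)(?:\.(\d*))?$")
_BRACKET_RE = re.compile(r"\[[^\]]*\]")


@dataclass(frozen=True)
class TranscriptMeta:
    """Identity and child-age metadata for one transcript."""

    path: str
    corpus_name: str = ""
    language: str = ""
    child_age_months: int | None = None
    ordering_key: tuple = ()

    def __post_init__(self) -> None:
        if self.child_age_months is not None and not (0 <= self.child_age_months < 240):
            raise ValueError(f"implausible child age: {self.child_age_months} months")
        if not self.ordering_key:
            object.__setattr__(self, "ordering_key", (self.corpus_name, self.path))


@dataclass(frozen=True)
class Utterance:
    speaker_code: str
    speaker_role: str
    tokens: tuple[str, ...]
    pos_tags: tuple[str, ...] | None = None
    transcript: TranscriptMeta | None = None

    def __post_init__(self) -> None:
        if self.pos_tags is not None and len(self.pos_tags) != len(self.tokens):
            raise ValueError("pos_tags must align 1:1 with tokens")


@dataclass(frozen=True)
class CorpusSelection:
    """Inclusion rules for building an adult-speech corpus."""

    max_child_age_months: int = 42
    adult_roles_excluded: frozenset[str] = field(
        default_factory=lambda: CHILD_ROLES | YOUNG_ROLES
    )
    min_corpus_tokens: int = 100_000
    lowercase: bool = True

    def __post_init__(self) -> None:
        if self.min_corpus_tokens <= 0:
            raise ValueError("min_corpus_tokens must be positive")


def parse_age(age_text: str) -> int | None:
    """CHAT age notation ``Y;M`` or ``Y;M.D`` -> months (days dropped)."""
    if not age_text or not age_text.strip():
        return None
    m = _AGE_RE.match(age_text.strip())
    if m is None:
        raise ValueError(f"unparseable CHAT age: {age_text!r}")
    return 12 * int(m.group(1)) + int(m.group(2))


def _strip_word(tok: str) -> str:
    # terminal punctuation and quote characters are markup, not word material
    return tok.strip(".,!?;:\"“”‘’()<>«»")


def clean_tokens(main_tier_text: str, lowercase: bool = True) -> list[str]:
    """Orthographic word forms from a main-tier line.

    Removes bracketed annotations, event/filler codes, unintelligible codes,
    omitted-word codes and punctuation.  Never returns empty strings or
    strings containing whitespace.
    """
    text = _BRACKET_RE.sub(" ", main_tier_text)
    # stray group delimiters (unmatched brackets, angle-bracket scopes) are
    # markup, never word material
    text = re.sub(r"[\[\]<>]", " ", text)
    out: list[str] = []
    for raw in text.split():
        if raw.startswith("&") or raw.startswith("0") or raw.startswith("+"):
            continue
        tok = _strip_word(raw)
        if not tok or tok.lower() in _UNINTELLIGIBLE:
            continue
        if not any(ch.isalnum() for ch in tok):
            continue
        out.append(tok.lower() if lowercase else tok)
    return out


def _clean_mor(mor_text: str) -> list[str]:
    """Category codes from a %mor tier: ``n|doggy`` -> ``n``."""
    tags = []
    for item in mor_text.split():
        if not any(ch.isalnum() for ch in item):
            continue  # utterance terminator on the mor tier
        tags.append(item.split("|", 1)[0] if "|" in item else item)
    return tags


def _logical_lines(raw: str) -> list[str]:
    """Join tab-continuation lines onto their tier line."""
    lines: list[str] = []
    for line in raw.splitlines():
        if line.startswith(("\t", " ")) and lines:
            lines[-1] += " " + line.strip()
        elif line.strip():
            lines.append(line.rstrip())
    return lines


def parse_chat(
    raw_transcript: str,
    path: str = "",
    lowercase: bool = True,
) -> tuple[TranscriptMeta, list[Utterance]]:
    """Parse CHAT text into transcript metadata and utterances.

    Speaker roles come from ``@ID`` headers (falling back to
    ``@Participants``); the child's age is taken from the target child's
    ``@ID`` record.  ``%mor`` lines are attached as ``pos_tags`` when their
    length matches the cleaned main tier; mismatches are dropped with a
    debug log.  Malformed headers degrade to warnings, never errors.
    """
    roles: dict[str, str] = {}
    corpus_name, language = "", ""
    age_months: int | None = None

    body: list[tuple[str, str]] = []  # (tier, text) with tier like *MOT / %mor
    for line in _logical_lines(raw_transcript):
        if ":" in line:
            head, _, rest = line.partition(":")
            rest = rest.strip()
        else:
            head, rest = line, ""
        if head.startswith("@ID"):
            fields = [f.strip() for f in rest.split("|")]
            if len(fields) < 8:
                logger.warning("malformed @ID in %s: %r", path, rest)
                continue
            lang, corpus, code, age_text, role = (
                fields[0], fields[1], fields[2], fields[3], fields[7],
            )
            roles[code] = role or roles.get(code, "")
            corpus_name = corpus_name or corpus
            language = language or lang
            if role in CHILD_ROLES or code == "CHI":
                try:
                    parsed = parse_age(age_text)
                except ValueError:
                    logger.warning("unparseable age %r in %s", age_text, path)
                    parsed = None
                if parsed is not None:
                    age_months = parsed
        elif head.startswith("@Participants"):
            for part in rest.split(","):
                bits = part.split()
                if len(bits) >= 2:
                    roles.setdefault(bits[0], bits[-1])
        elif head.startswith("*") or head.startswith("%"):
            body.append((head, rest))

    meta = TranscriptMeta(
        path=path, corpus_name=corpus_name, language=language,
        child_age_months=age_months,
    )

    utterances: list[Utterance] = []
    for tier, text in body:
        if tier.startswith("*"):
            code = tier[1:]
            tokens = clean_tokens(text, lowercase=lowercase)
            utterances.append(
                Utterance(
                    speaker_code=code,
                    speaker_role=roles.get(code, ""),
                    tokens=tuple(tokens),
                    transcript=meta,
                )
            )
        elif tier == "%mor" and utterances:
            tags = _clean_mor(text)
            prev = utterances[-1]
            if len(tags) == len(prev.tokens) and prev.pos_tags is None:
                utterances[-1] = Utterance(
                    speaker_code=prev.speaker_code,
                    speaker_role=prev.speaker_role,
                    tokens=prev.tokens,
                    pos_tags=tuple(tags),
                    transcript=meta,
                )
            else:
                logger.debug("%%mor misaligned in %s (%d tags, %d tokens)",
                             path, len(tags), len(prev.tokens))
    if not utterances:
        logger.warning("no main tiers in %s", path)
    return meta, utterances


def filter_adult(
    utterances: Iterable[Utterance],
    selection: CorpusSelection | None = None,
) -> list[Utterance]:
    """Keep utterances from adult speakers (caregivers and experimenters).

    Utterances whose role is in ``adult_roles_excluded`` are dropped; unknown
    roles are kept and logged (conservative inclusion of adults).  Idempotent.
    """
    selection = selection or CorpusSelection()
    kept = []
    for utt in utterances:
        if utt.speaker_role in selection.adult_roles_excluded:
            continue
        if not utt.speaker_role and utt.speaker_code == "CHI":
            continue  # unresolved role but canonical child code
        if not utt.speaker_role:
            logger.info("unknown role for speaker %s; kept", utt.speaker_code)
        kept.append(utt)
    return kept


def adult_tokens(
    utterances: Iterable[Utterance],
    selection: CorpusSelection | None = None,
) -> list[str]:
    """Flat adult token stream, the unit every analysis consumes."""
    return [t for u in filter_adult(utterances, selection) for t in u.tokens]


def read_chat_file(path: str | Path, lowercase: bool = True):
    p = Path(path)
    return parse_chat(p.read_text(encoding="utf-8"), path=str(p), lowercase=lowercase)


def read_chat_dir(directory: str | Path, lowercase: bool = True):
    """Parse every ``.cha`` file under a directory, sorted by path."""
    out = []
    for p in sorted(Path(directory).rglob("*.cha")):
        out.append(read_chat_file(p, lowercase=lowercase))
    return out


def read_frequency_list(path_or_frame, word_col=0, count_col=1) -> FrequencyTable:
    """Two-column (word, count) table -> FrequencyTable.

    Counts may be relative frequencies (non-integers permitted; some
    published lists report fractional totals).  Duplicate words are summed
    with a warning; non-positive counts are rejected row-wise.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        sep = "\t" if str(path_or_frame).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path_or_frame, sep=sep, header=None, comment="#")
        if isinstance(df.iloc[0, count_col], str):  # header row present
            df = pd.read_csv(path_or_frame, sep=sep, comment="#")
    words = df.iloc[:, word_col].astype(str)
    counts = pd.to_numeric(df.iloc[:, count_col], errors="coerce")
    bad = counts.isna() | (counts <= 0)
    if bad.any():
        logger.warning("rejected %d rows with non-positive/invalid counts", bad.sum())
    words, counts = words[~bad], counts[~bad]
    if words.duplicated().any():
        logger.warning("summed %d duplicate word rows", words.duplicated().sum())
    merged = counts.groupby(words).sum()
    return FrequencyTable(dict(merged.items()))


def write_token_stream(
    path: str | Path,
    utterances: Sequence[Utterance],
    meta: TranscriptMeta | None = None,
) -> None:
    """One utterance per line (UTF-8) plus a sidecar ``.meta.json``."""
    p = Path(path)
    p.write_text(
        "\n".join(" ".join(u.tokens) for u in utterances) + "\n", encoding="utf-8"
    )
    if meta is not None:
        sidecar = p.with_suffix(p.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps(
                {
                    "path": meta.path,
                    "corpus_name": meta.corpus_name,
                    "language": meta.language,
                    "child_age_months": meta.child_age_months,
                },
                indent=1,
            ),
            encoding="utf-8",
        )
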