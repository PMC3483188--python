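"""Text cleaning, tokenisation and lexicon resolution.

Raw GP free text is cleaned of computer-generated boilerplate, split into
sentences and classified tokens (words, numbers, UK-format dates, times,
fractions, durations), and each word is resolved against a 'medical'
lexicon (every word of the terminology) and a general British-English
word list.  Out-of-lexicon words are spell-corrected by a single letter
insertion or substitution only — never a deletion — and only when the
correction is unambiguous; anything still unresolved is ignored
downstream.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Optional, Union

__all__ = [
    "TokenKind",
    "LexiconStatus",
    "Token",
    "Lexicons",
    "clean_text",
    "tokenize",
    "resolve_word",
    "resolve_tokens",
    "single_edit_candidates",
]


class TokenKind(str, Enum):
    WORD = "WORD"
    NUMBER = "NUMBER"
    DATE = "DATE"
    TIME = "TIME"
    FRACTION = "FRACTION"
    BP_PAIR = "BP_PAIR"
    DURATION = "DURATION"
    PUNCT = "PUNCT"


class LexiconStatus(str, Enum):
    MEDICAL = "MEDICAL"
    GENERAL = "GENERAL"
    CORRECTED = "CORRECTED"
    UNKNOWN = "UNKNOWN"
    NOT_A_WORD = "NOT_A_WORD"


@dataclass
class Token:
    surface: str
    norm: str
    kind: TokenKind
    sentence_index: int
    token_index: int
    lexicon_status: LexiconStatus = LexiconStatus.NOT_A_WORD
    corrected_from: Optional[str] = None
    value: Any = None  # parsed payload: number, (num, den), date dict, ...

    @property
    def is_word(self) -> bool:
        return self.kind is TokenKind.WORD


@dataclass
class Lexicons:
    """Medical and general word sets used for lookup and spell correction."""

    medical: set[str]
    general: set[str]

    def __post_init__(self) -> None:
        if not self.medical or not self.general:
            raise ValueError("both lexicons must be non-empty")
        self.medical = {w.lower() for w in self.medical}
        self.general = {w.lower() for w in self.general}


def load_general_words(path: Union[str, Path]) -> set[str]:
    with open(path, encoding="utf-8") as handle:
        return {line.strip().lower() for line in handle if line.strip()}


# ---------------------------------------------------------------------------
# cleaning

_WS_RE = re.compile(r"[ \t]+")
_TITLE_DOT_RE = re.compile(r"\b(mr|mrs|ms|dr|miss|prof)\.", re.IGNORECASE)


def clean_text(raw: str, rules: Optional[Iterable[tuple[str, str]]] = None) -> str:
    """Strip masking runs and boilerplate, collapse whitespace.

    *rules* is an iterable of (regex, action) pairs; the only supported
    action is ``remove``.  Clinically meaningful punctuation (/ - : .) is
    preserved.  A full stop after a personal title is dropped so that
    'Mr. Smith' does not split a sentence.
    """
    text = raw.replace("’", "'").replace("‘", "'")
    for pattern, action in rules or []:
        if action == "remove":
            text = re.sub(pattern, " ", text, flags=re.IGNORECASE)
    text = _TITLE_DOT_RE.sub(r"\1", text)
    text = _WS_RE.sub(" ", text)
    return text.strip()


# ---------------------------------------------------------------------------
# tokenisation

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}
_MONTH_ALT = (
    "jan(?:uary)?|feb(?:ruary)?|mar(?:ch)?|apr(?:il)?|may|jun(?:e)?|"
    "jul(?:y)?|aug(?:ust)?|sep(?:t(?:ember)?)?|oct(?:ober)?|nov(?:ember)?|dec(?:ember)?"
)

#: ordered master token patterns; first match at each position wins
_TOKEN_PATTERNS: list[tuple[str, re.Pattern[str]]] = [
    ("date_slash", re.compile(r"\d{1,2}/\d{1,2}/\d{2,4}")),
    ("date_dmy", re.compile(rf"\d{{1,2}}[- ](?:{_MONTH_ALT})[- ]\d{{2,4}}", re.IGNORECASE)),
    ("date_my", re.compile(rf"(?:{_MONTH_ALT})[- ]\d{{4}}", re.IGNORECASE)),
    ("time_hrs", re.compile(r"(\d{3,4})\s*hrs\b", re.IGNORECASE)),
    ("time_colon", re.compile(r"\d{1,2}:\d{2}\b")),
    ("fraction", re.compile(r"\d+/\d+")),
    ("mccd", re.compile(r"1[abc](?![a-z0-9])", re.IGNORECASE)),
    ("number", re.compile(r"\d+(?:\.\s?\d+)?")),
    ("word", re.compile(r"[a-z][a-z0-9]*(?:[/'#-][a-z0-9]+)*|#", re.IGNORECASE)),
]

_DURATION_UNITS = {
    "w": "week", "wk": "week", "wks": "week", "week": "week", "weeks": "week",
    "d": "day", "day": "day", "days": "day",
    "mo": "month", "month": "month", "months": "month",
    "yr": "year", "yrs": "year", "year": "year", "years": "year",
}

_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.;\n])")
_YEAR_RANGE = (1900, 2100)


def _parse_slash_date(text: str) -> Optional[dict[str, int]]:
    day, month, year = (int(p) for p in text.split("/"))
    if year < 100:
        year += 2000 if year < 50 else 1900
    if not (1 <= day <= 31 and 1 <= month <= 12 and _YEAR_RANGE[0] <= year <= _YEAR_RANGE[1]):
        return None
    return {"year": year, "month": month, "day": day}


def _split_sentences(text: str) -> list[str]:
    # protect decimal points before splitting on . ; and newline
    protected = re.sub(r"(?<=\d)\.(?=\d)", "\x00", text)
    parts = _SENTENCE_SPLIT_RE.split(protected)
    return [p.replace("\x00", ".") for p in parts if p.strip()]


def tokenize(cleaned: str) -> list[Token]:
    """Split cleaned text into classified tokens grouped by sentence.

    Sentence boundaries are '.', ';' and newline (decimal points and
    personal-title stops are protected upstream).  Number+unit pairs such
    as '4w' or '1 month' are merged into DURATION tokens.
    """
    tokens: list[Token] = []
    for s_index, sentence in enumerate(_split_sentences(cleaned)):
        sentence_tokens = _tokenize_sentence(sentence, s_index)
        tokens.extend(_merge_durations(sentence_tokens))
    return tokens


def _tokenize_sentence(sentence: str, s_index: int) -> list[Token]:
    tokens: list[Token] = []
    pos = 0
    t_index = 0
    lower = sentence.lower()
    while pos < len(sentence):
        if sentence[pos].isspace():
            pos += 1
            continue
        for name, pattern in _TOKEN_PATTERNS:
            m = pattern.match(lower, pos)
            if m:
                token = _classify(name, sentence[pos:m.end()], m, s_index, t_index)
                if token is not None:
                    tokens.append(token)
                    t_index += 1
                pos = m.end()
                break
        else:
            ch = sentence[pos]
            if ch not in string.whitespace:
                tokens.append(
                    Token(ch, ch, TokenKind.PUNCT, s_index, t_index)
                )
                t_index += 1
            pos += 1
    return tokens


def _classify(
    name: str, surface: str, m: re.Match, s_index: int, t_index: int
) -> Optional[Token]:
    norm = surface.lower()
    if name == "date_slash":
        parsed = _parse_slash_date(norm)
        if parsed is None:  # e.g. 176/100 has no valid calendar reading
            num, den = (int(p) for p in norm.split("/")[:2])
            return Token(surface, norm, TokenKind.FRACTION, s_index, t_index,
                         value=(num, den))
        return Token(surface, norm, TokenKind.DATE, s_index, t_index, value=parsed)
    if name == "date_dmy":
        day, mon, year = re.split(r"[- ]", norm)
        parsed = {"year": _fix_year(int(year)), "month": _month_num(mon), "day": int(day)}
        return Token(surface, norm, TokenKind.DATE, s_index, t_index, value=parsed)
    if name == "date_my":
        mon, year = re.split(r"[- ]", norm)
        parsed = {"year": int(year), "month": _month_num(mon), "day": None}
        return Token(surface, norm, TokenKind.DATE, s_index, t_index, value=parsed)
    if name == "time_hrs":
        digits = m.group(1)
        hh, mm = int(digits[:-2]), int(digits[-2:])
        if hh > 23 or mm > 59:
            return Token(surface, norm, TokenKind.NUMBER, s_index, t_index,
                         value=float(digits))
        return Token(surface, f"{hh:02d}:{mm:02d}", TokenKind.TIME, s_index, t_index,
                     value=f"{hh:02d}:{mm:02d}")
    if name == "time_colon":
        hh, mm = (int(p) for p in norm.split(":"))
        if hh > 23 or mm > 59:
            return Token(surface, norm, TokenKind.PUNCT, s_index, t_index)
        return Token(surface, f"{hh:02d}:{mm:02d}", TokenKind.TIME, s_index, t_index,
                     value=f"{hh:02d}:{mm:02d}")
    if name == "fraction":
        num, den = (int(p) for p in norm.split("/"))
        return Token(surface, norm, TokenKind.FRACTION, s_index, t_index,
                     value=(num, den))
    if name == "mccd":
        return Token(surface, norm, TokenKind.WORD, s_index, t_index)
    if name == "number":
        compact = norm.replace(" ", "")
        value = float(compact)
        if compact.isdigit() and _YEAR_RANGE[0] <= int(compact) <= _YEAR_RANGE[1]:
            return Token(surface, compact, TokenKind.DATE, s_index, t_index,
                         value={"year": int(compact), "month": None, "day": None})
        return Token(surface, compact, TokenKind.NUMBER, s_index, t_index, value=value)
    # word
    norm = norm.replace("'", "")
    if set(norm) == {"#"}:
        return Token(surface, norm, TokenKind.PUNCT, s_index, t_index)
    return Token(surface, norm, TokenKind.WORD, s_index, t_index)


def _month_num(name: str) -> int:
    return _MONTHS[name[:3]]


def _fix_year(year: int) -> int:
    if year < 100:
        return year + (2000 if year < 50 else 1900)
    return year


def _merge_durations(tokens: list[Token]) -> list[Token]:
    merged: list[Token] = []
    skip = False
    for i, tok in enumerate(tokens):
        if skip:
            skip = False
            continue
        nxt = tokens[i + 1] if i + 1 < len(tokens) else None
        number_like = tok.kind is TokenKind.NUMBER or (
            tok.kind is TokenKind.DATE and tok.value and tok.value.get("day") is None
            and tok.value.get("month") is None
        )
        if (
            number_like
            and nxt is not None
            and nxt.kind is TokenKind.WORD
            and nxt.norm in _DURATION_UNITS
        ):
            value = (
                float(tok.norm) if tok.kind is TokenKind.NUMBER else float(tok.value["year"])
            )
            merged.append(
                Token(
                    f"{tok.surface} {nxt.surface}",
                    f"{tok.norm} {nxt.norm}",
                    TokenKind.DURATION,
                    tok.sentence_index,
                    tok.token_index,
                    value=(value, _DURATION_UNITS[nxt.norm]),
                )
            )
            skip = True
        else:
            merged.append(tok)
    return _renumber(merged)


def _renumber(tokens: list[Token]) -> list[Token]:
    for i, tok in enumerate(tokens):
        tok.token_index = i
    return tokens


# ---------------------------------------------------------------------------
# lexicon resolution and spelling correction

_ALPHABET = string.ascii_lowercase


def single_edit_candidates(word: str) -> set[str]:
    """All strings reachable by one letter insertion or substitution.

    Deletions are deliberately excluded: a mis-spelt clinical word is
    assumed to have a letter missing or wrong, never one too many.
    """
    out: set[str] = set()
    for i in range(len(word) + 1):
        for ch in _ALPHABET:
            out.add(word[:i] + ch + word[i:])
    for i in range(len(word)):
        for ch in _ALPHABET:
            if ch != word[i]:
                out.add(word[:i] + ch + word[i + 1:])
    return out


def _correct(word: str, lexicon: set[str]) -> Optional[str]:
    hits = sorted(single_edit_candidates(word) & lexicon)
    if len(hits) == 1:
        return hits[0]
    return None  # ambiguous or no candidate: stay unknown


def resolve_word(token: Token, lex: Lexicons) -> Token:
    """Assign a lexicon status (and correction) to a WORD token."""
    if token.kind is not TokenKind.WORD:
        return token
    norm = token.norm
    if norm in lex.medical:
        token.lexicon_status = LexiconStatus.MEDICAL
    elif norm in lex.general:
        token.lexicon_status = LexiconStatus.GENERAL
    elif not norm.isalpha() or len(norm) < 4:
        # digits/symbols and very short tokens are usually abbreviations,
        # not misspellings: never "correct" them
        token.lexicon_status = LexiconStatus.UNKNOWN
    else:
        corrected = _correct(norm, lex.medical) or _correct(norm, lex.general)
        if corrected is not None:
            token.lexicon_status = LexiconStatus.CORRECTED
            token.corrected_from = norm
            token.norm = corrected
        else:
            token.lexicon_status = LexiconStatus.UNKNOWN
    return token


def resolve_tokens(tokens: list[Token], lex: Lexicons) -> list[Token]:
    for token in tokens:
        resolve_word(token, lex)
    return tokens
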