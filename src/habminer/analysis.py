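"""Shallow linguistic analysis behind a pluggable analyzer contract.

Habitat recognition needs, per sentence, the tokens with their surface form,
lemma, Penn-Treebank POS tag, IOB2 chunk label, and character offsets into the
*original* document.  Any tagger can stand behind the :data:`Analyzer`
contract; the package ships :class:`LexiconAnalyzer`, a deterministic
lexicon-driven analyzer (packaged word list plus suffix heuristics) so the
whole pipeline runs reproducibly with no external models.

Offsets are 0-based, end-exclusive code-point indices; every token surface
must slice the document text exactly, which :func:`analyze` enforces.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Sequence

Span = tuple[int, int]

#: Analyzer contract: document text in, a list of sentences out.  Each
#: sentence is ``(start, end, tokens)`` with tokens as 6-tuples
#: ``(surface, lemma, pos, chunk, start, end)`` in document offsets.
RawToken = tuple[str, str, str, str, int, int]
RawSentence = tuple[int, int, Sequence[RawToken]]
Analyzer = Callable[[str], Sequence[RawSentence]]


class AnalyzerContractError(Exception):
    """An analyzer produced output violating the token/offset contract."""


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: str
    chunk: str  # IOB2 label, e.g. B-NP / I-NP / O
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid token span [{self.start}, {self.end})")


@dataclass(frozen=True)
class AnalyzedSentence:
    """One sentence with its tokens and position within the document."""

    tokens: tuple[Token, ...]
    start: int
    end: int
    text: str
    sentence_index: int
    paragraph_index: int


@dataclass(frozen=True)
class AnalyzedDocument:
    text: str
    sentences: tuple[AnalyzedSentence, ...]
    paragraphs: tuple[Span, ...]

    def token_at(self, offset: int) -> Token | None:
        """The token whose span contains ``offset``, if any."""
        for sentence in self.sentences:
            if sentence.start <= offset < sentence.end:
                for token in sentence.tokens:
                    if token.start <= offset < token.end:
                        return token
        return None

    def token_before(self, offset: int) -> Token | None:
        """The last token ending at or before ``offset``."""
        best: Token | None = None
        for sentence in self.sentences:
            for token in sentence.tokens:
                if token.end <= offset and (best is None or token.end > best.end):
                    best = token
        return best

    def sentence_containing(self, offset: int) -> AnalyzedSentence | None:
        for sentence in self.sentences:
            if sentence.start <= offset < sentence.end:
                return sentence
        return None


@dataclass(frozen=True)
class NounPhrase:
    """A maximal B-NP/I-NP chunk run inside one sentence.

    ``token_start``/``token_stop`` index into the sentence token list
    (stop exclusive)."""

    token_start: int
    token_stop: int
    char_span: Span


# ---------------------------------------------------------------------------
# Paragraph segmentation
# ---------------------------------------------------------------------------

def segment_paragraphs(text: str) -> list[Span]:
    """Split a document into paragraph spans at runs of blank lines.

    A span stretches from the first to the last non-whitespace character of a
    block of consecutive non-blank lines, so the spans partition the non-blank
    content in order.  A leading title line followed by a blank line is
    naturally its own paragraph.
    """
    spans: list[Span] = []
    offset = 0
    block_start: int | None = None
    block_end = 0
    for line in text.splitlines(keepends=True):
        content = line.rstrip("\n").rstrip("\r")
        if content.strip():
            first = offset + (len(content) - len(content.lstrip()))
            last = offset + len(content.rstrip())
            if block_start is None:
                block_start = first
            block_end = last
        else:
            if block_start is not None:
                spans.append((block_start, block_end))
                block_start = None
        offset += len(line)
    if block_start is not None:
        spans.append((block_start, block_end))
    return spans


# ---------------------------------------------------------------------------
# Document assembly over an analyzer
# ---------------------------------------------------------------------------

_VALID_CHUNK = re.compile(r"O|[BI]-[A-Z]+")


def analyze(text: str, analyzer: Analyzer) -> AnalyzedDocument:
    """Run ``analyzer`` over ``text`` and assemble a validated document.

    Enforces the contract: token surfaces round-trip against the original
    text, token spans are ordered and non-overlapping within a sentence, and
    chunk labels form a syntactically valid IOB2 sequence.  Violations raise
    :class:`AnalyzerContractError` naming the offending token.
    """
    paragraphs = tuple(segment_paragraphs(text))
    sentences: list[AnalyzedSentence] = []
    for sent_index, (s_start, s_end, raw_tokens) in enumerate(analyzer(text)):
        tokens: list[Token] = []
        prev_chunk = "O"
        prev_end = s_start
        for surface, lemma, pos, chunk, t_start, t_end in raw_tokens:
            if text[t_start:t_end] != surface:
                raise AnalyzerContractError(
                    f"token {surface!r} at [{t_start}, {t_end}) does not match "
                    f"document text {text[t_start:t_end]!r}"
                )
            if t_start < prev_end:
                raise AnalyzerContractError(
                    f"token {surface!r} at {t_start} overlaps or reorders the "
                    "previous token"
                )
            if not _VALID_CHUNK.fullmatch(chunk):
                raise AnalyzerContractError(
                    f"token {surface!r}: invalid chunk label {chunk!r}"
                )
            if chunk.startswith("I-") and (
                prev_chunk == "O" or prev_chunk[2:] != chunk[2:]
            ):
                raise AnalyzerContractError(
                    f"token {surface!r}: I-{chunk[2:]} cannot follow {prev_chunk}"
                )
            tokens.append(Token(surface, lemma, pos, chunk, t_start, t_end))
            prev_chunk = chunk
            prev_end = t_end
        if tokens and not (s_start <= tokens[0].start and tokens[-1].end <= s_end):
            raise AnalyzerContractError(
                f"sentence [{s_start}, {s_end}) does not contain all its tokens"
            )
        paragraph_index = _paragraph_of(s_start, paragraphs)
        sentences.append(
            AnalyzedSentence(
                tokens=tuple(tokens),
                start=s_start,
                end=s_end,
                text=text[s_start:s_end],
                sentence_index=sent_index,
                paragraph_index=paragraph_index,
            )
        )
    return AnalyzedDocument(text=text, sentences=tuple(sentences), paragraphs=paragraphs)


def _paragraph_of(offset: int, paragraphs: Sequence[Span]) -> int:
    for index, (start, end) in enumerate(paragraphs):
        if start <= offset <= end:
            return index
    # a sentence starting in inter-paragraph whitespace attaches to the next
    for index, (start, _) in enumerate(paragraphs):
        if offset < start:
            return index
    return max(len(paragraphs) - 1, 0)


def extract_noun_phrases(sentence: AnalyzedSentence) -> list[NounPhrase]:
    """One :class:`NounPhrase` per maximal ``B-NP``/``I-NP`` run, in order."""
    phrases: list[NounPhrase] = []
    start: int | None = None
    for index, token in enumerate(sentence.tokens):
        in_np = token.chunk in ("B-NP", "I-NP")
        if in_np and (token.chunk == "B-NP" or start is None):
            if start is not None:
                phrases.append(_make_np(sentence, start, index))
            start = index
        elif not in_np and start is not None:
            phrases.append(_make_np(sentence, start, index))
            start = None
    if start is not None:
        phrases.append(_make_np(sentence, start, len(sentence.tokens)))
    return phrases


def _make_np(sentence: AnalyzedSentence, start: int, stop: int) -> NounPhrase:
    return NounPhrase(
        token_start=start,
        token_stop=stop,
        char_span=(sentence.tokens[start].start, sentence.tokens[stop - 1].end),
    )


# ---------------------------------------------------------------------------
# Deterministic lexicon analyzer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+(?:[-'’]\w+)*|[^\w\s]", re.UNICODE)
_SENT_BREAK_RE = re.compile(r'(?<=[.!?])\s+(?=["(]?[A-Z0-9])')

#: POS tags whose tokens may belong to a noun-phrase chunk.
NP_POS = frozenset(
    {"DT", "PDT", "WDT", "PRP$", "POS", "JJ", "JJR", "JJS",
     "NN", "NNS", "NNP", "NNPS", "CD", "FW"}
)


def load_default_lexicon() -> dict[str, tuple[str, str]]:
    """Load the packaged surface -> (lemma, POS) lexicon (keys lowercased)."""
    lexicon: dict[str, tuple[str, str]] = {}
    data = resources.files("habminer.data").joinpath("lexicon.tsv").read_text("utf-8")
    for line in data.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        surface, lemma, pos = line.split("\t")
        lexicon[surface.lower()] = (lemma, pos)
    return lexicon


class LexiconAnalyzer:
    """Deterministic sentence splitter + tagger driven by a word lexicon.

    Sentences break at newlines and after ``.!?`` followed by whitespace and
    an upper-case/digit character.  Tokens are maximal word characters
    (hyphenated words such as ``iron-rich`` stay single tokens) or isolated
    punctuation.  Unknown words fall back to suffix heuristics: hyphenated ->
    adjective, digits -> number, capitalized -> proper noun, ``-s`` plural,
    ``-ed``/``-ing`` participle, else common noun.  Chunking groups nominal
    POS runs into NPs and keeps the conjunction ``and`` inside an NP when it
    directly joins two nominal runs, which is how within-phrase coordination
    reaches the habitat recognizer.
    """

    def __init__(self, lexicon: Mapping[str, tuple[str, str]] | None = None):
        self._lexicon = dict(lexicon) if lexicon is not None else load_default_lexicon()

    def __call__(self, text: str) -> list[RawSentence]:
        sentences: list[RawSentence] = []
        for p_start, p_end in segment_paragraphs(text):
            for s_start, s_end in self._split_sentences(text, p_start, p_end):
                tokens = self._tag(text, s_start, s_end)
                if tokens:
                    sentences.append((s_start, s_end, tokens))
        return sentences

    # -- sentence segmentation ---------------------------------------------

    def _split_sentences(self, text: str, start: int, end: int) -> list[Span]:
        spans: list[Span] = []
        for line_start, line_end in self._lines(text, start, end):
            piece = text[line_start:line_end]
            cut = line_start
            for match in _SENT_BREAK_RE.finditer(piece):
                spans.append((cut, line_start + match.start()))
                cut = line_start + match.end()
            if cut < line_end:
                spans.append((cut, line_end))
        return [
            (s + len(text[s:e]) - len(text[s:e].lstrip()), s + len(text[s:e].rstrip()))
            for s, e in spans
            if text[s:e].strip()
        ]

    @staticmethod
    def _lines(text: str, start: int, end: int) -> list[Span]:
        spans: list[Span] = []
        cursor = start
        while cursor <= end:
            newline = text.find("\n", cursor, end)
            if newline == -1:
                spans.append((cursor, end))
                break
            spans.append((cursor, newline))
            cursor = newline + 1
        return spans

    # -- tagging and chunking ----------------------------------------------

    def _tag(self, text: str, start: int, end: int) -> list[RawToken]:
        raw: list[tuple[str, str, str, int, int]] = []
        for match in _TOKEN_RE.finditer(text, start, end):
            surface = match.group()
            lemma, pos = self._classify(surface)
            raw.append((surface, lemma, pos, match.start(), match.end()))
        chunks = self._chunk([pos for _, _, pos, _, _ in raw],
                             [s for s, *_ in raw])
        return [
            (surface, lemma, pos, chunk, t_start, t_end)
            for (surface, lemma, pos, t_start, t_end), chunk in zip(raw, chunks)
        ]

    def _classify(self, surface: str) -> tuple[str, str]:
        entry = self._lexicon.get(surface.lower())
        if entry is not None:
            lemma, pos = entry
            if pos in ("NNP", "NNPS"):
                return surface, pos
            return lemma, pos
        lower = surface.lower()
        if not any(ch.isalnum() for ch in surface):
            return surface, "."
        if surface.isdigit():
            return surface, "CD"
        if "-" in surface:
            return lower, "JJ"
        if any(ch.isdigit() for ch in surface):
            return surface, "NNP"
        if surface[0].isupper():
            return surface, "NNP"
        if lower.endswith("ing") and len(lower) > 4:
            return lower[:-3], "VBG"
        if lower.endswith("ed") and len(lower) > 3:
            return lower[:-2], "VBN"
        if lower.endswith("s") and len(lower) > 3 and not lower.endswith("ss"):
            return lower[:-1], "NNS"
        return lower, "NN"

    def _chunk(self, tags: list[str], starts: list[int]) -> list[str]:
        chunks = ["O"] * len(tags)
        in_np = False
        for index, pos in enumerate(tags):
            if pos in NP_POS:
                chunks[index] = "I-NP" if in_np else "B-NP"
                in_np = True
            else:
                chunks[index] = "O"
                in_np = False
        # keep "and" inside one NP when it directly bridges two nominal runs
        for index in range(1, len(tags) - 1):
            if (
                chunks[index] == "O"
                and tags[index] == "CC"
                and chunks[index - 1] in ("B-NP", "I-NP")
                and chunks[index + 1] == "B-NP"
            ):
                chunks[index] = "I-NP"
                chunks[index + 1] = "I-NP"
        return chunks
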