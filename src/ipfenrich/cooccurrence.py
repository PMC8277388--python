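"""Gene co-occurrence mining over PubTator-annotated abstracts.

The PubTator plain format carries, per document, a ``PMID|t|`` title line,
a ``PMID|a|`` abstract line and tab-separated annotation lines
(``pmid  start  end  mention  type  normalized-id``), with documents
separated by blank lines.  Offsets index into the concatenation
``title + " " + abstract``.

Two co-occurrence windows turn a corpus into gene pairs:

* ``ABSTRACT`` — every unordered pair of distinct normalized gene ids
  annotated anywhere in the same document;
* ``SENTENCE`` — pairs restricted to genes whose mentions fall in the same
  sentence, under a deterministic punctuation-based splitter (period,
  question or exclamation mark followed by whitespace and a capital letter
  or digit, with a guard list of common abbreviations).

Sentence pairs are always a subset of abstract pairs.  Repeated mentions
of the same gene add no multiplicity; a document (or sentence) with a
single gene yields nothing.  Stricter syntactic extraction rules can be
plugged in through :func:`read_pair_tsv`.
"""

from __future__ import annotations

import os
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "ABSTRACT",
    "SENTENCE",
    "Annotation",
    "AnnotatedDocument",
    "GenePairSet",
    "parse_pubtator",
    "split_sentences",
    "extract_pairs",
    "filter_documents",
    "write_gene_list",
    "write_pair_tsv",
    "read_pair_tsv",
]

ABSTRACT = "ABSTRACT"
SENTENCE = "SENTENCE"


@dataclass(frozen=True)
class Annotation:
    start: int
    end: int
    text: str
    type: str
    norm_id: str


@dataclass
class AnnotatedDocument:
    """One title+abstract with offset-anchored entity annotations."""

    doc_id: str
    title: str
    abstract: str
    annotations: list[Annotation] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return f"{self.title} {self.abstract}" if self.abstract else self.title

    def gene_annotations(self) -> list[Annotation]:
        return [a for a in self.annotations if a.type.lower() == "gene"]

    def gene_ids(self) -> set[str]:
        return {a.norm_id for a in self.gene_annotations()}

    def sentence_spans(self) -> list[tuple[int, int]]:
        """Title as one sentence, then the abstract's sentences, as offsets
        into :attr:`full_text`."""
        spans = [(0, len(self.title))]
        offset = len(self.title) + 1
        for s, e in split_sentences(self.abstract):
            spans.append((s + offset, e + offset))
        return spans


@dataclass
class GenePairSet:
    """Unordered gene pairs (and their union) mined by one method."""

    method_label: str
    pairs: frozenset[tuple[str, str]]
    support: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for pair in self.pairs for g in pair)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_pubtator(path: str | os.PathLike) -> list[AnnotatedDocument]:
    """Parse a PubTator plain-format file into annotated documents.

    Annotations whose offsets fall outside the text are dropped with a
    warning; a mention/span mismatch is tolerated (warned, kept).  Gene
    annotations without a normalized id are dropped.
    """
    path = Path(path)
    docs: list[AnnotatedDocument] = []
    cur: AnnotatedDocument | None = None

    def flush() -> None:
        nonlocal cur
        if cur is not None:
            docs.append(cur)
            cur = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            m = re.match(r"^([^|\t]+)\|([ta])\|(.*)$", line)
            if m:
                doc_id, kind, text = m.groups()
                if kind == "t":
                    flush()
                    cur = AnnotatedDocument(doc_id=doc_id, title=text, abstract="")
                else:
                    if cur is None or cur.doc_id != doc_id:
                        raise ValueError(
                            f"{path}:{lineno}: abstract line for {doc_id!r} "
                            "without a preceding title line"
                        )
                    cur.abstract = text
                continue
            fields = line.split("\t")
            if cur is None or len(fields) < 5 or fields[0] != cur.doc_id:
                raise ValueError(f"{path}:{lineno}: malformed annotation line")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer annotation offsets"
                ) from None
            mention, ann_type = fields[3], fields[4]
            norm_id = fields[5].strip() if len(fields) > 5 else ""
            text = cur.full_text
            if not (0 <= start < end <= len(text)):
                warnings.warn(
                    f"{path}:{lineno}: annotation offsets [{start}, {end}) outside "
                    f"document {cur.doc_id!r}; dropped",
                    stacklevel=2,
                )
                continue
            if text[start:end] != mention:
                warnings.warn(
                    f"{path}:{lineno}: span text {text[start:end]!r} does not match "
                    f"mention {mention!r}; kept",
                    stacklevel=2,
                )
            if ann_type.lower() == "gene" and (not norm_id or norm_id == "-"):
                warnings.warn(
                    f"{path}:{lineno}: gene annotation without normalized id; dropped",
                    stacklevel=2,
                )
                continue
            cur.annotations.append(Annotation(start, end, mention, ann_type, norm_id))
    flush()
    return docs


# Sentence boundary: terminal punctuation, whitespace, then a capital or
# digit.  Deterministic by construction; the guard list blocks the most
# common scientific abbreviations.
_ABBREV_GUARD = (
    "e.g.", "i.e.", "et al.", "vs.", "cf.", "ca.", "fig.", "figs.",
    "no.", "dr.", "approx.", "resp.", "spp.", "sp.",
)
_BOUNDARY = re.compile(r"[.!?](?=\s+[A-Z0-9(\"'])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Deterministic sentence spans (start, end) over ``text``."""
    if not text.strip():
        return []
    cuts = []
    for m in _BOUNDARY.finditer(text):
        prefix = text[: m.end()].lower()
        if any(prefix.endswith(g) for g in _ABBREV_GUARD):
            continue
        cuts.append(m.end())
    spans = []
    start = 0
    for cut in cuts:
        spans.append((start, cut))
        # skip the inter-sentence whitespace
        start = cut
        while start < len(text) and text[start].isspace():
            start += 1
    if start < len(text):
        spans.append((start, len(text)))
    return spans


# ---------------------------------------------------------------------------
# Pair extraction
# ---------------------------------------------------------------------------

def _pairs_of(ids: set[str]) -> set[tuple[str, str]]:
    ordered = sorted(ids)
    return {
        (ordered[i], ordered[j])
        for i in range(len(ordered))
        for j in range(i + 1, len(ordered))
    }


def extract_pairs(
    docs: Iterable[AnnotatedDocument], method: str = ABSTRACT
) -> GenePairSet:
    """Mine unordered gene-id pairs under the chosen co-occurrence window.

    Support counts the number of documents in which a pair co-occurs
    within its window.
    """
    if method not in (ABSTRACT, SENTENCE):
        raise ValueError(f"method must be {ABSTRACT!r} or {SENTENCE!r}")
    support: Counter[tuple[str, str]] = Counter()
    for doc in docs:
        if method == ABSTRACT:
            doc_pairs = _pairs_of(doc.gene_ids())
        else:
            doc_pairs = set()
            spans = doc.sentence_spans()
            for s, e in spans:
                ids = {
                    a.norm_id
                    for a in doc.gene_annotations()
                    if s <= a.start < e
                }
                doc_pairs |= _pairs_of(ids)
        support.update(doc_pairs)
    return GenePairSet(
        method_label=method,
        pairs=frozenset(support),
        support=dict(support),
    )


def filter_documents(
    docs: Iterable[AnnotatedDocument], synonyms: Iterable[str]
) -> list[AnnotatedDocument]:
    """Keep documents mentioning any synonym (case-insensitive substring)."""
    terms = [s.lower() for s in synonyms if s.strip()]
    if not terms:
        raise ValueError("at least one synonym is required")
    return [
        d for d in docs if any(t in d.full_text.lower() for t in terms)
    ]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def write_pair_tsv(pair_set: GenePairSet, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tsupport\n")
        for a, b in sorted(pair_set.pairs):
            fh.write(f"{a}\t{b}\t{pair_set.support.get((a, b), 1)}\n")


def read_pair_tsv(path: str | os.PathLike, method_label: str) -> GenePairSet:
    """Load externally produced gene pairs (e.g. from a syntactic or event
    extraction system) into the same container."""
    support: dict[tuple[str, str], int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "gene_a\t")):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-pair {a!r}")
            pair = (a, b) if a <= b else (b, a)
            count = int(fields[2]) if len(fields) > 2 and fields[2].strip() else 1
            support[pair] = support.get(pair, 0) + count
    return GenePairSet(
        method_label=method_label, pairs=frozenset(support), support=support
    )
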