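"""Node Identification Strategy (NIS).

Dictionary-based entity recognition over policy-document text, construction
of the directed co-mention network, degree centrality on the binary
connection view, and the four-way connection-type classification.

The edge rule: a document links each of its issuers to every *other* agency
appearing in it (mentioned agencies and fellow issuers alike), one unit of
multiplicity per document and ordered pair.  The orientation is
initiator -> receiver, which is why purely-mentioned agencies accumulate
in-degree only.
"""

from __future__ import annotations

import re
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .config import ClassThresholds
from .corpus_io import AgencyDictionary, CollabNetwork, CorpusError, PolicyDocument

FULL = "full"
WIDE_RANGE = "wide-range"
SMALL_RANGE = "small-range"
SCATTER = "scatter"
CONNECTION_CLASSES = (FULL, WIDE_RANGE, SMALL_RANGE, SCATTER)


class EntityMatch(NamedTuple):
    surface_form: str
    code: str
    position: int


def _compile_pattern(dictionary: AgencyDictionary) -> re.Pattern:
    # longest-first alternation: the regex engine tries alternatives in
    # order, so at any position the longest surface form wins
    forms = sorted(dictionary.lookup, key=len, reverse=True)
    return re.compile("|".join(re.escape(f) for f in forms))


def recognize_entities(text: str, dictionary: AgencyDictionary) -> list[EntityMatch]:
    """Find all non-overlapping agency mentions in ``text``.

    Scanning is left-to-right; at each position the longest matching
    surface form (canonical name or alias) wins, so an alias nested inside
    a longer canonical name is not double-counted.  Returns matches sorted
    by position.
    """
    if not len(dictionary):
        raise CorpusError("entity recognition requires a non-empty dictionary")
    if not text:
        return []
    pattern = _compile_pattern(dictionary)
    return [
        EntityMatch(m.group(0), dictionary.lookup[m.group(0)], m.start())
        for m in pattern.finditer(text)
    ]


def resolve_corpus(
    corpus: Iterable[PolicyDocument], dictionary: AgencyDictionary
) -> list[PolicyDocument]:
    """Fill in mentions for documents that carry raw text only."""
    resolved = []
    for doc in corpus:
        if not doc.mentions and doc.text is not None:
            matches = recognize_entities(doc.text, dictionary)
            doc = PolicyDocument(
                doc_id=doc.doc_id,
                date=doc.date,
                issuers=doc.issuers,
                mentions=tuple((m.surface_form, m.code) for m in matches),
                aspect_counts=doc.aspect_counts,
                text=doc.text,
            )
        resolved.append(doc)
    return resolved


def build_network(
    corpus: Sequence[PolicyDocument], dictionary: AgencyDictionary
) -> CollabNetwork:
    """Build the directed co-mention network from a resolved corpus.

    Every issuer of a document gets one unit of multiplicity towards every
    other agency appearing in that document; within one document each
    ordered pair is counted at most once, and self-loops are excluded.
    Nodes are all dictionary codes, so agencies never observed still appear
    as isolates.
    """
    multiplicity: dict[tuple[str, str], int] = {}
    for doc in corpus:
        bad = sorted(c for c in doc.participants if c not in dictionary)
        if bad:
            raise CorpusError(
                f"document {doc.doc_id!r}: unresolvable agency codes {bad}"
            )
        for issuer in doc.issuers:
            for other in doc.participants:
                if other == issuer:
                    continue
                key = (issuer, other)
                multiplicity[key] = multiplicity.get(key, 0) + 1
    return CollabNetwork(dictionary.codes, multiplicity)


def classify_connection_type(degree: int, thresholds: ClassThresholds | None = None) -> str:
    """Map a degree to its connection type.

    full iff degree >= 20; wide-range iff 10 <= degree < 20; small-range
    iff 5 <= degree < 10; scatter iff degree < 5 (default thresholds).
    """
    t = thresholds or ClassThresholds()
    if degree < 0:
        raise CorpusError(f"degree must be non-negative, got {degree}")
    if degree >= t.full:
        return FULL
    if degree >= t.wide:
        return WIDE_RANGE
    if degree >= t.small:
        return SMALL_RANGE
    return SCATTER


def degree_centrality(
    net: CollabNetwork, thresholds: ClassThresholds | None = None
) -> pd.DataFrame:
    """Per-node out/in degree centrality on the binary connection view.

    out_degree(i) counts distinct j with connection(i, j) = 1; multiplicity
    is ignored.  Returns a DataFrame indexed by code with columns
    out_degree, in_degree, out_class, in_class.
    """
    out = {c: 0 for c in net.nodes}
    inc = {c: 0 for c in net.nodes}
    for i, j in net.multiplicity:
        out[i] += 1
        inc[j] += 1
    df = pd.DataFrame(
        {
            "out_degree": pd.Series(out),
            "in_degree": pd.Series(inc),
        }
    ).loc[list(net.nodes)]
    df["out_class"] = df["out_degree"].map(lambda d: classify_connection_type(d, thresholds))
    df["in_class"] = df["in_degree"].map(lambda d: classify_connection_type(d, thresholds))
    df.index.name = "code"
    return df
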