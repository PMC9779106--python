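"""Synthetic corpora with the statistical shape the analysis assumes.

The generator emulates an issuer-led policy corpus over a fixed agency
roster: a couple of high-activity hub agencies issue a large share of the
documents (a two-tier activity model, the minimal mechanism behind a
two-hub-dominated out-degree distribution with a long scatter tail), every
document co-mentions a handful of agencies across five index aspects, and
a tunable fraction of mentions use an alias instead of the canonical name.

Alongside the corpus a :class:`GroundTruth` records the planted directed
multiplicities and per-aspect mention counts, so every downstream stage can
be checked against what was actually planted.  All randomness flows from a
single seed through one generator stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .corpus_io import (
    GOVERNMENT_DEPARTMENT,
    PUBLIC_ORGANIZATION,
    Agency,
    AgencyDictionary,
    CorpusError,
    MentionMatrix,
    PolicyDocument,
)
from .lass import normalize_mentions

_PREFIXES = ("National", "State", "Central", "General")
_TAGGED = ("Ministry", "Commission", "Administration", "Bureau", "Office")
_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "ne",
    "po", "ra", "su", "te", "vi", "wo", "xa", "yu", "ze", "qi",
)
_FILLER = (
    "the", "relevant", "departments", "shall", "jointly", "promote", "and",
    "coordinate", "implementation", "of", "measures", "to", "strengthen",
    "support", "for", "integrated", "services", "in", "all", "regions",
)
_DEFAULT_ASPECTS = (
    "main-policies",
    "medical-resources",
    "natural-resources",
    "economic-support",
    "personnel-training",
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic corpus.

    Defaults mirror the emulated study corpus: 22 agencies, 484 documents,
    5 index aspects, about 4 mentions per document, roughly a third of
    mentions written as aliases, and 2 hub issuers behind most documents
    while a background agency issues only a few — so the out-degree
    distribution is hub-dominated (hubs connected to essentially everyone)
    with a long scatter tail, as in the emulated corpus.
    """

    n_agencies: int = 22
    n_docs: int = 484
    n_aspects: int = 5
    n_hubs: int = 2
    hub_activity: float = 0.40
    background_activity: float = 0.003
    #: relative sampling weight of a hub when drawing mentioned agencies
    hub_mention_boost: float = 6.0
    mention_rate: float = 4.0
    alias_rate: float = 0.30
    #: optional per-aspect probabilities; None means uniform
    aspect_skew: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agencies < 2:
            raise CorpusError("need at least 2 agencies")
        if self.n_aspects < 2:
            raise CorpusError("need at least 2 aspects")
        if self.n_hubs < 0 or self.n_hubs > self.n_agencies:
            raise CorpusError("n_hubs must lie in [0, n_agencies]")
        for name in ("hub_activity", "background_activity", "alias_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CorpusError(f"{name} must lie in [0, 1], got {v}")
        if self.n_hubs and self.hub_activity <= self.background_activity:
            raise CorpusError("hub activity must strictly exceed the background")
        if self.aspect_skew is not None and len(self.aspect_skew) != self.n_aspects:
            raise CorpusError("aspect_skew length must equal n_aspects")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_agencies))

    @property
    def hub_codes(self) -> tuple[str, ...]:
        return self.codes[: self.n_hubs]

    @property
    def issuer_activity(self) -> dict[str, float]:
        hubs = set(self.hub_codes)
        return {
            c: self.hub_activity if c in hubs else self.background_activity
            for c in self.codes
        }

    @property
    def aspect_labels(self) -> tuple[str, ...]:
        if self.n_aspects == len(_DEFAULT_ASPECTS):
            return _DEFAULT_ASPECTS
        return tuple(f"aspect-{j + 1}" for j in range(self.n_aspects))


@dataclass
class GroundTruth:
    """What the generator actually planted.

    ``multiplicity`` holds the directed co-mention counts m*(i, j) implied
    by the emitted documents; ``aspect_counts`` the raw n x k per-aspect
    mention counts; ``hub_codes`` the planted hub identities.
    """

    multiplicity: dict[tuple[str, str], int] = field(default_factory=dict)
    aspect_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    hub_codes: tuple[str, ...] = ()


def _middle_word(index: int) -> str:
    base = len(_SYLLABLES)
    word = _SYLLABLES[index // base] + _SYLLABLES[index % base] + "n"
    return word.capitalize()


def generate_dictionary(spec: GeneratorSpec) -> AgencyDictionary:
    """Synthesize an agency dictionary.

    Canonical names decompose into (prefix, middle, tagged) parts; each
    agency gets 1-3 aliases — the prefix-less short name (a substring of
    the canonical name, exercising longest-match recognition), an acronym,
    and the upper-cased middle word.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    entries = []
    used_forms: set[str] = set()
    n_public = max(1, round(0.14 * spec.n_agencies)) if spec.n_agencies >= 7 else 0
    for i, code in enumerate(spec.codes):
        prefix = _PREFIXES[int(rng.integers(len(_PREFIXES)))]
        middle = _middle_word(i)
        tagged = _TAGGED[int(rng.integers(len(_TAGGED)))]
        canonical = f"{prefix} {middle} {tagged}"
        acronym = prefix[0] + middle[0] + tagged[0]
        if acronym in used_forms or acronym == canonical:
            acronym = f"{prefix[0]}{middle[:2].upper()}{tagged[0]}"
        if acronym in used_forms:
            acronym = f"{acronym}{i + 1}"
        candidates = [f"{middle} {tagged}", acronym, middle.upper()]
        n_aliases = int(rng.integers(1, 4))
        aliases = frozenset(candidates[:n_aliases])
        used_forms.update(aliases | {canonical})
        category = (
            PUBLIC_ORGANIZATION
            if i >= spec.n_agencies - n_public
            else GOVERNMENT_DEPARTMENT
        )
        entries.append(
            Agency(
                code=code,
                canonical_name=canonical,
                aliases=aliases,
                name_parts=(prefix, middle, tagged),
                category=category,
            )
        )
    return AgencyDictionary(entries)


def _draw_issuers(rng: np.random.Generator, spec: GeneratorSpec) -> frozenset[str]:
    activity = spec.issuer_activity
    codes = spec.codes
    probs = np.array([activity[c] for c in codes])
    mask = rng.random(len(codes)) < probs
    issuers = {c for c, hit in zip(codes, mask) if hit}
    if not issuers:
        weights = probs / probs.sum()
        issuers = {str(rng.choice(np.array(codes), p=weights))}
    return frozenset(issuers)


def generate_corpus(
    spec: GeneratorSpec,
    dictionary: AgencyDictionary,
    config: PipelineConfig | None = None,
) -> tuple[list[PolicyDocument], GroundTruth]:
    """Generate an issuer-led synthetic corpus plus its ground truth.

    Each document draws its issuer set by per-agency activity (at least one
    issuer, re-drawn activity-weighted if the Bernoulli pass comes up
    empty), a Poisson number of mentions with hub-biased agency choice, one
    aspect per mention, and a date uniform in the retrieval window.  Raw
    text interleaves the chosen surface forms with filler words so the
    recognizer can re-derive the mentions.
    """
    if all(v == 0.0 for v in spec.issuer_activity.values()):
        raise CorpusError("all issuer activities are zero; no documents can be issued")
    config = config or PipelineConfig()
    rng = np.random.default_rng(spec.seed)
    codes = spec.codes
    hubs = set(spec.hub_codes)
    mention_weights = np.array(
        [spec.hub_mention_boost if c in hubs else 1.0 for c in codes]
    )
    mention_weights = mention_weights / mention_weights.sum()
    aspect_probs = (
        np.array(spec.aspect_skew, dtype=float) / sum(spec.aspect_skew)
        if spec.aspect_skew is not None
        else np.full(spec.n_aspects, 1.0 / spec.n_aspects)
    )
    window_days = (config.window_end - config.window_start).days
    aspects = spec.aspect_labels
    raw_counts = pd.DataFrame(0, index=list(codes), columns=list(aspects))
    truth = GroundTruth(aspect_counts=raw_counts, hub_codes=spec.hub_codes)
    docs: list[PolicyDocument] = []
    for d in range(spec.n_docs):
        issuers = _draw_issuers(rng, spec)
        n_mentions = int(rng.poisson(spec.mention_rate))
        mention_codes = rng.choice(len(codes), size=n_mentions, p=mention_weights)
        mentions: list[tuple[str, str]] = []
        aspect_counts: dict[str, int] = {}
        tokens: list[str] = []
        for idx in mention_codes:
            code = codes[int(idx)]
            agency = dictionary.by_code[code]
            if agency.aliases and rng.random() < spec.alias_rate:
                alias_pool = sorted(agency.aliases)
                surface = alias_pool[int(rng.integers(len(alias_pool)))]
            else:
                surface = agency.canonical_name
            mentions.append((surface, code))
            aspect = aspects[int(rng.choice(spec.n_aspects, p=aspect_probs))]
            aspect_counts[aspect] = aspect_counts.get(aspect, 0) + 1
            raw_counts.loc[code, aspect] += 1
            tokens.extend(rng.choice(_FILLER, size=int(rng.integers(2, 6))))
            tokens.append(surface)
        tokens.extend(rng.choice(_FILLER, size=3))
        doc = PolicyDocument(
            doc_id=f"doc-{d:04d}",
            date=config.window_start + timedelta(days=int(rng.integers(window_days + 1))),
            issuers=issuers,
            mentions=tuple(mentions),
            aspect_counts=aspect_counts,
            text=" ".join(tokens),
        )
        docs.append(doc)
        for issuer in doc.issuers:
            for other in doc.participants:
                if other != issuer:
                    key = (issuer, other)
                    truth.multiplicity[key] = truth.multiplicity.get(key, 0) + 1
    return docs, truth


def generate_mention_matrix(spec: GeneratorSpec, truth: GroundTruth) -> MentionMatrix:
    """Mention matrix from the planted aspect counts, normalized onto [1, 2]."""
    return normalize_mentions(truth.aspect_counts)


def write_ground_truth(truth: GroundTruth, path) -> None:
    import json

    payload = {
        "multiplicity": {f"{i}->{j}": m for (i, j), m in sorted(truth.multiplicity.items())},
        "aspect_counts": {
            code: {a: int(v) for a, v in row.items()}
            for code, row in truth.aspect_counts.iterrows()
        },
        "hub_codes": list(truth.hub_codes),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
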