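"""Data model and I/O for the inter-agency collaboration pipeline.

Core containers
---------------
``Agency`` / ``AgencyDictionary``
    The gazetteer used for dictionary-based entity recognition: every
    canonical agency name plus its aliases (abbreviations, acronyms,
    colloquial forms) maps to one short code.
``PolicyDocument``
    One corpus record: issuing agencies, resolved mentions, and per-aspect
    mention counts.
``CollabNetwork``
    The directed co-mention network; edges carry a document multiplicity
    and expose a binary connection view.
``MentionMatrix``
    The n-agencies x k-aspects mention-count matrix, together with its
    min-max normalization onto [1.0, 2.0].

Serialization is deliberately plain text: the dictionary is TSV, the corpus
newline-delimited JSON, networks go to edge-list CSV / GEXF / GraphML, and
result tables to CSV.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .config import PipelineConfig

logger = logging.getLogger(__name__)

GOVERNMENT_DEPARTMENT = "government-department"
PUBLIC_ORGANIZATION = "public-organization"
CATEGORIES = (GOVERNMENT_DEPARTMENT, PUBLIC_ORGANIZATION)

_DICT_COLUMNS = ["code", "canonical_name", "aliases", "prefix", "middle", "tagged", "category"]


class CorpusError(ValueError):
    """Raised for malformed dictionaries, corpora, or networks."""


# ---------------------------------------------------------------------------
# agencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Agency:
    """One network node: a government department or public organization.

    ``name_parts`` is the (prefix word, middle word, tagged word)
    decomposition of the canonical name used by the recognizer; the tagged
    word — the institutional head noun such as "Ministry" or "Commission" —
    is the anchor of the decomposition and must be non-empty.
    """

    code: str
    canonical_name: str
    aliases: frozenset[str] = frozenset()
    name_parts: tuple[str, str, str] = ("", "", "")
    category: str = GOVERNMENT_DEPARTMENT

    def __post_init__(self) -> None:
        if not self.code:
            raise CorpusError("agency code must be non-empty")
        if not self.canonical_name:
            raise CorpusError(f"agency {self.code}: canonical name must be non-empty")
        if not self.name_parts[2]:
            raise CorpusError(f"agency {self.code}: tagged word must be non-empty")
        if self.canonical_name in self.aliases:
            raise CorpusError(
                f"agency {self.code}: canonical name {self.canonical_name!r} "
                "may not also be listed as an alias"
            )
        if self.category not in CATEGORIES:
            raise CorpusError(
                f"agency {self.code}: category {self.category!r} not one of {CATEGORIES}"
            )

    @property
    def surface_forms(self) -> frozenset[str]:
        return self.aliases | {self.canonical_name}


class AgencyDictionary:
    """Gazetteer mapping every surface form to an agency code.

    Codes are unique and no surface form may resolve to two codes.
    """

    def __init__(self, entries: Sequence[Agency]):
        self.entries: tuple[Agency, ...] = tuple(entries)
        self.by_code: dict[str, Agency] = {}
        self.lookup: dict[str, str] = {}
        for agency in self.entries:
            if agency.code in self.by_code:
                raise CorpusError(f"duplicate agency code {agency.code!r}")
            self.by_code[agency.code] = agency
        for agency in self.entries:
            for form in sorted(agency.surface_forms):
                other = self.lookup.get(form)
                if other is not None and other != agency.code:
                    raise CorpusError(
                        f"surface form {form!r} maps to both {other!r} and {agency.code!r}"
                    )
                self.lookup[form] = agency.code

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.by_code

    def __eq__(self, other) -> bool:
        return isinstance(other, AgencyDictionary) and self.entries == other.entries

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(a.code for a in self.entries)


def read_agency_dictionary(path: str | Path) -> AgencyDictionary:
    """Read a tab-separated agency dictionary.

    Columns: code, canonical_name, aliases (semicolon-joined), prefix,
    middle, tagged, category.  An empty aliases field means no aliases.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _DICT_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusError(f"dictionary {path}: missing columns {missing}")
    entries = []
    for row in df.itertuples(index=False):
        aliases = frozenset(a for a in str(row.aliases).split(";") if a)
        entries.append(
            Agency(
                code=row.code,
                canonical_name=row.canonical_name,
                aliases=aliases,
                name_parts=(row.prefix, row.middle, row.tagged),
                category=row.category,
            )
        )
    return AgencyDictionary(entries)


def write_agency_dictionary(dictionary: AgencyDictionary, path: str | Path) -> None:
    rows = [
        {
            "code": a.code,
            "canonical_name": a.canonical_name,
            "aliases": ";".join(sorted(a.aliases)),
            "prefix": a.name_parts[0],
            "middle": a.name_parts[1],
            "tagged": a.name_parts[2],
            "category": a.category,
        }
        for a in dictionary
    ]
    pd.DataFrame(rows, columns=_DICT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# documents
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolicyDocument:
    """One policy document: who issued it and which agencies it mentions.

    ``mentions`` keeps (surface_form, code) pairs in document order;
    ``aspect_counts`` attributes each mention to exactly one index aspect.
    ``text`` is optional raw text, carried when mentions still have to be
    resolved by the recognizer.
    """

    doc_id: str
    date: date
    issuers: frozenset[str]
    mentions: tuple[tuple[str, str], ...] = ()
    aspect_counts: Mapping[str, int] = field(default_factory=dict)
    text: str | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("doc_id must be non-empty")
        if not self.issuers:
            raise CorpusError(f"document {self.doc_id}: issuers must be non-empty")
        for aspect, count in self.aspect_counts.items():
            if count < 0:
                raise CorpusError(
                    f"document {self.doc_id}: negative count for aspect {aspect!r}"
                )

    @property
    def mention_codes(self) -> frozenset[str]:
        return frozenset(code for _, code in self.mentions)

    @property
    def participants(self) -> frozenset[str]:
        """All agencies appearing in the document: issuers and mentions."""
        return self.issuers | self.mention_codes


def _doc_to_record(doc: PolicyDocument) -> dict:
    rec = {
        "doc_id": doc.doc_id,
        "date": doc.date.isoformat(),
        "issuers": sorted(doc.issuers),
        "mentions": [list(m) for m in doc.mentions],
        "aspect_counts": dict(doc.aspect_counts),
    }
    if doc.text is not None:
        rec["text"] = doc.text
    return rec


def _record_to_doc(rec: dict, dictionary: AgencyDictionary | None) -> PolicyDocument:
    doc_id = rec.get("doc_id", "")
    if "mentions" not in rec and "text" not in rec:
        raise CorpusError(f"document {doc_id!r}: needs either mentions or raw text")
    issuers = frozenset(rec.get("issuers", []))
    mentions = tuple((m[0], m[1]) for m in rec.get("mentions", []))
    if dictionary is not None:
        unknown = [c for c in issuers if c not in dictionary]
        if unknown:
            raise CorpusError(f"document {doc_id!r}: unknown issuer codes {sorted(unknown)}")
        bad = [c for _, c in mentions if c not in dictionary]
        if bad:
            raise CorpusError(f"document {doc_id!r}: unknown mention codes {sorted(set(bad))}")
    return PolicyDocument(
        doc_id=doc_id,
        date=date.fromisoformat(rec["date"]),
        issuers=issuers,
        mentions=mentions,
        aspect_counts=dict(rec.get("aspect_counts", {})),
        text=rec.get("text"),
    )


def read_corpus(
    path: str | Path,
    dictionary: AgencyDictionary | None = None,
    config: PipelineConfig | None = None,
) -> list[PolicyDocument]:
    """Read a newline-delimited JSON corpus.

    Documents dated outside the configured retrieval window (inclusive on
    both ends) are dropped; the dropped count is logged.  When a dictionary
    is given, issuer and mention codes are validated against it.
    """
    config = config or PipelineConfig()
    docs: list[PolicyDocument] = []
    dropped = 0
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON record") from exc
            doc = _record_to_doc(rec, dictionary)
            if doc.doc_id in seen_ids:
                raise CorpusError(f"duplicate doc_id {doc.doc_id!r}")
            seen_ids.add(doc.doc_id)
            if config.window_start <= doc.date <= config.window_end:
                docs.append(doc)
            else:
                dropped += 1
    if dropped:
        logger.info("read_corpus: dropped %d document(s) outside retrieval window", dropped)
    return docs


def write_corpus(docs: Iterable[PolicyDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(_doc_to_record(doc), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# the collaboration network
# ---------------------------------------------------------------------------


class CollabNetwork:
    """Directed co-mention network with per-pair document multiplicities.

    ``multiplicity[(i, j)]`` is the number of documents creating an i -> j
    connection; the binary view ``connection(i, j)`` is 1 iff that count is
    at least one.  Self-loops are excluded.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        multiplicity: Mapping[tuple[str, str], int],
    ):
        self.nodes: tuple[str, ...] = tuple(nodes)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise CorpusError("network nodes must be unique")
        self.multiplicity: dict[tuple[str, str], int] = {}
        for (i, j), m in multiplicity.items():
            if i == j:
                raise CorpusError(f"self-loop on node {i!r} is not allowed")
            if i not in node_set or j not in node_set:
                raise CorpusError(f"edge ({i!r}, {j!r}) references unknown node")
            if m < 1:
                raise CorpusError(f"edge ({i!r}, {j!r}): multiplicity must be >= 1, got {m}")
            self.multiplicity[(i, j)] = int(m)

    def connection(self, i: str, j: str) -> int:
        """Binary connection indicator: 1 iff at least one document links i -> j."""
        return 1 if (i, j) in self.multiplicity else 0

    def link_count(self, i: str, j: str) -> int:
        """Total document multiplicity between i and j, both directions."""
        return self.multiplicity.get((i, j), 0) + self.multiplicity.get((j, i), 0)

    def neighbors(self, i: str) -> frozenset[str]:
        """Nodes connected to ``i`` in either direction."""
        out = {j for (a, j) in self.multiplicity if a == i}
        inc = {a for (a, j) in self.multiplicity if j == i}
        return frozenset(out | inc)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CollabNetwork)
            and self.nodes == other.nodes
            and self.multiplicity == other.multiplicity
        )

    def to_networkx(self, dictionary: AgencyDictionary | None = None) -> nx.DiGraph:
        g = nx.DiGraph()
        for code in self.nodes:
            attrs = {"code": code}
            if dictionary is not None and code in dictionary:
                agency = dictionary.by_code[code]
                attrs["name"] = agency.canonical_name
                attrs["category"] = agency.category
            g.add_node(code, **attrs)
        for (i, j), m in sorted(self.multiplicity.items()):
            g.add_edge(i, j, multiplicity=m)
        return g

    @classmethod
    def from_edge_list(cls, path: str | Path, nodes: Sequence[str] | None = None) -> "CollabNetwork":
        """Read an edge-list CSV with columns source, target, multiplicity."""
        df = pd.read_csv(path, dtype={"source": str, "target": str})
        mult = {
            (row.source, row.target): int(row.multiplicity)
            for row in df.itertuples(index=False)
        }
        if nodes is None:
            nodes = sorted({n for pair in mult for n in pair})
        return cls(nodes, mult)


EXPORT_FORMATS = ("edge-list-csv", "gexf", "graphml")


def export_network(
    net: CollabNetwork,
    fmt: str,
    path: str | Path,
    dictionary: AgencyDictionary | None = None,
    degree_report: pd.DataFrame | None = None,
) -> None:
    """Write the network as edge-list CSV, GEXF 1.2, or GraphML.

    Graph formats carry node attributes (code, name, category, degrees and
    connection classes when a degree report is supplied) so the file drops
    straight into Gephi or any standard graph tool.
    """
    if fmt not in EXPORT_FORMATS:
        raise CorpusError(f"unknown export format {fmt!r}; choose one of {EXPORT_FORMATS}")
    if not net.multiplicity:
        raise CorpusError("refusing to export a network with no edges")
    if fmt == "edge-list-csv":
        rows = [
            {"source": i, "target": j, "multiplicity": m}
            for (i, j), m in sorted(net.multiplicity.items())
        ]
        pd.DataFrame(rows, columns=["source", "target", "multiplicity"]).to_csv(path, index=False)
        return
    g = net.to_networkx(dictionary)
    if degree_report is not None:
        for code in g.nodes:
            if code in degree_report.index:
                row = degree_report.loc[code]
                g.nodes[code]["out_degree"] = int(row["out_degree"])
                g.nodes[code]["in_degree"] = int(row["in_degree"])
                g.nodes[code]["out_class"] = str(row["out_class"])
                g.nodes[code]["in_class"] = str(row["in_class"])
    if fmt == "gexf":
        nx.write_gexf(g, path, version="1.2draft")
    else:
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# the mention matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MentionMatrix:
    """Per-agency, per-aspect mention counts and their [1, 2] normalization.

    ``raw`` holds non-negative counts (rows: agency codes, columns: aspect
    labels); ``normalized`` holds the min-max mapped values ``data(i, j)``
    with every entry in [1.0, 2.0].
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.raw.values < 0).any():
            raise CorpusError("mention matrix raw counts must be non-negative")
        if not self.raw.index.equals(self.normalized.index) or not self.raw.columns.equals(
            self.normalized.columns
        ):
            raise CorpusError("raw and normalized matrices must share labels")
        vals = self.normalized.values
        if (vals < 1.0 - 1e-12).any() or (vals > 2.0 + 1e-12).any():
            raise CorpusError("normalized mention-matrix entries must lie in [1.0, 2.0]")

    @property
    def agency_codes(self) -> list[str]:
        return list(self.raw.index)

    @property
    def aspect_labels(self) -> list[str]:
        return list(self.raw.columns)


def read_mention_matrix_raw(path: str | Path) -> pd.DataFrame:
    """Read a raw mention-count CSV (first column: agency code)."""
    df = pd.read_csv(path, index_col=0)
    if (df.values < 0).any():
        raise CorpusError(f"{path}: mention counts must be non-negative")
    return df


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------


@dataclass
class ResultsBundle:
    """Everything the three analysis stages produce, ready for reporting."""

    degree_report: pd.DataFrame | None = None
    index_weights: pd.DataFrame | None = None
    node_weights: pd.DataFrame | None = None
    coverage: pd.DataFrame | None = None  # columns: coverage, cse
    effects: pd.DataFrame | None = None  # symmetric percentage matrix
    top_effects: pd.DataFrame | None = None  # columns: rank, pair, effect_pct


def _round_half_up(x: float, ndigits: int) -> float:
    if not math.isfinite(x):
        return x
    scale = 10**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def write_results_tables(results: ResultsBundle, out_dir: str | Path, top_n: int = 10) -> list[Path]:
    """Emit the six result CSVs (degree tables, index weights, node weights,
    coverage/cse, top-N effect pairs).

    Percentages are rounded half-up to 3 decimals, weights to 4; a missing
    stage yields a header-only file so the bundle layout is stable.
    """
    if top_n < 1:
        raise CorpusError(f"top_n must be >= 1, got {top_n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame | None, columns: list[str]) -> None:
        p = out_dir / name
        if df is None or df.empty:
            pd.DataFrame(columns=columns).to_csv(p, index=False)
        else:
            df.to_csv(p, index=False)
        written.append(p)

    dr = results.degree_report
    if dr is not None and not dr.empty:
        out_tbl = dr.reset_index(names="code")[["code", "out_degree", "out_class"]]
        out_tbl = out_tbl.sort_values(["out_degree", "code"], ascending=[False, True])
        in_tbl = dr.reset_index(names="code")[["code", "in_degree", "in_class"]]
        in_tbl = in_tbl.sort_values(["in_degree", "code"], ascending=[False, True])
    else:
        out_tbl = in_tbl = None
    emit("out_degree.csv", out_tbl, ["code", "out_degree", "out_class"])
    emit("in_degree.csv", in_tbl, ["code", "in_degree", "in_class"])

    iw = results.index_weights
    if iw is not None and not iw.empty:
        iw = iw.reset_index(names="aspect").copy()
        for col in ("inf_entropy", "inf_utility", "weight_index"):
            iw[col] = iw[col].map(lambda v: _round_half_up(v, 4))
    emit("index_weights.csv", iw, ["aspect", "inf_entropy", "inf_utility", "weight_index"])

    nw = results.node_weights
    if nw is not None and not nw.empty:
        nw = nw.reset_index(names="code").copy()
        for col in ("dis_plus", "dis_minus", "closeness", "weight_node"):
            nw[col] = nw[col].map(lambda v: _round_half_up(v, 3))
        nw = nw.sort_values(["weight_node", "code"], ascending=[False, True])[
            ["code", "dis_plus", "dis_minus", "closeness", "weight_node"]
        ]
    emit("node_weights.csv", nw, ["code", "dis_plus", "dis_minus", "closeness", "weight_node"])

    cov = results.coverage
    if cov is not None and not cov.empty:
        cov = cov.reset_index(names="code").copy()
        cov["coverage"] = cov["coverage"].map(lambda v: _round_half_up(v, 2))
        cov["cse"] = cov["cse"].map(lambda v: _round_half_up(v, 2))
        cov = cov.sort_values(["coverage", "code"], ascending=[False, True])
        cov.insert(0, "rank", range(1, len(cov) + 1))
    emit("coverage_cse.csv", cov, ["rank", "code", "coverage", "cse"])

    top = results.top_effects
    if top is not None and not top.empty:
        top = top.head(top_n).copy()
        top["effect_pct"] = top["effect_pct"].map(lambda v: _round_half_up(v, 3))
    emit("top_effects.csv", top, ["rank", "pair", "effect_pct"])

    if results.effects is not None and not results.effects.empty:
        p = out_dir / "effect_matrix.csv"
        results.effects.round(3).to_csv(p)
        written.append(p)
    return written
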