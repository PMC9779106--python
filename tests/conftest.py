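from datetime import date

import pytest

from hnicn import fixtures
from hnicn.corpus_io import Agency, AgencyDictionary, CollabNetwork, PolicyDocument


@pytest.fixture(scope="session")
def roster() -> AgencyDictionary:
    """The bundled 22-agency reference roster."""
    return fixtures.agency_dictionary()


@pytest.fixture(scope="session")
def reference_network() -> CollabNetwork:
    """Directed network realizing the published degree sequences."""
    return fixtures.reference_network()


@pytest.fixture(scope="session")
def mini_dict() -> AgencyDictionary:
    """Three agencies with nested surface forms for recognizer tests."""
    return AgencyDictionary(
        [
            Agency(
                code="A1",
                canonical_name="Great Xandu Ministry",
                aliases=frozenset({"Xandu Ministry", "GXM"}),
                name_parts=("Great", "Xandu", "Ministry"),
            ),
            Agency(
                code="A2",
                canonical_name="Central Belor Commission",
                aliases=frozenset({"Belor Commission", "CBC"}),
                name_parts=("Central", "Belor", "Commission"),
            ),
            Agency(
                code="B1",
                canonical_name="Relief Society of Quorn",
                aliases=frozenset({"RSQ"}),
                name_parts=("Relief", "Quorn", "Society"),
                category="public-organization",
            ),
        ]
    )


def make_doc(doc_id, issuers, mention_codes, dictionary=None, when=date(2020, 6, 1)):
    """Document with canonical-name mentions for the given codes."""
    mentions = tuple(
        (dictionary.by_code[c].canonical_name if dictionary else c, c)
        for c in mention_codes
    )
    return PolicyDocument(
        doc_id=doc_id, date=when, issuers=frozenset(issuers), mentions=mentions
    )
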