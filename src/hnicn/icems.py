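"""Information Collaboration Effect Measurement Strategy (ICEMS).

Collaboration structure entropy per node,

    cse_i = coverage_i * log_b(coverage_i),    b > 1 (default 2),

and the psi-damped pairwise collaboration effect: with
M = max over unordered pairs {i, j} of cse_i * cse_j,

    effect(i, j) = M / (M + psi)          if cse_i * cse_j = M
                 = cse_i * cse_j / M      otherwise,

reported as a percentage.  The damping keeps the maximal pair strictly
below 100% for any psi > 0; every other pair is a fraction of the maximal
product, so the whole matrix lies in [0, 100).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd

from .corpus_io import CorpusError


def collaboration_structure_entropy(coverage: float, base: float = 2.0) -> float:
    """cse = coverage * log_base(coverage); zero at the coverage floor 1.0."""
    if coverage <= 0:
        raise CorpusError(f"coverage must be positive, got {coverage}")
    if base <= 1:
        raise CorpusError(f"log base must exceed 1, got {base}")
    return coverage * math.log(coverage, base)


def cse_table(coverage: pd.Series, base: float = 2.0) -> pd.Series:
    """Collaboration structure entropy for a whole coverage table."""
    out = coverage.map(lambda c: collaboration_structure_entropy(c, base))
    out.name = "cse"
    return out


@dataclass(frozen=True)
class EffectMatrix:
    """Symmetric pairwise collaboration-effect percentages.

    ``matrix`` is an n x n DataFrame (diagonal NaN); ``max_pairs`` lists the
    unordered pair(s) attaining the maximal cse product M; ``max_product``
    is M itself.
    """

    matrix: pd.DataFrame
    max_pairs: tuple[tuple[str, str], ...]
    max_product: float
    psi: float


def collaboration_effect_matrix(cse: pd.Series, psi: float = 10_000.0) -> EffectMatrix:
    """Pairwise collaboration effects from a cse table.

    Requires at least two agencies and at least one pair with a positive
    cse product.  If several pairs tie at the maximal product M, the psi
    damping applies to all of them.
    """
    if psi <= 0:
        raise CorpusError(f"psi must be positive, got {psi}")
    codes = list(cse.index)
    if len(codes) < 2:
        raise CorpusError("effect matrix needs at least 2 agencies")
    if (cse < 0).any():
        raise CorpusError("cse values must be non-negative")
    products = {}
    for a_idx, a in enumerate(codes):
        for b in codes[a_idx + 1 :]:
            products[(a, b)] = float(cse[a]) * float(cse[b])
    m = max(products.values())
    if m <= 0:
        raise CorpusError("all cse products are zero; collaboration effect undefined")
    max_pairs = tuple(
        sorted(
            (tuple(sorted(pair, key=_code_key)) for pair, p in products.items() if p == m),
            key=lambda pair: (_code_key(pair[0]), _code_key(pair[1])),
        )
    )
    matrix = pd.DataFrame(float("nan"), index=codes, columns=codes)
    for (a, b), p in products.items():
        pct = 100.0 * (m / (m + psi) if p == m else p / m)
        matrix.loc[a, b] = pct
        matrix.loc[b, a] = pct
    return EffectMatrix(matrix=matrix, max_pairs=max_pairs, max_product=m, psi=psi)


def _code_key(code: str) -> tuple:
    """Natural ordering for agency codes: alpha prefix, then numeric part
    (A2 before A14), falling back to plain string order."""
    m = re.fullmatch(r"([A-Za-z]+)(\d+)", code)
    if m:
        return (m.group(1), int(m.group(2)))
    return (code, -1)


def rank_effects(effects: EffectMatrix, top_n: int = 10) -> pd.DataFrame:
    """Top-N node pairs by collaboration effect.

    Descending by effect; ties break on the natural ordering of the code
    pair, so the ordering is deterministic across runs.  Returns a
    DataFrame with columns rank, pair, effect_pct.
    """
    if top_n < 1:
        raise CorpusError(f"top_n must be >= 1, got {top_n}")
    codes = list(effects.matrix.index)
    rows = []
    for a_idx, a in enumerate(codes):
        for b in codes[a_idx + 1 :]:
            i, j = sorted((a, b), key=_code_key)
            rows.append((float(effects.matrix.loc[a, b]), i, j))
    rows.sort(key=lambda r: (-r[0], _code_key(r[1]), _code_key(r[2])))
    top = rows[:top_n]
    return pd.DataFrame(
        {
            "rank": range(1, len(top) + 1),
            "pair": [f"{i}-{j}" for _, i, j in top],
            "effect_pct": [e for e, _, _ in top],
        }
    )
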