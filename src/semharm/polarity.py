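"""Construct-polarity classification and validation against a reference.

Items are assigned to the construct (e.g. positive vs negative formal
thought disorder) whose description paragraph their embedding is most
cosine-similar to.  The assignment is then compared with an independent
reference classification (such as a published factor-analytic split) via
accuracy and a 2x2 Pearson chi-square association test.

Construct paragraphs are embedded exactly as given — the illustrative
"(e.g., ...)" stripping applies to scale items only, since construct
definitions use those clauses as substantive content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .embedding import EmbeddingBackend, EmbeddingError, embed_texts
from .item_bank import ConstructDescription, ItemBank

__all__ = [
    "PolarityAssignment",
    "PolarityComparison",
    "classify_by_construct",
    "chi2_2x2",
    "compare_to_reference",
]


@dataclass(frozen=True)
class PolarityAssignment:
    """One item's similarity profile over constructs and its argmax label."""

    item_id: str
    similarities: dict[str, float]  # construct_id -> raw cosine, listing order
    assigned: str
    margin: float  # top similarity minus runner-up, >= 0
    tie: bool = False


@dataclass(frozen=True)
class PolarityComparison:
    """Machine-vs-reference agreement summary over a two-construct split."""

    n_items: int
    n_match: int
    accuracy: float
    categories: tuple[str, str]
    contingency: np.ndarray  # rows: machine, cols: reference
    chi2: float
    df: int
    p_value: float


def classify_by_construct(
    bank: ItemBank,
    constructs: Sequence[ConstructDescription],
    backend: EmbeddingBackend,
) -> list[PolarityAssignment]:
    """Assign every bank item to its most-similar construct description.

    Similarities are raw cosines.  Exact ties go to the construct listed
    first and are flagged rather than silently broken.
    """
    ids = [c.construct_id for c in constructs]
    if len(constructs) < 2:
        raise ValueError("need at least 2 construct descriptions")
    if len(set(ids)) != len(ids):
        raise ValueError("construct_ids must be pairwise distinct")
    item_emb = embed_texts([it.clean_text for it in bank], backend,
                           ids=bank.item_ids)
    cons_emb = embed_texts([c.text for c in constructs], backend, ids=ids)

    def unit(m: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise EmbeddingError("zero-norm embedding")
        return m / norms[:, None]

    sims = unit(item_emb.vectors) @ unit(cons_emb.vectors).T  # items x constructs
    out = []
    for i, item_id in enumerate(bank.item_ids):
        row = sims[i]
        best = int(np.argmax(row))  # first max wins on exact ties
        order = np.sort(row)[::-1]
        margin = float(order[0] - order[1])
        out.append(
            PolarityAssignment(
                item_id=item_id,
                similarities={cid: float(s) for cid, s in zip(ids, row)},
                assigned=ids[best],
                margin=margin,
                tie=bool(np.sum(row == row[best]) > 1),
            )
        )
    return out


def chi2_2x2(contingency: np.ndarray,
             continuity_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, 1 degree of freedom.

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; with Yates
    correction ``|ad - bc|`` is shrunk by ``N/2`` (floored at 0) before
    squaring.  Zero row or column margins make the statistic undefined.
    """
    t = np.asarray(contingency, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("contingency must be a nonnegative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty table")
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("zero row or column margin: chi-square undefined")
    det = abs(a * d - b * c)
    if continuity_correction:
        det = max(0.0, det - n / 2.0)
    chi2 = n * det**2 / np.prod(margins)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def compare_to_reference(
    assignments: Sequence[PolarityAssignment],
    reference: Mapping[str, str],
    continuity_correction: bool = False,
) -> PolarityComparison:
    """Accuracy and 2x2 association between machine and reference labels."""
    missing = [a.item_id for a in assignments if a.item_id not in reference]
    if missing:
        raise KeyError(
            f"items missing from reference classification: {', '.join(missing)}"
        )
    cats = tuple(assignments[0].similarities)  # constructs in listing order
    if len(cats) != 2:
        raise ValueError("comparison is defined for exactly 2 constructs")
    unknown = sorted({reference[a.item_id] for a in assignments} - set(cats))
    if unknown:
        raise ValueError(f"reference uses unknown construct(s): {unknown}")
    table = np.zeros((2, 2), dtype=int)
    n_match = 0
    for a in assignments:
        i = cats.index(a.assigned)
        j = cats.index(reference[a.item_id])
        table[i, j] += 1
        n_match += int(i == j)
    n = len(assignments)
    chi2, p = chi2_2x2(table, continuity_correction=continuity_correction)
    return PolarityComparison(
        n_items=n,
        n_match=n_match,
        accuracy=n_match / n,
        categories=cats,
        contingency=table,
        chi2=chi2,
        df=1,
        p_value=p,
    )
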