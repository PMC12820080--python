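"""Multi-rater agreement between expert and machine item groupings.

Fleiss' kappa measures chance-corrected agreement among m raters placing N
items into k nominal categories.  With counts ``n_ij`` (raters placing
item i in category j):

    P_i   = (sum_j n_ij^2 - m) / (m (m - 1))
    Pbar  = mean_i P_i
    p_j   = sum_i n_ij / (N m)
    Pbar_e = sum_j p_j^2
    kappa = (Pbar - Pbar_e) / (1 - Pbar_e)

The per-category decomposition is

    kappa_j = 1 - [sum_i n_ij (m - n_ij)] / [N m (m-1) p_j (1 - p_j)]

Standard errors are the classic large-sample (asymptotic) forms of Fleiss,
Nee & Landis; confidence intervals are kappa +/- z * SE.  The machine
clustering can be folded in as one additional pseudo-rater, which is the
only reading that yields a single pooled Fleiss statistic with per-category
values; the per-item human-vs-machine view is served separately by
:func:`disagreement_ranking`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .backbone import ClusterAssignment

__all__ = [
    "AssignmentMatrix",
    "AgreementResult",
    "build_assignment_matrix",
    "majority_machine_map",
    "fleiss_kappa",
    "category_kappa",
    "disagreement_ranking",
]

MACHINE_RATER_ID = "machine"


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class AssignmentMatrix:
    """Items x categories count table from m raters (machine optionally folded in)."""

    items: tuple[str, ...]
    raters: tuple[str, ...]
    categories: tuple[str, ...]
    counts: np.ndarray  # N x k ints, each row sums to m

    def __post_init__(self) -> None:
        n, k = self.counts.shape
        if n != len(self.items) or k != len(self.categories):
            raise AgreementError("counts shape must be (n_items, n_categories)")
        m = len(self.raters)
        if m < 2:
            raise AgreementError("need at least 2 raters")
        if k < 2:
            raise AgreementError("need at least 2 categories")
        if not np.all(self.counts.sum(axis=1) == m):
            raise AgreementError("every item must be rated by every rater")

    @property
    def n_raters(self) -> int:
        return len(self.raters)


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    scope: str  # "overall" or "category:<name>"


def majority_machine_map(
    expert_table: pd.DataFrame, machine: ClusterAssignment
) -> dict[int, str]:
    """Map each machine cluster onto the expert category its items most
    often receive (majority vote over all expert ratings; ties go to the
    lexicographically smallest category).

    Machine clusters are anonymous integers while experts rate against
    named group descriptions; this recovers the correspondence the same way
    a reader matches described groups to network clusters.
    """
    table = expert_table.astype(str)
    votes: dict[int, dict[str, int]] = {}
    for _, row in table.iterrows():
        item = row["item_id"]
        if item not in machine.labels:
            continue
        c = machine.labels[item]
        votes.setdefault(c, {})
        votes[c][row["category"]] = votes[c].get(row["category"], 0) + 1
    out = {}
    for c in sorted(set(machine.labels.values())):
        if c not in votes:
            raise AgreementError(f"machine cluster {c} has no expert-rated items")
        best = max(votes[c].items(), key=lambda kv: (kv[1], kv[0]))
        # tie -> smallest category name, deterministically
        top = max(votes[c].values())
        out[c] = min(k for k, v in votes[c].items() if v == top)
        del best
    return out


def build_assignment_matrix(
    expert_table: pd.DataFrame,
    machine: ClusterAssignment | None = None,
    categories: Sequence[str] | None = None,
    machine_map: Mapping[int, str] | None = None,
) -> AssignmentMatrix:
    """Tally a long-form expert table (``item_id, rater_id, category``).

    When ``machine`` is given it is appended as one extra rater.  Machine
    cluster labels are matched to expert categories as strings (experts
    rating "1".."4" pair with clusters 1..4); for named expert categories
    supply ``machine_map`` (see :func:`majority_machine_map`).
    """
    required = {"item_id", "rater_id", "category"}
    if not required.issubset(expert_table.columns):
        raise AgreementError(
            f"expert table needs columns {sorted(required)}"
        )
    if expert_table["category"].isna().any():
        bad = expert_table[expert_table["category"].isna()].iloc[0]
        raise AgreementError(
            f"missing rating for item {bad['item_id']!r} by rater {bad['rater_id']!r}"
        )
    items = tuple(dict.fromkeys(expert_table["item_id"].astype(str)))
    raters = tuple(dict.fromkeys(expert_table["rater_id"].astype(str)))
    wide = expert_table.astype({"item_id": str, "rater_id": str, "category": str})
    pivot = wide.pivot(index="item_id", columns="rater_id", values="category")
    pivot = pivot.reindex(index=items, columns=raters)
    if pivot.isna().any().any():
        where = np.argwhere(pivot.isna().to_numpy())[0]
        raise AgreementError(
            f"missing rating for item {items[where[0]]!r} "
            f"by rater {raters[where[1]]!r}"
        )

    labels = pivot.copy()
    rater_list = list(raters)
    if machine is not None:
        missing_items = [i for i in items if i not in machine.labels]
        if missing_items:
            raise AgreementError(
                f"machine clustering lacks item(s): {', '.join(missing_items)}"
            )
        if machine_map is None:
            machine_labels = [str(machine.labels[i]) for i in items]
        else:
            machine_labels = [str(machine_map[machine.labels[i]]) for i in items]
        expert_cats = set(labels.values.ravel().tolist())
        stray = sorted(set(machine_labels) - expert_cats)
        if stray and categories is None:
            raise AgreementError(
                f"machine label(s) {stray} not in the expert category set; "
                "supply machine_map (e.g. majority_machine_map) or categories"
            )
        labels[MACHINE_RATER_ID] = machine_labels
        rater_list.append(MACHINE_RATER_ID)

    if categories is None:
        cats = tuple(sorted(set(labels.values.ravel().tolist())))
    else:
        cats = tuple(str(c) for c in categories)
        unknown = sorted(set(labels.values.ravel()) - set(cats))
        if unknown:
            raise AgreementError(f"unknown category value(s): {unknown}")
    cat_index = {c: j for j, c in enumerate(cats)}
    counts = np.zeros((len(items), len(cats)), dtype=int)
    for i, item in enumerate(items):
        for lab in labels.loc[item]:
            counts[i, cat_index[lab]] += 1
    return AssignmentMatrix(
        items=items, raters=tuple(rater_list), categories=cats, counts=counts
    )


def _marginals(matrix: AssignmentMatrix) -> tuple[int, int, np.ndarray]:
    n, _ = matrix.counts.shape
    m = matrix.n_raters
    p = matrix.counts.sum(axis=0) / (n * m)
    return n, m, p


def fleiss_kappa(matrix: AssignmentMatrix, level: float = 0.95) -> AgreementResult:
    """Overall Fleiss' kappa with asymptotic SE and CI."""
    n, m, p = _marginals(matrix)
    counts = matrix.counts.astype(float)
    p_i = (np.sum(counts**2, axis=1) - m) / (m * (m - 1))
    p_bar = float(np.mean(p_i))
    p_e = float(np.sum(p**2))
    if p_e >= 1.0:
        raise AgreementError("all ratings fall in one category: kappa undefined")
    kappa = (p_bar - p_e) / (1 - p_e)
    q2, q3 = float(np.sum(p**2)), float(np.sum(p**3))
    var = (2.0 / (n * m * (m - 1))) * (
        (q2 - (2 * m - 3) * q2**2 + 2 * (m - 2) * q3) / (1 - q2) ** 2
    )
    se = float(np.sqrt(var))
    z = float(stats.norm.ppf(0.5 + level / 2))
    return AgreementResult(
        kappa=float(kappa), se=se,
        ci_low=float(kappa - z * se), ci_high=float(kappa + z * se),
        level=level, scope="overall",
    )


def category_kappa(matrix: AssignmentMatrix, category: str,
                   level: float = 0.95) -> AgreementResult:
    """Per-category kappa: agreement specifically about membership in one group."""
    if category not in matrix.categories:
        raise AgreementError(f"unknown category {category!r}")
    j = matrix.categories.index(category)
    n, m, p = _marginals(matrix)
    pj = float(p[j])
    if pj <= 0.0 or pj >= 1.0:
        raise AgreementError(
            f"category {category!r} used never or always: kappa undefined"
        )
    nj = matrix.counts[:, j].astype(float)
    kappa = 1.0 - float(np.sum(nj * (m - nj))) / (n * m * (m - 1) * pj * (1 - pj))
    se = float(np.sqrt(2.0 / (n * m * (m - 1))))
    z = float(stats.norm.ppf(0.5 + level / 2))
    return AgreementResult(
        kappa=kappa, se=se,
        ci_low=kappa - z * se, ci_high=kappa + z * se,
        level=level, scope=f"category:{category}",
    )


def disagreement_ranking(
    matrix: AssignmentMatrix, machine: ClusterAssignment,
    machine_map: Mapping[int, str] | None = None,
) -> list[tuple[str, float]]:
    """Items ordered by the share of raters agreeing with the machine label.

    Pass the experts-only matrix (machine *not* folded in), so the fraction
    measures human concordance with the machine assignment.  Ties sort by
    item_id.  Best-agreed items come first.
    """
    missing = [i for i in matrix.items if i not in machine.labels]
    if missing:
        raise AgreementError(f"machine clustering lacks item(s): {', '.join(missing)}")
    m = matrix.n_raters
    fractions = []
    for i, item in enumerate(matrix.items):
        raw = machine.labels[item]
        lab = str(machine_map[raw]) if machine_map is not None else str(raw)
        if lab in matrix.categories:
            j = matrix.categories.index(lab)
            frac = matrix.counts[i, j] / m
        else:
            frac = 0.0
        fractions.append((item, float(frac)))
    return sorted(fractions, key=lambda t: (-t[1], t[0]))
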