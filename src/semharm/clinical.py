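"""Clinical alignment: cross-scale correlation pairing and co-cluster test.

Given participant ratings on two instruments (a backbone scale and a
partner scale), each backbone item is paired with the partner item it
correlates most strongly with across participants.  The exact one-sided
binomial test then asks whether those data-driven pairs land in the same
semantic cluster more often than a stated chance level.

The "strongest correlate" is the *signed* maximum, not the absolute one:
the pairing is meant to capture phenomena that co-occur, and an
absolute-value rule would pair clinical opposites.  A flag switches this.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .backbone import ClusterAssignment

__all__ = [
    "RatingsMatrix",
    "CorrelationPair",
    "AlignmentResult",
    "load_ratings_csv",
    "save_ratings_csv",
    "exclude_degenerate_items",
    "top_correlate_pairing",
    "cocluster_test",
    "exact_binomial_upper_tail",
    "chance_level",
]


class ClinicalError(ValueError):
    pass


@dataclass(frozen=True)
class RatingsMatrix:
    """Participants x items ordinal scores for one scale.

    ``scores`` is indexed by participant id with item_id columns; entries
    are nonnegative integers with no missing cells (resolve missingness
    upstream).  ``groups`` optionally tags each participant patient/control;
    demographics are pass-through metadata and never affect correlations.
    """

    scale_id: str
    scores: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scores.isna().any().any():
            raise ClinicalError(f"{self.scale_id}: ratings contain missing cells")
        vals = self.scores.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ClinicalError(f"{self.scale_id}: scores must be integers")
        if (vals < 0).any():
            raise ClinicalError(f"{self.scale_id}: scores must be nonnegative")

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(self.scores.index.astype(str))

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.scores.columns.astype(str))


@dataclass(frozen=True)
class CorrelationPair:
    backbone_item: str
    partner_item: str
    correlation: float
    tie: bool = False


@dataclass(frozen=True)
class AlignmentResult:
    pairs: tuple[CorrelationPair, ...]
    n_pairs: int
    n_cocluster: int
    chance_level: float
    p_value: float

    @property
    def cocluster_proportion(self) -> float:
        return self.n_cocluster / self.n_pairs if self.n_pairs else float("nan")


def load_ratings_csv(path, scale_id: str) -> RatingsMatrix:
    """Read ``participant_id,group,<item columns...>`` ratings for one scale."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise ClinicalError(f"{path}: missing participant_id column")
    df = df.set_index("participant_id")
    groups = None
    if "group" in df.columns:
        groups = df.pop("group")
    return RatingsMatrix(scale_id=scale_id, scores=df.astype(int), groups=groups)


def save_ratings_csv(ratings: RatingsMatrix, path) -> None:
    df = ratings.scores.copy()
    if ratings.groups is not None:
        df.insert(0, "group", ratings.groups)
    df.index.name = "participant_id"
    df.to_csv(path)


def exclude_degenerate_items(
    ratings: RatingsMatrix,
) -> tuple[RatingsMatrix, list[str], list[str]]:
    """Drop items no correlation can be computed for.

    Returns ``(filtered, all_zero_items, constant_nonzero_items)``: columns
    where no participant scored above zero, and separately columns that are
    constant at a nonzero value (zero variance, correlation undefined).
    """
    scores = ratings.scores
    all_zero = [c for c in scores.columns if (scores[c] == 0).all()]
    constant = [
        c for c in scores.columns
        if c not in all_zero and scores[c].nunique() == 1
    ]
    keep = [c for c in scores.columns if c not in all_zero and c not in constant]
    if not keep:
        raise ClinicalError(f"{ratings.scale_id}: all items are degenerate")
    return (
        RatingsMatrix(ratings.scale_id, scores[keep], ratings.groups),
        all_zero,
        constant,
    )


def top_correlate_pairing(
    backbone: RatingsMatrix,
    partner: RatingsMatrix,
    method: str = "pearson",
    signed: bool = True,
) -> list[CorrelationPair]:
    """For each backbone item, the partner item with maximal correlation.

    Both matrices must carry the same participants in the same order and
    should already be filtered of degenerate items.  ``signed=False``
    switches to maximal absolute correlation.  Ties resolve to the earliest
    partner column and are flagged.
    """
    if backbone.participants != partner.participants:
        raise ClinicalError(
            f"participant mismatch between {backbone.scale_id} and {partner.scale_id}"
        )
    if method not in ("pearson", "spearman"):
        raise ClinicalError(f"unknown correlation method {method!r}")
    b = backbone.scores.to_numpy(dtype=float)
    p = partner.scores.to_numpy(dtype=float)
    if method == "spearman":
        b = np.apply_along_axis(stats.rankdata, 0, b)
        p = np.apply_along_axis(stats.rankdata, 0, p)
    for mat, rm in ((b, backbone), (p, partner)):
        flat = np.flatnonzero(mat.std(axis=0) == 0)
        if flat.size:
            raise ClinicalError(
                f"{rm.scale_id}: zero-variance item {rm.items[flat[0]]!r}; "
                "run exclude_degenerate_items first"
            )
    bz = (b - b.mean(axis=0)) / b.std(axis=0)
    pz = (p - p.mean(axis=0)) / p.std(axis=0)
    corr = bz.T @ pz / b.shape[0]  # backbone items x partner items
    key = corr if signed else np.abs(corr)
    pairs = []
    for i, b_item in enumerate(backbone.items):
        j = int(np.argmax(key[i]))
        tie = bool(np.sum(key[i] == key[i, j]) > 1)
        pairs.append(
            CorrelationPair(b_item, partner.items[j], float(corr[i, j]), tie)
        )
    return pairs


def exact_binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), one-sided upper tail.

    Exact rational arithmetic for n <= 64 (then rounded once to float);
    stable log-space summation via the regularized survival function
    otherwise.
    """
    if not (0 <= k <= n):
        raise ClinicalError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < p0 < 1):
        raise ClinicalError(f"need 0 < p0 < 1, got {p0}")
    if k == 0:
        return 1.0
    if n <= 64:
        q = Fraction(p0).limit_denominator(10**9)
        total = sum(
            comb(n, j) * q**j * (1 - q) ** (n - j) for j in range(k, n + 1)
        )
        return float(total)
    return float(stats.binom.sf(k - 1, n, p0))


def chance_level(clusters: ClusterAssignment, rule: str = "flat") -> float:
    """Null probability that a random pair co-clusters.

    ``flat``: 1 / n_clusters (equal-probability clusters, the conventional
    choice).  ``size_weighted``: sum of squared cluster-share, which
    accounts for unequal cluster sizes.
    """
    if rule == "flat":
        return 1.0 / clusters.n_clusters
    if rule == "size_weighted":
        sizes = np.array(list(clusters.sizes().values()), dtype=float)
        shares = sizes / sizes.sum()
        return float(np.sum(shares**2))
    raise ClinicalError(f"unknown chance rule {rule!r}")


def cocluster_test(
    pairs: Sequence[CorrelationPair],
    clusters: ClusterAssignment,
    chance: float,
) -> AlignmentResult:
    """Exact binomial test of co-clustering among correlation pairs."""
    if not (0 < chance < 1):
        raise ClinicalError(f"chance level must be in (0, 1), got {chance}")
    missing = sorted(
        {
            i
            for p in pairs
            for i in (p.backbone_item, p.partner_item)
            if i not in clusters.labels
        }
    )
    if missing:
        raise ClinicalError(f"item(s) missing from clustering: {', '.join(missing)}")
    n_co = sum(
        1
        for p in pairs
        if clusters.labels[p.backbone_item] == clusters.labels[p.partner_item]
    )
    p_value = exact_binomial_upper_tail(n_co, len(pairs), chance)
    return AlignmentResult(
        pairs=tuple(pairs),
        n_pairs=len(pairs),
        n_cocluster=n_co,
        chance_level=chance,
        p_value=p_value,
    )
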