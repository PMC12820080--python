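"""Synthetic study data with known ground truth.

Real psychopathology scale texts are copyrighted and real expert/participant
data are unpublished, so every pipeline stage is exercised against generated
stand-ins whose true structure is known:

* **Item banks** — each item's description mixes tokens from its theme's
  core vocabulary (pairwise disjoint across themes) with shared filler
  tokens.  The mixing weight ``w`` controls between-theme separation
  monotonically: at ``w = 1`` themes share no content words, at ``w = 0``
  the theme is unrecoverable.
* **Expert assignments** — each rater labels each item with its true theme
  with probability ``a`` (fidelity), otherwise uniformly over all k
  categories (including the truth, so the effective correct probability is
  ``a + (1 - a)/k``).
* **Participant ratings** — a per-participant latent severity per theme
  drives all items of that theme: ``raw = lambda * s_theme + sigma * eps``,
  discretized to 0..4 at equal-probability cut points of the marginal
  latent distribution, then zero-inflated per group (controls more often
  zero, so patients score higher on average).

Identical config + seed reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import RatingsMatrix, save_ratings_csv
from .item_bank import ItemBank, ScaleItem, save_item_bank

__all__ = [
    "ThemeSpec",
    "GeneratorConfig",
    "default_themes",
    "generate_item_bank",
    "generate_expert_assignments",
    "generate_participant_ratings",
    "write_dataset",
]

# Four default themes mirroring the kind of semantic groups cross-scale
# thought-disorder items form: muddled/incomprehensible speech, abrupt topic
# shifts, disorganized narrative logic, and restricted/impoverished speech.
_THEME_WORDS: dict[str, list[str]] = {
    "muddled_communication": [
        "incoherent", "garbled", "jumbled", "unintelligible", "distorted",
        "neologism", "paraphasia", "substitution", "incomprehensible",
        "nonsense", "syllable", "mixture", "muddled", "invented", "approximate",
        "scrambled", "confusion", "cryptic", "opaque", "misused",
    ],
    "topic_shifts": [
        "derailment", "shift", "abrupt", "distractible", "interruption",
        "perseveration", "repetition", "pressured", "racing", "blocking",
        "switching", "intrusion", "clang", "rhyming", "stimulus",
        "tangent", "jump", "interference", "rush", "echo",
    ],
    "disjointed_narrative": [
        "illogical", "unfounded", "conclusion", "irrelevant", "reply",
        "disjointed", "loose", "association", "goal", "wandering",
        "reasoning", "idiosyncratic", "continuity", "fragmented", "unconnected",
        "drifting", "sidetracked", "inference", "leap", "unrelated",
    ],
    "restricted_speech": [
        "poverty", "restricted", "brief", "concrete", "terse",
        "impoverished", "sparse", "monosyllabic", "laconic", "empty",
        "vague", "uninformative", "minimal", "curt", "slowed",
        "latency", "reduced", "hesitant", "stilted", "meager",
    ],
}

_FILLER_WORDS: list[str] = [
    "speech", "the", "patient", "response", "often", "with", "and", "of",
    "a", "during", "interview", "examiner", "answers", "shows", "marked",
    "degree", "observed", "present", "when", "questions", "rated", "talk",
    "to", "in", "may", "be", "form", "thought", "language", "flow",
]


@dataclass(frozen=True)
class ThemeSpec:
    """One latent theme: a disjoint core vocabulary plus shared filler."""

    theme_id: str
    core_vocabulary: tuple[str, ...]
    filler_vocabulary: tuple[str, ...]
    mixing_weight: float = 0.8  # share of core tokens per item text

    def __post_init__(self) -> None:
        if not self.core_vocabulary or not self.filler_vocabulary:
            raise ValueError(f"theme {self.theme_id!r}: empty vocabulary")
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing_weight must be in [0, 1]")


def default_themes(w: float = 0.8, n_themes: int = 4) -> tuple[ThemeSpec, ...]:
    names = list(_THEME_WORDS)
    if not 1 <= n_themes <= len(names):
        raise ValueError(f"n_themes must be in 1..{len(names)}")
    themes = tuple(
        ThemeSpec(
            theme_id=name,
            core_vocabulary=tuple(_THEME_WORDS[name]),
            filler_vocabulary=tuple(_FILLER_WORDS),
            mixing_weight=w,
        )
        for name in names[:n_themes]
    )
    # core vocabularies must be pairwise disjoint (and disjoint from filler)
    seen: set[str] = set(_FILLER_WORDS)
    for t in themes:
        overlap = seen & set(t.core_vocabulary)
        if overlap:
            raise ValueError(f"vocabulary overlap: {sorted(overlap)}")
        seen |= set(t.core_vocabulary)
    return themes


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped defaults: 4 themes across 7 scales (~100 items, with the
    backbone scale and the clinical partner scale sized like their real
    counterparts), 6 expert raters, ordinal 0-4 ratings with group-dependent
    zero inflation (controls more often zero)."""

    n_themes: int = 4
    # (scale_id, items per theme)
    scales: tuple[tuple[str, int], ...] = (
        ("TLC", 5), ("TALD", 7), ("CLANG", 4), ("SAPS", 3),
        ("PANSS", 1), ("TLI", 2), ("BIT", 3),
    )
    mixing_weight: float = 0.8
    text_length: int = 30  # fallback tokens per item description
    # per-scale description lengths mirroring how unevenly real instruments
    # document their items (two verbose scales, one terse, rest mid-range)
    text_lengths: Mapping[str, int] = field(
        default_factory=lambda: {
            "TLC": 95, "SAPS": 90, "PANSS": 40, "TALD": 30,
            "BIT": 25, "TLI": 20, "CLANG": 14,
        }
    )
    expert_fidelity: float = 0.9
    n_raters: int = 6
    latent_loading: float = 0.8
    noise_sd: float = 0.5
    n_levels: int = 5  # ordinal scores 0 .. n_levels-1
    zero_inflation: Mapping[str, float] = field(
        default_factory=lambda: {"patient": 0.1, "control": 0.3}
    )
    n_participants: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for key, p in self.zero_inflation.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"zero_inflation[{key!r}] must be in [0, 1]")
        if not 0.0 <= self.expert_fidelity <= 1.0:
            raise ValueError("expert_fidelity must be in [0, 1]")
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing_weight must be in [0, 1]")

    def themes(self) -> tuple[ThemeSpec, ...]:
        return default_themes(self.mixing_weight, self.n_themes)


def generate_item_bank(
    config: GeneratorConfig,
) -> tuple[ItemBank, dict[str, str]]:
    """Build a themed synthetic bank and its ground-truth theme partition.

    Each item draws ``ceil(w * L)`` tokens from its theme's core vocabulary
    and the rest from the shared filler pool, where L is the scale's entry
    in ``text_lengths`` (fallback ``text_length``); fully determined by the
    config seed.
    """
    themes = config.themes()
    rng = np.random.default_rng(config.seed)
    items: list[ScaleItem] = []
    truth: dict[str, str] = {}
    for scale_id, per_theme in config.scales:
        L = config.text_lengths.get(scale_id, config.text_length)
        n_core = int(np.ceil(config.mixing_weight * L))
        index = 0
        for theme in themes:
            for _ in range(per_theme):
                index += 1
                core = rng.choice(theme.core_vocabulary, size=n_core, replace=True)
                fill = rng.choice(theme.filler_vocabulary, size=L - n_core,
                                  replace=True)
                tokens = np.concatenate([core, fill])
                rng.shuffle(tokens)
                item = ScaleItem(
                    scale_id=scale_id,
                    item_index=str(index),
                    label=f"synthetic {theme.theme_id} symptom {index}",
                    description=" ".join(tokens.tolist()),
                )
                items.append(item)
                truth[item.item_id] = theme.theme_id
    bank = ItemBank(tuple(items))
    return bank, truth


def generate_expert_assignments(
    truth: Mapping[str, str],
    fidelity: float,
    n_raters: int,
    categories: Sequence[str],
    seed: int,
) -> pd.DataFrame:
    """Long-form expert table: correct with probability ``fidelity``, else
    uniform over all categories (truth included)."""
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must be in [0, 1]")
    cats = list(categories)
    rng = np.random.default_rng(seed)
    rows = []
    for rater in range(1, n_raters + 1):
        rater_id = f"R{rater}"
        for item_id, true_cat in truth.items():
            if rng.random() < fidelity:
                cat = true_cat
            else:
                cat = cats[rng.integers(len(cats))]
            rows.append({"item_id": item_id, "rater_id": rater_id, "category": cat})
    return pd.DataFrame(rows, columns=["item_id", "rater_id", "category"])


def _ordinal_thresholds(config: GeneratorConfig) -> np.ndarray:
    # equal-probability cut points of the marginal latent N(0, lam^2 + sig^2)
    marginal_sd = np.hypot(config.latent_loading, config.noise_sd)
    qs = np.arange(1, config.n_levels) / config.n_levels
    return stats.norm.ppf(qs) * marginal_sd


def generate_participant_ratings(
    bank: ItemBank,
    truth: Mapping[str, str],
    config: GeneratorConfig,
    scale_ids: Sequence[str] = ("TLC", "CLANG"),
    plant_all_zero: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, RatingsMatrix]:
    """Simulate ordinal ratings for the requested scales from shared latents.

    All items of one theme load on the same per-participant severity factor,
    so same-theme items correlate across scales — the structure the
    correlation-pairing analysis is meant to recover.  ``plant_all_zero``
    maps scale_id to item_ids forced to all-zero columns (for testing the
    degenerate-item filter).
    """
    themes = [t.theme_id for t in config.themes()]
    theme_pos = {t: i for i, t in enumerate(themes)}
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from bank text
    n = config.n_participants
    n_patients = n // 2
    groups = ["patient"] * n_patients + ["control"] * (n - n_patients)
    participants = [f"P{i + 1:03d}" for i in range(n)]
    severities = rng.standard_normal((n, len(themes)))
    thresholds = _ordinal_thresholds(config)
    plant_all_zero = plant_all_zero or {}

    out: dict[str, RatingsMatrix] = {}
    for scale_id in scale_ids:
        sub = bank.subset([scale_id])
        if len(sub) == 0:
            raise ValueError(f"scale {scale_id!r} has no items in the bank")
        cols = sub.item_ids
        theme_idx = np.array([theme_pos[truth[i]] for i in cols])
        raw = (
            config.latent_loading * severities[:, theme_idx]
            + config.noise_sd * rng.standard_normal((n, len(cols)))
        )
        scores = np.digitize(raw, thresholds)
        # zero-inflation post-discretization, per participant group
        pi0 = np.array([config.zero_inflation.get(g, 0.0) for g in groups])
        mask = rng.random((n, len(cols))) < pi0[:, None]
        scores = np.where(mask, 0, scores)
        df = pd.DataFrame(scores, index=pd.Index(participants, name="participant_id"),
                          columns=list(cols), dtype=int)
        for item_id in plant_all_zero.get(scale_id, ()):
            if item_id not in df.columns:
                raise ValueError(f"cannot plant zeros: {item_id!r} not in {scale_id}")
            df[item_id] = 0
        out[scale_id] = RatingsMatrix(
            scale_id=scale_id,
            scores=df,
            groups=pd.Series(groups, index=df.index, name="group"),
        )
    return out


def write_dataset(config: GeneratorConfig, out_dir: str | Path,
                  ratings_scales: Sequence[str] = ("TLC", "CLANG")) -> dict[str, Path]:
    """Emit a full synthetic dataset in the CSV dialects the pipeline reads.

    Writes the item bank, ground-truth themes, expert assignments and one
    ratings CSV per requested scale; returns the path of each artifact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bank, truth = generate_item_bank(config)
    themes = [t.theme_id for t in config.themes()]
    paths: dict[str, Path] = {}

    paths["item_bank"] = out_dir / "item_bank.csv"
    save_item_bank(bank, paths["item_bank"])

    paths["truth"] = out_dir / "theme_truth.csv"
    pd.DataFrame(
        {"item_id": list(truth), "theme": list(truth.values())}
    ).to_csv(paths["truth"], index=False)

    experts = generate_expert_assignments(
        truth, config.expert_fidelity, config.n_raters, themes, config.seed + 2
    )
    paths["experts"] = out_dir / "expert_assignments.csv"
    experts.to_csv(paths["experts"], index=False)

    ratings = generate_participant_ratings(bank, truth, config, ratings_scales)
    for scale_id, rm in ratings.items():
        p = out_dir / f"ratings_{scale_id}.csv"
        save_ratings_csv(rm, p)
        paths[f"ratings_{scale_id}"] = p
    return paths
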