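"""Coding Interactive Behavior (CIB) record validation and composites.

The CIB is a clinician-rated global interaction scale of 43 item codes on
a 1-5 Likert scale, aggregated by arithmetic mean into eight composite
subscores.  Items may contribute to several composites.  No reverse
scoring is applied (the published composite listing states none).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import OutOfRange, SchemaMismatch

__all__ = [
    "CIB_ITEMS",
    "COMPOSITES",
    "CibRecord",
    "CibComposites",
    "validate_record",
    "composite_scores",
    "composite_profile_plot",
]

COMPOSITES: dict[str, tuple[str, ...]] = {
    "parental_sensitivity": (
        "acknowledging", "imitating", "elaborating", "parent_gaze",
        "parent_positive_affect", "vocal_appropriateness_clarity",
        "appropriate_range_of_affect", "resourcefulness", "praising",
        "affectionate_touch", "supportive_presence", "infant_led_interaction",
    ),
    "parent_intrusiveness": (
        "forcing_physical_manipulation", "overriding_intrusiveness",
        "parent_negative_affect_anger", "parent_anxiety", "criticizing",
        "parent_led_interaction",
    ),
    "parent_limit_setting": (
        "consistency_of_style", "resourcefulness",
        "appropriate_structure_limit_setting",
    ),
    "child_compliance": (
        "compliance_to_parent", "reliance_on_parent_for_help",
        "on_task_persistence",
    ),
    "child_withdrawal": (
        "child_negative_emotionality_fussy", "withdrawal", "labile_affect",
        "avoidance_of_parent",
    ),
    "child_engagement": (
        "joint_attention", "child_positive_affect", "affection_to_parent",
        "alertness", "fatigue", "vocalizations_verbal_output", "initiation",
        "competent_use_of_environment", "creative_symbolic_play",
        "infant_led_interaction",
    ),
    "dyadic_joint_negative_state": (
        "parent_negative_affect_anger", "hostility",
        "child_negative_emotionality_fussy", "withdrawal", "labile_affect",
        "fatigue", "constriction", "tension",
    ),
    "dyadic_reciprocity": (
        "parent_gaze", "parent_positive_affect", "praising",
        "affectionate_touch", "joint_attention", "child_positive_affect",
        "vocalizations_verbal_output", "initiation", "dyadic_reciprocity",
        "adaptation_regulation", "fluency",
    ),
}

# The composite listing above covers 42 distinct items; the published
# instrument has 43 codes.  `child_gaze` completes the schema and
# contributes to no composite.
_EXTRA_ITEMS = ("child_gaze",)

CIB_ITEMS: tuple[str, ...] = tuple(
    sorted(set(i for items in COMPOSITES.values() for i in items) | set(_EXTRA_ITEMS))
)

MISSING_LIMIT = 0.5  # composite undefined when > 50% of its items are missing


@dataclass(frozen=True)
class CibRecord:
    """Validated 43-item record; missing items are None."""

    codes: dict[str, int | None]

    def __post_init__(self) -> None:
        if set(self.codes) != set(CIB_ITEMS):
            raise SchemaMismatch("record does not match the canonical item set")


@dataclass(frozen=True)
class CibComposites:
    """The eight composite subscores; NaN where undefined."""

    scores: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.scores[name]


def validate_record(raw: dict[str, int | None]) -> CibRecord:
    """Check item names, count and code range (1-5; None marks missing)."""
    unknown = set(raw) - set(CIB_ITEMS)
    if unknown:
        raise SchemaMismatch(f"unknown items: {sorted(unknown)}")
    if len(raw) != len(CIB_ITEMS):
        missing = set(CIB_ITEMS) - set(raw)
        raise SchemaMismatch(
            f"expected {len(CIB_ITEMS)} items, got {len(raw)}"
            + (f"; missing {sorted(missing)}" if missing else "")
        )
    codes: dict[str, int | None] = {}
    for item in CIB_ITEMS:
        code = raw[item]
        if code is None:
            codes[item] = None
            continue
        if not isinstance(code, (int, np.integer)) or not 1 <= code <= 5:
            raise OutOfRange(f"item {item!r}: code {code!r} outside 1-5")
        codes[item] = int(code)
    return CibRecord(codes)


def composite_scores(record: CibRecord) -> CibComposites:
    """Arithmetic mean of each composite's contributing items.

    Items in several composites count in each; a composite with more than
    half of its items missing is undefined (NaN).
    """
    scores: dict[str, float] = {}
    for name, items in COMPOSITES.items():
        vals = [record.codes[i] for i in items if record.codes[i] is not None]
        if len(vals) <= len(items) * (1 - MISSING_LIMIT):
            scores[name] = float("nan")
        else:
            scores[name] = float(np.mean(vals))
    return CibComposites(scores)


def composite_profile_plot(
    composites_by_dyad: dict[str, CibComposites], path: str
) -> str:
    """Grouped bar chart of the eight composites, one series per dyad."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not composites_by_dyad:
        raise ValueError("need at least one dyad")
    names = list(COMPOSITES)
    n_dyads = len(composites_by_dyad)
    width = 0.8 / n_dyads
    fig, ax = plt.subplots(figsize=(10, 4))
    x = np.arange(len(names))
    for k, (dyad, comps) in enumerate(composites_by_dyad.items()):
        vals = np.array([comps[n] for n in names])
        offs = x + (k - (n_dyads - 1) / 2) * width
        ax.bar(offs, np.nan_to_num(vals), width=width, label=dyad)
        for xi, v in zip(offs, vals):
            if not np.isfinite(v):
                ax.annotate("n/a", (xi, 0.1), ha="center", fontsize=7,
                            rotation=90)
    ax.set_xticks(x)
    ax.set_xticklabels([n.replace("_", "\n") for n in names], fontsize=7)
    ax.set_ylabel("composite score (1-5)")
    ax.set_ylim(0, 5.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
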