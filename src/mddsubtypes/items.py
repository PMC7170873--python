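"""Fixed vocabularies: QIDS-SR item roster and the FreeSurfer ROI measure set.

The QIDS-SR (Quick Inventory of Depressive Symptomatology, Self Report) has 16
items scored 0-3 covering sleep, mood, appetite/weight, cognitive and
psychomotor symptoms.  Several item pairs describe symptoms of opposite
polarity (e.g. decreased vs. increased appetite): a respondent cannot endorse
both members of a pair at the same time, which induces the strong negative
inter-item correlations characteristic of this instrument.
"""

from __future__ import annotations

QIDS_ITEMS: tuple[str, ...] = (
    "sleep_onset_insomnia",
    "mid_nocturnal_insomnia",
    "early_morning_awakening",
    "hypersomnia",
    "sad_mood",
    "decreased_appetite",
    "increased_appetite",
    "weight_loss",
    "weight_gain",
    "concentration",
    "self_view",
    "suicidal_ideation",
    "general_interest",
    "fatigue",
    "psychomotor_slowing",
    "psychomotor_agitation",
)

N_ITEMS = len(QIDS_ITEMS)

# Opposite-polarity symptom pairs: (side_a items, side_b items).  Within one
# subject at most one side of a pair may carry nonzero scores.  The three
# insomnia items jointly oppose the single hypersomnia item.
POLARITY_PAIRS: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] = (
    (("decreased_appetite",), ("increased_appetite",)),
    (("weight_loss",), ("weight_gain",)),
    (
        (
            "sleep_onset_insomnia",
            "mid_nocturnal_insomnia",
            "early_morning_awakening",
        ),
        ("hypersomnia",),
    ),
)

#: items belonging to any polarity pair (the neurovegetative sleep and
#: appetite/weight items); a profile's severity shift applies to the rest.
NEUROVEGETATIVE_ITEMS: frozenset[str] = frozenset(
    item for pair in POLARITY_PAIRS for side in pair for item in side
)

MIN_SCORE = 0
MAX_SCORE = 3

# ---------------------------------------------------------------------------
# ROI measures: bilateral means of FreeSurfer-derived cortical surface area
# (mm^2) and thickness (mm) for five cortical regions, and subcortical volume
# (mm^3) for three structures.  Measure kind determines whether intracranial
# volume enters the group comparison as a covariate (thickness does not scale
# with head size, so ICV is excluded there).
ROI_MEASURES: tuple[tuple[str, str], ...] = (
    ("rostral_acc_area", "area"),
    ("rostral_acc_thickness", "thickness"),
    ("caudal_acc_area", "area"),
    ("caudal_acc_thickness", "thickness"),
    ("medial_ofc_area", "area"),
    ("medial_ofc_thickness", "thickness"),
    ("anterior_insula_area", "area"),
    ("anterior_insula_thickness", "thickness"),
    ("posterior_insula_area", "area"),
    ("posterior_insula_thickness", "thickness"),
    ("hippocampus_volume", "volume"),
    ("amygdala_volume", "volume"),
    ("ventral_striatum_volume", "volume"),
)

ROI_NAMES: tuple[str, ...] = tuple(name for name, _ in ROI_MEASURES)
ROI_KINDS: dict[str, str] = dict(ROI_MEASURES)


def item_index(name: str) -> int:
    """Position of a QIDS item in the canonical order."""
    try:
        return QIDS_ITEMS.index(name)
    except ValueError:
        raise KeyError(f"unknown QIDS item: {name!r}") from None


def polarity_pair_of(item: str) -> int | None:
    """Index of the polarity pair an item belongs to, or None."""
    for i, (a, b) in enumerate(POLARITY_PAIRS):
        if item in a or item in b:
            return i
    return None
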