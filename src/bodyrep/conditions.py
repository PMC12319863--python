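"""Stimulus conditions and the hypothesized body-part category structure.

The experiment presents 10 stimulus conditions per run. Two of them
(whole body, chair) serve only the functional localizer contrast; the
remaining 8 body-part conditions enter all multivariate analyses in the
fixed order below. The hypothesized representational structure groups the
8 body parts into three labeled categories of sizes 4/2/2:
action effectors, faces, and non-effector (torso) parts.
"""

from __future__ import annotations

#: All 10 stimulus conditions in canonical order.
CONDITIONS: tuple[str, ...] = (
    "whole body",
    "chair",
    "hand",
    "foot",
    "arm",
    "leg",
    "chest",
    "waist",
    "upper face",
    "lower face",
)

#: The 8 body-part conditions used in RSA and decoding (localizer
#: conditions excluded), in canonical order.
BODY_PARTS: tuple[str, ...] = CONDITIONS[2:]

#: Category labels in canonical order (sizes 4, 2, 2).
CATEGORY_LABELS: tuple[str, ...] = ("effector", "face", "non-effector")

#: Hypothesized condition -> category assignment.
HYPOTHESIZED_CATEGORIES: dict[str, str] = {
    "hand": "effector",
    "foot": "effector",
    "arm": "effector",
    "leg": "effector",
    "upper face": "face",
    "lower face": "face",
    "chest": "non-effector",
    "waist": "non-effector",
}

LOCALIZER_CONDITIONS: tuple[str, str] = ("whole body", "chair")

N_CONDITIONS = len(CONDITIONS)
N_BODY_PARTS = len(BODY_PARTS)
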