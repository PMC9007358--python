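"""Shared label vocabularies for activity classes and intensity categories.

Five direct-observation activity classes are used throughout: sedentary
(SED), light-intensity activities and games (L_ACT_G), moderate-to-vigorous
activities and games (M_ACT_G), brisk walking (WALK) and running (RUN).
Epoch-level intensity is the usual three-category scale SED < LPA < MVPA.
"""

from __future__ import annotations

ACTIVITY_CLASSES: tuple[str, ...] = ("SED", "L_ACT_G", "M_ACT_G", "WALK", "RUN")

OUT_OF_VIEW = "OUT_OF_VIEW"

INTENSITIES: tuple[str, ...] = ("SED", "LPA", "MVPA")

# Ordering used only to break majority-class ties toward the more intense
# class; WALK sits below M_ACT_G because the latter spans up to vigorous play.
TIE_BREAK_ORDER: tuple[str, ...] = ("SED", "L_ACT_G", "WALK", "M_ACT_G", "RUN")

CLASS_TO_INTENSITY: dict[str, str] = {
    "SED": "SED",
    "L_ACT_G": "LPA",
    "M_ACT_G": "MVPA",
    "WALK": "MVPA",
    "RUN": "MVPA",
}

# CARS codes (Children's Activity Rating Scale, 1 = stationary/motionless ...
# 5 = fast translocation) that each observed class may plausibly receive.
CARS_SUPPORT: dict[str, tuple[int, ...]] = {
    "SED": (1, 2),
    "L_ACT_G": (2, 3),
    "M_ACT_G": (3, 4, 5),
    "WALK": (3, 4),
    "RUN": (4, 5),
}


def class_to_intensity(label: str) -> str:
    """Collapse a five-class activity label onto SED/LPA/MVPA."""
    try:
        return CLASS_TO_INTENSITY[label]
    except KeyError:
        raise ValueError(
            f"unknown activity class {label!r}; expected one of {ACTIVITY_CLASSES}"
        ) from None
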