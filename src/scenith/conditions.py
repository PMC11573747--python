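"""The four metabolic-inhibitor conditions of the assay.

Translation is measured under a 2x2 design of metabolic inhibition:

* ``CONTROL`` — vehicle (DMSO); full ATP production.
* ``GLUCOSE_INHIBITED`` — 2-deoxy-D-glucose (2-DG) blocks glucose metabolism.
* ``MITO_INHIBITED`` — oligomycin blocks mitochondrial ATP synthase.
* ``DOUBLE_INHIBITED`` — both compounds; ATP production fully blocked.

Serialized labels follow the conventional short names "DMSO", "2DG", "Oligo"
and "2DG+Oligo".
"""

from __future__ import annotations

import enum


class Condition(str, enum.Enum):
    CONTROL = "DMSO"
    GLUCOSE_INHIBITED = "2DG"
    MITO_INHIBITED = "Oligo"
    DOUBLE_INHIBITED = "2DG+Oligo"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        """Parse a serialized label ("DMSO", "2DG", "Oligo", "2DG+Oligo")."""
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(
            f"unknown condition label {label!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


#: Fixed iteration order used throughout: control first, double inhibition last.
CONDITION_ORDER = (
    Condition.CONTROL,
    Condition.GLUCOSE_INHIBITED,
    Condition.MITO_INHIBITED,
    Condition.DOUBLE_INHIBITED,
)
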