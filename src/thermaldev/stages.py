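"""Life-stage vocabulary shared across the package.

The cohort is tracked through the pre-adult stages of a cyclorrhaphan fly:
egg (E), first and second larval instars (L1, L2), feeding and post-feeding
("migratory") third instars (L3f, L3m), pupa (P), and adult (A).  Stage order
is fixed; every table and model in the package indexes stages by this order.
"""

from __future__ import annotations

#: Canonical stage order, egg through adult.
STAGES: tuple[str, ...] = ("E", "L1", "L2", "L3f", "L3m", "P", "A")

#: Pre-adult stages, i.e. stages with a finite duration in the model.
PREADULT_STAGES: tuple[str, ...] = STAGES[:-1]

#: Stage boundaries (from-stage, to-stage) in developmental order.
BOUNDARIES: tuple[tuple[str, str], ...] = tuple(
    (STAGES[i], STAGES[i + 1]) for i in range(len(STAGES) - 1)
)

#: Cumulative "transition" event labels, oviposition to each boundary.
TRANSITION_EVENTS: tuple[str, ...] = tuple(f"E-{b}" for _, b in BOUNDARIES)

#: Within-stage "duration" event labels (egg written out for readability).
STAGE_EVENTS: tuple[str, ...] = ("Egg", "L1", "L2", "L3f", "L3m", "P")

#: Marker used in observation tables for individuals that died in the cup.
DEAD = "dead"

STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}


def boundary_label(boundary: tuple[str, str]) -> str:
    """Human-readable label for a stage boundary, e.g. ``'L1->L2'``."""
    return f"{boundary[0]}->{boundary[1]}"


def validate_stage(stage: str) -> str:
    """Return *stage* if it is a recognised label, else raise ``ValueError``."""
    if stage not in STAGES and stage != DEAD:
        raise ValueError(
            f"unknown stage label {stage!r}; accepted labels are "
            f"{', '.join(STAGES)} or {DEAD!r}"
        )
    return stage
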