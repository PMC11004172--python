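"""Fixed label vocabularies: the 16 ALOT cell classes and the 5 diagnosis groups.

The orders below are frozen package-wide; composition vectors, classifier
outputs and report rows all index into them.
"""

from __future__ import annotations

# 9 physiological classes, debris, 6 pathological classes.
CELL_TYPES: tuple[str, ...] = (
    "B-lym",
    "T-lym",
    "Neu",
    "Mono",
    "Ery",
    "Eos",
    "NK",
    "CD34posM",
    "CD34posB",
    "debris",
    "AML-CD34pos",
    "AML-CD34neg",
    "B-ALL-CD34pos",
    "B-ALL-CD34neg",
    "T-ALL",
    "BCLPD",
)

N_CELL_TYPES = len(CELL_TYPES)
CELL_TYPE_INDEX: dict[str, int] = {c: i for i, c in enumerate(CELL_TYPES)}

PHYSIOLOGICAL_CLASSES: tuple[str, ...] = CELL_TYPES[:9]
PATHOLOGICAL_CLASSES: tuple[str, ...] = CELL_TYPES[10:]
DEBRIS = "debris"

# Patient-level diagnosis groups, in report-row order.
DIAGNOSES: tuple[str, ...] = ("Normal", "AML", "B-ALL", "Complex", "Other")
N_DIAGNOSES = len(DIAGNOSES)
DIAGNOSIS_INDEX: dict[str, int] = {d: i for i, d in enumerate(DIAGNOSES)}
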