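"""Small bundled reference data.

``casas_activity_confusion`` is the published pooled confusion matrix of
a random-forest recognizer with key-feature selection on the 8-activity
CASAS Cognitive Assessment (Kyoto) task (79 participants, 2662 evaluated
instances).  It is used in examples and as a worked example for the
metric calculations; the package never requires the CASAS download
itself.
"""

from __future__ import annotations

import numpy as np

from keysense.evaluation import ConfusionMatrix

__all__ = ["CASAS_ACTIVITY_NAMES", "casas_activity_confusion"]

#: Activity short names: kitchen cleanup, medication, birthday card,
#: DVD search, plant watering, phone call, soup cooking, outfit choice.
CASAS_ACTIVITY_NAMES = ["Kit", "Med", "BC", "DVD", "Wat", "Phone", "Soup", "Outfit"]

_COUNTS = [
    [321, 0, 0, 0, 1, 14, 1, 1],
    [0, 329, 2, 0, 0, 0, 4, 0],
    [0, 0, 311, 0, 0, 24, 0, 0],
    [0, 0, 1, 328, 0, 1, 0, 1],
    [5, 0, 0, 0, 335, 0, 0, 0],
    [3, 1, 24, 3, 0, 272, 0, 4],
    [1, 6, 0, 0, 0, 0, 326, 0],
    [0, 0, 1, 0, 0, 0, 0, 342],
]


def casas_activity_confusion() -> ConfusionMatrix:
    """The reference 8-activity confusion matrix (rows = true class)."""
    return ConfusionMatrix(list(CASAS_ACTIVITY_NAMES), np.array(_COUNTS))
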