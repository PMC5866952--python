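"""Worked-example validation data for the evaluation module.

Two published confusion matrices from a potato drought-tolerance marker
study serve as a fixed worked example: a metabolite-marker Random-Forest
model validated on 490 leaf samples from 16 agronomic field trials, and a
transcript-marker model validated on 185 samples from six agronomic
trials. Rows are predicted tolerance classes, columns observed classes
(low / intermediate / high). Recomputing sensitivity, specificity and
overall accuracy from these counts reproduces the published percentages
and pins down the metric conventions of :mod:`drymarker.evaluate`.
"""

from __future__ import annotations

import pandas as pd

from .tolerance import TOLERANCE_CLASSES

_CLASSES = list(TOLERANCE_CLASSES)


def _counts(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, index=_CLASSES, columns=_CLASSES, dtype=int)
    df.index.name = "predicted"
    df.columns.name = "observed"
    return df


#: Metabolite-marker model validated on 490 samples, 16 agronomic trials.
METABOLITE_VALIDATION_COUNTS = _counts(
    [
        [143, 5, 3],
        [13, 157, 7],
        [2, 10, 150],
    ]
)

#: Transcript-marker model validated on 185 samples, 6 agronomic trials.
TRANSCRIPT_VALIDATION_COUNTS = _counts(
    [
        [48, 18, 11],
        [1, 34, 1],
        [11, 14, 47],
    ]
)
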