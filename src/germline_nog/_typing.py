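"""Shared label conventions and small helpers."""
from __future__ import annotations

import numpy as np
import pandas as pd

RECURRED = "recurred"
NON_RECURRED = "non-recurred"

LOW = "low"
HIGH = "high"
UNPREDICTED = "unpredicted"
ABSTAIN = "abstain"


def as_binary_labels(labels) -> pd.Series:
    """Coerce recurrence labels to a 0/1 Series (1 = recurred).

    Accepts the string labels ``recurred``/``non-recurred``, booleans, or
    0/1 integers, indexed by sample id.
    """
    s = pd.Series(labels)
    if s.dtype == object:
        mapping = {RECURRED: 1, NON_RECURRED: 0}
        unknown = set(s.unique()) - set(mapping)
        if unknown:
            raise ValueError(f"unknown recurrence labels: {sorted(unknown)}")
        s = s.map(mapping)
    s = s.astype(int)
    if not s.isin([0, 1]).all():
        raise ValueError("labels must be binary (recurred / non-recurred)")
    return s


def round_half_down(x: float) -> int:
    """Round to nearest integer, ties going down (2.5 -> 2)."""
    return int(np.ceil(x - 0.5))
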