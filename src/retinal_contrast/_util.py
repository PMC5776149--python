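"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np


def round_half_away(x):
    """Round to nearest integer, ties away from zero.

    numpy's default rounding is banker's (half-to-even); the 8-bit scaling
    steps here are specified with the conventional half-away-from-zero rule
    so that e.g. 0.5 -> 1 and -0.5 -> -1.
    """
    x = np.asarray(x)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)
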