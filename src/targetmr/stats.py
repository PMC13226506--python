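"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats


def two_sided_normal_p(z):
    """Two-sided p-value for a standard-normal test statistic."""
    return 2.0 * stats.norm.sf(np.abs(z))


def two_sided_t_p(t, df: int):
    """Two-sided p-value for a t statistic with ``df`` degrees of freedom."""
    return 2.0 * stats.t.sf(np.abs(t), df)
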