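"""Hi-C interaction-strength draws for unplaced scaffolds.

Each scaffold gets two vectors of contact strengths at 10-kb bin resolution:
one toward the autosomes/X pool and one toward the Y backbone. Strengths are
gamma-distributed; for truly Y-linked scaffolds the Y-directed strengths are
multiplied by ``bias``. Scaffolds with five or fewer values on either side
are flagged unusable, matching the power threshold of the rescue test.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .._rng import substream

__all__ = ["simulate_hic_interactions", "MIN_USABLE_VALUES"]

MIN_USABLE_VALUES = 5  # strictly more than this many values are required


def simulate_hic_interactions(
    scaffold_spec: Mapping[str, bool] | Sequence[tuple[str, bool]],
    bias: float = 3.0,
    n_values: int | Mapping[str, int] = 50,
    seed: int = 0,
    gamma_shape: float = 2.0,
) -> pd.DataFrame:
    """One row per scaffold: name, truth flag, strength vectors, usability flag."""
    if bias < 1:
        raise ValueError("bias must be >= 1 (it scales Y-directed strengths)")
    items = list(scaffold_spec.items()) if isinstance(scaffold_spec, Mapping) else list(scaffold_spec)
    rng = substream(seed, "hic_interactions")
    rows = []
    for name, is_y in items:
        n = n_values[name] if isinstance(n_values, Mapping) else int(n_values)
        if n < 0:
            raise ValueError("n_values must be >= 0")
        to_aut = rng.gamma(gamma_shape, 1.0, size=n)
        to_y = rng.gamma(gamma_shape, 1.0, size=n)
        if is_y:
            to_y = to_y * bias
        rows.append((name, bool(is_y), to_aut, to_y, n > MIN_USABLE_VALUES))
    return pd.DataFrame(rows, columns=["scaffold", "is_y_truth", "to_autosomes_x",
                                       "to_y", "usable"])
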