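"""Indirect strand breaks from the chemical-reaction log.

Only OH-radical attack on 2-deoxyribose can break the backbone, and only 2
of the 5 reactive sugar sites are reachable from outside the helix, so each
such reaction converts into an indirect strand break with probability 2/5.
Reactions of OH with the bases are logged but never produce strand breaks
here (base damage is out of scope).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..constants import INDIRECT_SB_PROBABILITY
from ..direct import SB_COLUMNS


def score_indirect_breaks(events: pd.DataFrame, rng,
                          p_accept: float = INDIRECT_SB_PROBABILITY
                          ) -> pd.DataFrame:
    """Bernoulli acceptance of OH + deoxyribose events as indirect breaks."""
    if len(events) == 0:
        return pd.DataFrame(columns=SB_COLUMNS)
    a = events["reactant_a"].to_numpy(dtype=object)
    b = events["reactant_b"].to_numpy(dtype=object)
    is_target = (((a == "OH") & (b == "deoxyribose"))
                 | ((a == "deoxyribose") & (b == "OH")))
    accept = is_target & (rng.random(len(events)) < p_accept)
    hits = events[accept]
    return pd.DataFrame(dict(
        chromosome=hits["chromosome"].to_numpy(),
        bp=hits["bp"].to_numpy().astype(np.int64),
        strand=hits["strand"].to_numpy().astype(np.int64),
        origin="indirect",
        track_id=hits["track_id"].to_numpy()), columns=SB_COLUMNS)
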