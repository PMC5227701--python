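"""Directional bias of significant splicing calls.

Tests whether drug-dysregulated skipped-exon calls are skewed toward
skipping, and retained-intron calls toward retention, with an exact
one-sided binomial test under p = 1/2 (log-space tail summation; no normal
approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = ["DirectionTally", "tabulate_directions", "binomial_direction_test"]

#: Direction counted as "toward" the drug's hypothesized bias, per type.
TOWARD = {"SE": "more-skipped", "RI": "more-retained"}


@dataclass
class DirectionTally:
    event_type: str
    n_toward: int
    n_total: int
    comparison: str = ""

    def __post_init__(self):
        if not (0 <= self.n_toward <= self.n_total):
            raise ValueError("need 0 <= n_toward <= n_total")


def tabulate_directions(calls: pd.DataFrame, comparison: str = "") -> list:
    """Tally significant calls by event type and hypothesized direction.

    ``calls`` must carry ``event_type`` and ``direction`` columns (as emitted
    by ``call_dysregulated``); unlabeled calls raise.
    """
    if len(calls) and calls["direction"].isin(["NA", None]).any():
        raise ValueError("calls must carry direction labels")
    tallies = []
    for etype, toward in TOWARD.items():
        sub = calls[calls["event_type"] == etype] if len(calls) else calls
        n_total = len(sub)
        n_toward = int((sub["direction"] == toward).sum()) if n_total else 0
        tallies.append(
            DirectionTally(
                event_type=etype,
                n_toward=n_toward,
                n_total=n_total,
                comparison=comparison,
            )
        )
    return tallies


def binomial_direction_test(n_toward: int, n_total: int) -> float:
    """Exact one-sided upper-tail binomial p value at p = 1/2.

    Computes P(X >= n_toward) for X ~ Binomial(n_total, 1/2) by summing PMF
    terms in log space (stable for large n).
    """
    if n_total < 1 or not (0 <= n_toward <= n_total):
        raise ValueError("need 0 <= n_toward <= n_total and n_total >= 1")
    k = np.arange(n_toward, n_total + 1)
    logpmf = (
        special.gammaln(n_total + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n_total - k + 1)
        - n_total * np.log(2.0)
    )
    return float(min(1.0, np.exp(special.logsumexp(logpmf))))
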