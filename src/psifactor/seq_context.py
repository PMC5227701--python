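"""3' splice-acceptor sequence-context analysis.

Extracts fixed windows around cassette-exon / retained-intron acceptor
sites, builds position frequency matrices with per-position information
content (bits), and tests single-position base enrichment between
dysregulated and control event sets with Fisher's exact test.

Position convention: the exon's first base is position 0; intronic bases are
negative, so the acceptor AG dinucleotide occupies positions -2,-1 and the
branch-proximal pyrimidine context includes position -3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import SpliceEvent

__all__ = [
    "SpliceSiteContext",
    "PositionFrequencyMatrix",
    "extract_context",
    "build_pfm",
    "position_enrichment_test",
    "select_context_sets",
]

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpliceSiteContext:
    """Fixed-length acceptor context for one event."""

    event_id: str
    sequence: str
    intronic_len: int
    exonic_len: int

    def __post_init__(self):
        if len(self.sequence) != self.intronic_len + self.exonic_len:
            raise ValueError("sequence length must equal the window sum")
        if set(self.sequence) - set(BASES):
            raise ValueError("sequence must be over {A,C,G,T}")
        if self.base_at(-2) != "A" or self.base_at(-1) != "G":
            log.warning(
                "context %s lacks canonical AG at -2,-1", self.event_id
            )

    @property
    def positions(self) -> list:
        return list(range(-self.intronic_len, self.exonic_len))

    def base_at(self, position: int) -> str:
        """Base at a signed position (exon first base = 0)."""
        idx = position + self.intronic_len
        if not (0 <= idx < len(self.sequence)):
            raise IndexError(f"position {position} outside window")
        return self.sequence[idx]


@dataclass
class PositionFrequencyMatrix:
    """Per-position base frequencies plus information content in bits."""

    frequencies: pd.DataFrame  # positions x bases
    n_sequences: int

    @property
    def information_content(self) -> pd.Series:
        f = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0).sum(axis=1)
        return pd.Series(2.0 - h, index=self.frequencies.index, name="bits")


def _acceptor_coordinate(event: SpliceEvent) -> int:
    """Genomic coordinate of the exon's first base at the 3' acceptor."""
    c = event.coordinates
    if event.event_type == "SE":
        # cassette exon acceptor: left edge on +, right edge on -
        return c[1] if event.strand == "+" else c[2]
    # RI: acceptor of the downstream exon = intron end (+) / intron start (-)
    return c[1] if event.strand == "+" else c[0]


def extract_context(
    event: SpliceEvent,
    genome: dict,
    intronic_len: int = 20,
    exonic_len: int = 3,
) -> SpliceSiteContext | None:
    """Acceptor window from a genome (mapping chrom -> sequence string).

    For + strand the window is ``[acceptor - intronic_len, acceptor +
    exonic_len)``; for - strand, the reverse complement of the mirrored
    window.  Out-of-bounds windows return None and are logged.
    """
    chrom_seq = genome[event.chrom]
    acc = _acceptor_coordinate(event)
    if event.strand == "+":
        lo, hi = acc - intronic_len, acc + exonic_len
        if lo < 0 or hi > len(chrom_seq):
            log.warning("context window out of bounds for %s", event.event_id)
            return None
        seq = chrom_seq[lo:hi].upper()
    else:
        lo, hi = acc - exonic_len, acc + intronic_len
        if lo < 0 or hi > len(chrom_seq):
            log.warning("context window out of bounds for %s", event.event_id)
            return None
        seq = reverse_complement(chrom_seq[lo:hi].upper())
    return SpliceSiteContext(
        event_id=event.event_id,
        sequence=seq,
        intronic_len=intronic_len,
        exonic_len=exonic_len,
    )


def build_pfm(contexts) -> PositionFrequencyMatrix:
    """Empirical per-position base frequencies over equal-length contexts."""
    contexts = list(contexts)
    if not contexts:
        raise ValueError("need at least one context")
    lengths = {len(c.sequence) for c in contexts}
    if len(lengths) != 1:
        raise ValueError("contexts must have equal lengths")
    positions = contexts[0].positions
    counts = np.zeros((len(positions), 4))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for c in contexts:
        for j, ch in enumerate(c.sequence):
            counts[j, base_idx[ch]] += 1
    freq = counts / len(contexts)
    return PositionFrequencyMatrix(
        frequencies=pd.DataFrame(freq, index=positions, columns=list(BASES)),
        n_sequences=len(contexts),
    )


def position_enrichment_test(
    set_dys, set_ctrl, position: int, base: str = "T"
) -> tuple:
    """Two-sided Fisher's exact test for base enrichment at one position.

    The 2x2 table crosses (base vs not-base) with (dysregulated vs control).
    Returns ``(odds_ratio, p_value)``; the odds ratio uses the Haldane 0.5
    correction when any cell is zero.
    """
    set_dys, set_ctrl = list(set_dys), list(set_ctrl)
    if not set_dys or not set_ctrl:
        raise ValueError("both context sets must be non-empty")
    a = sum(c.base_at(position) == base for c in set_dys)
    b = len(set_dys) - a
    c = sum(x.base_at(position) == base for x in set_ctrl)
    d = len(set_ctrl) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return float(odds), float(p)


def select_context_sets(
    results: pd.DataFrame,
    dys_fdr_max: float = 0.05,
    dys_min_abs_dpsi: float = 0.10,
    ctrl_fdr_min: float = 0.50,
    ctrl_max_abs_dpsi: float = 0.001,
    mouse_variant: bool = False,
) -> tuple:
    """Pick dysregulated and control event-id sets from a comparison table.

    Dysregulated: FDR < ``dys_fdr_max`` and |dPSI| > ``dys_min_abs_dpsi``.
    Control (default): FDR > ``ctrl_fdr_min`` and |dPSI| < ``ctrl_max_abs_dpsi``.
    ``mouse_variant=True`` instead requires |dPSI| > ctrl_max_abs_dpsi with
    FDR > ctrl_fdr_min (the alternative published wording); sets are made
    disjoint by removing any overlap from the control set.
    """
    fdr = results["fdr"]
    adp = results["delta_psi"].abs()
    dys = results.loc[(fdr < dys_fdr_max) & (adp > dys_min_abs_dpsi), "event_id"]
    if mouse_variant:
        ctrl = results.loc[(fdr > ctrl_fdr_min) & (adp > ctrl_max_abs_dpsi), "event_id"]
    else:
        ctrl = results.loc[(fdr > ctrl_fdr_min) & (adp < ctrl_max_abs_dpsi), "event_id"]
    dys_set = list(dict.fromkeys(dys))
    ctrl_set = [e for e in dict.fromkeys(ctrl) if e not in set(dys_set)]
    if not ctrl_set:
        log.warning("select_context_sets: empty control set")
    return dys_set, ctrl_set
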