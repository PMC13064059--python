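"""LTR retrotransposon insertion-time estimation.

The two long terminal repeats of an element are identical at insertion and
diverge clock-like afterwards, so the element's age is T = K / (2 mu) with K
the per-site divergence between the 5' and 3' LTRs and mu the substitution
rate per site per generation (default 2.5e-9). The raw p-distance is
Jukes-Cantor corrected by default (K = -(3/4) ln(1 - (4/3) p)); both values
are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MU = 2.5e-9
JC_MAX_P = 0.75  # correction undefined at or above this raw divergence

GAP_CHARS = set("-.")


class SaturatedDivergenceError(ValueError):
    """Raw divergence at or above 3/4: the JC69 correction is undefined."""


@dataclass(frozen=True)
class DivergenceEstimate:
    k_raw: float  # p-distance over ungapped columns
    k: float  # JC69-corrected divergence
    n_compared: int  # ungapped aligned columns


@dataclass(frozen=True)
class InsertionTime:
    t: float  # generations
    mu: float


def jc69(p: float) -> float:
    """Jukes-Cantor distance from a p-distance."""
    if p < 0:
        raise ValueError("p-distance must be >= 0")
    if p >= JC_MAX_P:
        raise SaturatedDivergenceError(f"p = {p} >= 0.75; correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ltr_divergence(aligned5: str, aligned3: str, corrected: bool = True) -> DivergenceEstimate:
    """Divergence between two aligned LTR sequences.

    Columns with a gap in either sequence are excluded; an alignment without
    any ungapped column is an error.
    """
    if len(aligned5) != len(aligned3):
        raise ValueError("aligned sequences must have equal length")
    n = 0
    mismatches = 0
    for x, y in zip(aligned5.upper(), aligned3.upper()):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        n += 1
        if x != y:
            mismatches += 1
    if n == 0:
        raise ValueError("alignment has no ungapped columns to compare")
    p = mismatches / n
    k = jc69(p) if corrected else p
    return DivergenceEstimate(k_raw=p, k=k, n_compared=n)


def insertion_time(k: float, mu: float = DEFAULT_MU) -> InsertionTime:
    """Element age in generations from LTR-pair divergence: T = K / (2 mu)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if k < 0:
        raise ValueError("divergence must be >= 0")
    return InsertionTime(t=k / (2.0 * mu), mu=mu)


def align_ltr_pair(seq5: str, seq3: str) -> tuple:
    """Deterministic global alignment of an unaligned 5'/3' LTR pair.

    Fixed scoring (match +1, mismatch -1, gap open -5, gap extend -1); the
    first optimal alignment is used so results are reproducible.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-5,
        extend_gap_score=-1,
    )
    alignment = aligner.align(seq5.upper(), seq3.upper())[0]
    a, b = str(alignment[0]), str(alignment[1])
    return a, b


def date_ltr_pairs(
    pairs,
    mu: float = DEFAULT_MU,
    aligned: bool = False,
) -> pd.DataFrame:
    """Date a collection of LTR pairs.

    ``pairs`` yields (element_id, superfamily, seq5, seq3). Elements whose
    raw divergence saturates the correction are flagged (NaN K and T) and
    excluded from dating downstream.
    """
    rows = []
    for element_id, superfamily, seq5, seq3 in pairs:
        a, b = (seq5, seq3) if aligned else align_ltr_pair(seq5, seq3)
        try:
            div = ltr_divergence(a, b, corrected=True)
            k, k_raw, n = div.k, div.k_raw, div.n_compared
            t = insertion_time(k, mu).t
            flagged = False
        except SaturatedDivergenceError:
            raw = ltr_divergence(a, b, corrected=False)
            k_raw, n = raw.k_raw, raw.n_compared
            k = t = np.nan
            flagged = True
        rows.append(
            dict(
                element_id=element_id,
                superfamily=superfamily,
                k_raw=k_raw,
                k=k,
                t_generations=t,
                n_compared=n,
                saturated=flagged,
            )
        )
    return pd.DataFrame(rows)
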