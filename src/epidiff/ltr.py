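"""LTR retrotransposon insertion dating from paired terminal repeats.

The two long terminal repeats of an element are identical at insertion
and diverge neutrally afterwards, so their Kimura 2-parameter (K2P)
distance d, divided by twice the neutral substitution rate, dates the
insertion:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
    age = d / (2 * rate)

with P and Q the transition (A<->G, C<->T) and transversion proportions
over compared (ungapped, unambiguous) alignment columns.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import read_fasta
from .types import LTRPair

logger = logging.getLogger("epidiff")

GAP_CHARS = [b"-", b".", b"N"]


def count_substitutions(seq5: str, seq3: str):
    """Transition/transversion proportions between two aligned repeats.

    Columns containing a gap symbol or N in either sequence are skipped
    pairwise.  Returns (P, Q, sites); symmetric in its arguments.
    """
    if len(seq5) != len(seq3):
        raise ValueError("aligned sequences differ in length")
    a = np.frombuffer(seq5.upper().encode(), dtype="S1")
    b = np.frombuffer(seq3.upper().encode(), dtype="S1")
    ok = ~(np.isin(a, GAP_CHARS) | np.isin(b, GAP_CHARS))
    sites = int(ok.sum())
    if sites == 0:
        raise ValueError("no comparable (ungapped) positions")
    a, b = a[ok], b[ok]
    diff = a != b
    pur_a = np.isin(a, [b"A", b"G"])
    pur_b = np.isin(b, [b"A", b"G"])
    transitions = int((diff & (pur_a == pur_b)).sum())
    transversions = int((diff & (pur_a != pur_b)).sum())
    return transitions / sites, transversions / sites, sites


def k2p_distance(p_transitions: float, q_transversions: float
                 ) -> Optional[float]:
    """K2P distance in substitutions/site; None when saturated.

    The estimator is undefined when 1-2P-Q <= 0 or 1-2Q <= 0
    (substitutional saturation); such pairs are flagged rather than
    clamped, since clamping would fabricate finite ages.
    """
    w1 = 1.0 - 2.0 * p_transitions - q_transversions
    w2 = 1.0 - 2.0 * q_transversions
    if w1 <= 0 or w2 <= 0:
        logger.info("k2p_distance: saturated pair (P=%.4g, Q=%.4g)",
                    p_transitions, q_transversions)
        return None
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def insertion_age(d: float, rate: float = 1.05e-9):
    """Insertion age from a K2P distance at a neutral rate.

    Each repeat accumulates d/2 substitutions per site, so the element
    age in years is d / (2 * rate).  Returns (age_years, age_my).
    """
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    age_years = d / (2.0 * rate)
    return age_years, age_years / 1e6


def date_pair(element_id: str, seq5: str, seq3: str,
              rate: float = 1.05e-9) -> LTRPair:
    """Full dating of one pre-aligned LTR pair."""
    p, q, sites = count_substitutions(seq5, seq3)
    d = k2p_distance(p, q)
    age_years = insertion_age(d, rate)[0] if d is not None else None
    return LTRPair(element_id=element_id, seq5=seq5, seq3=seq3,
                   sites=sites, p_transitions=p, q_transversions=q,
                   d=d, age_years=age_years)


def date_pairs_fasta(path: str | Path, rate: float = 1.05e-9
                     ) -> list[LTRPair]:
    """Date every element in an interleaved 5'/3' LTR FASTA.

    Records come in pairs with IDs suffixed ``_5LTR`` and ``_3LTR``.
    """
    seqs = read_fasta(path)
    elements: dict[str, dict[str, str]] = {}
    for name, seq in seqs.items():
        for suffix in ("_5LTR", "_3LTR"):
            if name.endswith(suffix):
                elements.setdefault(name[: -len(suffix)], {})[suffix] = seq
                break
        else:
            raise ValueError(f"record {name!r} lacks _5LTR/_3LTR suffix")
    pairs = []
    for element_id, parts in elements.items():
        if set(parts) != {"_5LTR", "_3LTR"}:
            raise ValueError(f"element {element_id!r} is missing one LTR")
        pairs.append(date_pair(element_id, parts["_5LTR"], parts["_3LTR"],
                               rate=rate))
    return pairs


def age_histogram(pairs: Sequence[LTRPair], bin_my: float = 1.0):
    """Counts of estimable elements per age bin (million years).

    Returns (histogram dataframe with bin_start/bin_end/count, number
    of saturated/unestimable pairs reported separately).
    """
    ages = np.array([p.age_my for p in pairs if p.estimable])
    n_unestimable = sum(1 for p in pairs if not p.estimable)
    if ages.size == 0:
        return (pd.DataFrame(columns=["bin_start", "bin_end", "count"]),
                n_unestimable)
    n_bins = int(np.floor(ages.max() / bin_my)) + 1
    edges = np.arange(n_bins + 1) * bin_my
    counts, _ = np.histogram(ages, bins=edges)
    return (pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                          "count": counts}), n_unestimable)


def pairs_to_frame(pairs: Sequence[LTRPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "element_id": p.element_id, "sites": p.sites,
        "P": p.p_transitions, "Q": p.q_transversions,
        "d": p.d if p.estimable else float("nan"),
        "age_my": p.age_my if p.estimable else float("nan"),
        "estimable": p.estimable,
    } for p in pairs])
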