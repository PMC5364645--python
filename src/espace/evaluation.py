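"""Edge-recovery scoring and degree-based hub identification.

An estimated network is compared with the truth over all p(p−1)/2 node
pairs, yielding the usual confusion counts and five summary measures:
sensitivity, specificity, false discovery rate, mis-specification (total
error) rate, and the Matthews correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Iterable

import numpy as np

from .data import HubSet
from .netgen import NetworkStructure

__all__ = ["ConfusionCounts", "PerformanceReport", "confusion", "performance", "identify_hubs"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class PerformanceReport:
    """SEN, SPE, FDR, MISR in [0, 1]; MCC in [−1, 1]."""

    sen: float
    spe: float
    fdr: float
    misr: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"SEN": self.sen, "SPE": self.spe, "FDR": self.fdr,
                "MISR": self.misr, "MCC": self.mcc}


def _normalize_pairs(pairs: Iterable[tuple[int, int]], p: int) -> set[tuple[int, int]]:
    out = set()
    for i, j in pairs:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError("self-pairs are not allowed")
        if not (0 <= i < p and 0 <= j < p):
            raise ValueError(f"pair ({i},{j}) out of range for p={p}")
        out.add((min(i, j), max(i, j)))
    return out


def confusion(
    true_edges: Iterable[tuple[int, int]],
    est_edges: Iterable[tuple[int, int]],
    p: int,
) -> ConfusionCounts:
    """Confusion counts over all p(p−1)/2 unordered node pairs."""
    t = _normalize_pairs(true_edges, p)
    e = _normalize_pairs(est_edges, p)
    tp = len(t & e)
    fp = len(e - t)
    fn = len(t - e)
    tn = p * (p - 1) // 2 - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def performance(c: ConfusionCounts, p: int) -> PerformanceReport:
    """The five recovery measures.

    Degenerate denominators use the random-classification conventions:
    FDR = 0 when nothing is called (TP + FP = 0), SEN = 0 when there are
    no true edges, SPE = 0 when every pair is a true edge, and MCC = 0
    whenever any of its four denominator factors vanishes.
    """
    if c.total() != p * (p - 1) // 2:
        raise ValueError("confusion counts inconsistent with p")
    tp, fp, fn, tn = c.TP, c.FP, c.FN, c.TN
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    fdr = fp / (tp + fp) if tp + fp else 0.0
    misr = (fn + fp) / (p * (p - 1) // 2)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / sqrt(denom) if denom else 0.0
    return PerformanceReport(sen=sen, spe=spe, fdr=fdr, misr=misr, mcc=mcc)


def identify_hubs(net: NetworkStructure) -> HubSet:
    """Nodes whose degree exceeds both 7 and the 0.95 degree quantile.

    The empirical quantile uses the floor ('lower') convention — the
    largest observed degree at or below the 0.95 position — so that in a
    sparse network with a small fraction of hubs the quantile lands on the
    background-degree level and the strict inequality singles out exactly
    the high-degree nodes.
    """
    deg = net.degrees()
    q = float(np.quantile(deg, 0.95, method="lower"))
    members = frozenset(int(i) for i in np.flatnonzero((deg > 7) & (deg > q)))
    return HubSet(members)
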