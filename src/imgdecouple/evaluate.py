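"""Accuracy and agreement metrics for peaks and predictions.

Peak accuracy is the field's currency: the signed percent error
``(PK_s - PK_ref) / PK_ref * 100`` of a test peak against a reference peak
(CG ground truth in the laboratory/simulation; the original unsalvaged
value in the field, where it reads as percent *change*).  Peaks are taken
on resultant channels over t >= 0 only, excluding pre-trigger artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .signals import ChannelSignal

UNDEFINED = float("nan")


@dataclass
class PeakComparison:
    """One test-vs-reference peak pair for one kinematic measure."""

    pk_s: float
    pk_ref: float
    kinematic: str = "lin_acc"  # lin_acc | ang_vel | ang_acc
    event_id: str = ""

    @property
    def percent(self) -> float:
        return percent_error(self.pk_s, self.pk_ref)

    @property
    def difference(self) -> float:
        return self.pk_s - self.pk_ref


def post_trigger_peak(sig: ChannelSignal) -> float:
    """Maximum of a resultant channel at t >= 0."""
    return float(np.max(sig.samples[sig.trigger_index:]))


def percent_error(pk_s: float, pk_ref: float) -> float:
    """Signed percent error (or percent change) of a peak pair.

    Negative means the test peak falls below the reference.  Undefined
    (NaN) when the reference is zero.
    """
    if pk_ref == 0:
        return UNDEFINED
    return (pk_s - pk_ref) / pk_ref * 100.0


@dataclass
class BlandAltmanSummary:
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman_summary(pairs: Sequence[PeakComparison]) -> BlandAltmanSummary:
    """Mean difference, SD and 95% limits of agreement (mean +- 1.96 SD)."""
    if len(pairs) < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    d = np.array([p.difference for p in pairs])
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    return BlandAltmanSummary(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd,
                              n=len(d))


@dataclass
class AgreementTable:
    """Pairwise cross-tabulation of two methods' labels."""

    method_pair: tuple
    table: pd.DataFrame  # cross-tabulated counts
    agreement_rate: float
    n: int


def method_agreement(preds: pd.DataFrame,
                     unclear_label: str = "unclear") -> Dict[tuple, AgreementTable]:
    """Pairwise agreement over jointly defined events.

    ``preds`` has one column per method, one row per event; missing values
    and 'unclear' labels are excluded from each pair's binary agreement
    (they remain visible in the cross-tabulation margin).
    """
    methods = list(preds.columns)
    if len(methods) < 2:
        raise InsufficientDataError("need at least two methods to compare")
    out = {}
    for a, b in combinations(methods, 2):
        sub = preds[[a, b]].dropna()
        tab = pd.crosstab(sub[a], sub[b], dropna=False)
        defined = sub[(sub[a] != unclear_label) & (sub[b] != unclear_label)]
        if len(defined) == 0:
            raise InsufficientDataError(f"no jointly defined events for {a} vs {b}")
        rate = float((defined[a] == defined[b]).mean())
        out[(a, b)] = AgreementTable((a, b), tab, rate, len(defined))
    return out
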