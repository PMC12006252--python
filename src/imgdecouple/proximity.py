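"""Proximity- and quality-based coupling predictors (comparison baselines).

The iMG carries an infrared proximity sensor approximating the distance
between mouthguard and teeth.  Three simple predictors are implemented:

* **Delta-prox** — decoupled when the absolute change between the last
  pre-impact and first post-impact proximity reading strictly exceeds a
  device threshold (the manufacturer's threshold is proprietary; ours is a
  configurable parameter).
* **Quality mapping** — the manufacturer's 0/1/2 event grade: 0 is treated
  as coupled, 1 and 2 as decoupled.
* **Per-device k-means thresholding** (Luke-style) — two-means clustering
  of a device's proximity readings yields on-teeth and off-teeth cluster
  means; a device qualifies only when the mean silhouette score reaches
  0.9, and its threshold is the midpoint of the two means.  Pre/post
  readings above/below the threshold give a four-state verdict (coupled,
  decoupling, recoupling, decoupled) that collapses to binary with
  everything but 'coupled' counted as decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import IncompleteInputError, InvalidLabelError, InsufficientDataError
from .signals import COUPLED, DECOUPLED, ProximityTrace

UNCLEAR = "unclear"
RECOUPLING = "recoupling"
DECOUPLING = "decoupling"

SILHOUETTE_MIN = 0.9
#: default Delta-prox threshold, proximity units (free parameter: the
#: manufacturer's value is unpublished; this default keeps false alarms on
#: simulated coupled events rare)
DEFAULT_DELTA_PROX_THRESHOLD = 30.0


@dataclass
class DeviceClusterModel:
    """Per-device two-cluster proximity model."""

    device_id: str
    low_mean: float
    high_mean: float
    silhouette: float
    threshold: float
    status: str  # 'usable' or 'unclear'


def delta_prox_predict(trace: ProximityTrace,
                       threshold_units: float = DEFAULT_DELTA_PROX_THRESHOLD) -> str:
    """Decoupled when |post - pre| strictly exceeds the threshold."""
    if trace is None or trace.pre is None or trace.post is None:
        raise IncompleteInputError("Delta-prox needs pre and post readings")
    return DECOUPLED if abs(trace.post - trace.pre) > threshold_units else COUPLED


def quality_predict(label: int) -> str:
    """Quality 0 -> coupled; 1 or 2 -> decoupled."""
    if label is None:
        raise IncompleteInputError("quality label missing")
    if label not in (0, 1, 2):
        raise InvalidLabelError(f"quality label must be 0, 1 or 2, got {label!r}")
    return COUPLED if label == 0 else DECOUPLED


def luke_fit(readings: Sequence[float], device_id: str = "",
             silhouette_min: float = SILHOUETTE_MIN) -> DeviceClusterModel:
    """Fit a per-device two-means proximity threshold.

    In field mode pass the device's full reading series; in lab mode pass
    only the pooled per-impact pre/mid/post readings (the field series is
    biased toward on-teeth values when the device never moves before an
    impact).  Initialisation at the 10th/90th percentiles makes the fit
    deterministic and order-invariant; all-identical readings give an
    unclear device rather than an error.
    """
    x = np.sort(np.asarray(list(readings), dtype=float))  # order-invariant
    if len(x) < 4:
        raise InsufficientDataError("k-means thresholding needs >= 4 readings")
    if np.ptp(x) == 0:
        return DeviceClusterModel(device_id, float(x[0]), float(x[0]),
                                  silhouette=-1.0, threshold=float(x[0]),
                                  status=UNCLEAR)
    init = np.array([[np.percentile(x, 10)], [np.percentile(x, 90)]])
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300)
    labels = km.fit_predict(x[:, None])
    means = np.sort(km.cluster_centers_.ravel())
    if len(set(labels.tolist())) < 2:
        sil = -1.0
    else:
        sil = float(silhouette_score(x[:, None], labels))
    status = "usable" if sil >= silhouette_min else UNCLEAR
    return DeviceClusterModel(device_id, float(means[0]), float(means[1]),
                              silhouette=sil,
                              threshold=float(means.mean()), status=status)


def luke_predict(model: DeviceClusterModel, trace: ProximityTrace) -> str:
    """Four-state verdict from pre/post readings against the threshold.

    Readings above the threshold are on-teeth ('coupled' state): both above
    -> coupled; pre above, post below -> decoupling; pre below, post above
    -> recoupling; both below -> decoupled.  Unclear devices return
    'unclear'.
    """
    if model.status == UNCLEAR:
        return UNCLEAR
    if trace is None or trace.pre is None or trace.post is None:
        raise IncompleteInputError("Luke prediction needs pre and post readings")
    pre_on = trace.pre > model.threshold
    post_on = trace.post > model.threshold
    if pre_on and post_on:
        return COUPLED
    if pre_on and not post_on:
        return DECOUPLING
    if not pre_on and post_on:
        return RECOUPLING
    return DECOUPLED


def luke_binary(verdict: str) -> str:
    """Collapse the four-state verdict: everything but coupled is decoupled."""
    if verdict == UNCLEAR:
        return UNCLEAR
    return COUPLED if verdict == COUPLED else DECOUPLED
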