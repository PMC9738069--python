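"""Marker-panel dysbiosis classification.

Discriminating species from the biomarker stage are turned into a
per-sample classifier: each marker gets a relative-abundance threshold
from a ROC curve against the IBD / non-IBD phenotype labels, and a
sample is called dysbiotic (D) when it meets at least ``min_markers``
of the marker criteria (default: 3 of 4). A criterion is met on the
dysbiotic side of the threshold: above it for a dysbiosis-enriched
marker, below it for a depleted one.

Outlier samples (e.g. extreme single-species blooms) can be excluded
before marker discovery via explicit ids or per-species abundance caps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENRICHED = "dysbiosis-enriched"
DEPLETED = "dysbiosis-depleted"

__all__ = [
    "RocCurve",
    "Marker",
    "MarkerPanel",
    "DysbiosisCall",
    "roc_curve",
    "select_threshold",
    "exclude_outliers",
    "build_panel",
    "classify_dysbiosis",
    "classify_all",
]


@dataclass
class RocCurve:
    """ROC points over candidate thresholds (midpoints + infinite sentinels)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str  # "greater": score > threshold is called positive


@dataclass
class Marker:
    species: str
    direction: str  # ENRICHED or DEPLETED
    threshold: float


@dataclass
class MarkerPanel:
    markers: list[Marker]
    min_markers: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.min_markers <= len(self.markers):
            raise ValueError("min_markers must be in [1, number of markers]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "min_markers": self.min_markers,
                "markers": [
                    {"species": m.species, "direction": m.direction, "threshold": m.threshold}
                    for m in self.markers
                ],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MarkerPanel":
        obj = json.loads(text)
        return cls(
            markers=[Marker(m["species"], m["direction"], m["threshold"]) for m in obj["markers"]],
            min_markers=obj["min_markers"],
        )


@dataclass
class DysbiosisCall:
    sample_id: str
    n_criteria_met: int
    label: str  # "D" or "ND"


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = "greater",
) -> RocCurve:
    """ROC curve over midpoint thresholds.

    ``direction="greater"`` calls a sample positive when its score
    exceeds the threshold; ``"less"`` when it is below. AUC is the
    trapezoid integral of sensitivity over 1 - specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both label values must be present")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    npos, nneg = int(y.sum()), int((~y).sum())
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = s > t if direction == "greater" else s < t
        sens[i] = (pred & y).sum() / npos
        spec[i] = (~pred & ~y).sum() / nneg
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ascending fpr, ties by ascending tpr
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocCurve(thresholds, sens, spec, auc, direction)


def select_threshold(roc: RocCurve, policy: str = "youden") -> float:
    """Pick an operating threshold from a ROC curve.

    ``youden`` maximises J = sensitivity + specificity - 1; ties are
    broken by higher specificity, then by higher sensitivity (smaller
    sensitivity loss). ``max_specificity`` maximises specificity among
    points with positive J, breaking ties by higher sensitivity.
    """
    finite = np.isfinite(roc.thresholds)
    # keep sentinels usable only if nothing finite exists
    idx = np.flatnonzero(finite) if finite.any() else np.arange(len(roc.thresholds))
    sens, spec, thr = roc.sensitivity[idx], roc.specificity[idx], roc.thresholds[idx]
    j = sens + spec - 1.0
    if policy == "youden":
        keys = list(zip(np.round(j, 12), np.round(spec, 12), np.round(sens, 12)))
    elif policy == "max_specificity":
        ok = j > 0
        if not ok.any():
            ok = np.ones_like(j, dtype=bool)
        sens, spec, thr, j = sens[ok], spec[ok], thr[ok], j[ok]
        keys = list(zip(np.round(spec, 12), np.round(sens, 12), np.round(j, 12)))
    else:
        raise ValueError(f"unknown policy {policy!r}")
    best = max(range(len(keys)), key=lambda i: keys[i])
    return float(thr[best])


def exclude_outliers(
    abundances: pd.DataFrame,
    exclude_ids: Sequence[str] | None = None,
    species_caps: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop outlier samples before marker discovery / classification.

    ``abundances`` is samples x species (percent). A sample is excluded
    when its id is listed, or when any ``(species, max_percent)`` cap is
    exceeded. Returns (filtered table, report of exclusions with the
    triggering rule).
    """
    reasons: list[tuple[str, str]] = []
    for sid in abundances.index:
        if exclude_ids and sid in set(exclude_ids):
            reasons.append((sid, "explicit"))
            continue
        if species_caps:
            for sp, cap in species_caps.items():
                if sp in abundances.columns and abundances.at[sid, sp] > cap:
                    reasons.append((sid, f"{sp} > {cap}"))
                    break
    report = pd.DataFrame(reasons, columns=["sample_id", "rule"])
    for sid, rule in reasons:
        logger.info("excluding sample %s (%s)", sid, rule)
    kept = abundances.drop(index=report["sample_id"].tolist())
    return kept, report


def build_panel(
    lefse_result: pd.DataFrame,
    abundances: pd.DataFrame,
    labels: Sequence[str],
    positive_class: str,
    top_k: int = 4,
    policy: str = "youden",
    min_markers: int = 3,
) -> MarkerPanel:
    """Marker panel from biomarker results + per-marker ROC thresholds.

    Takes the ``top_k`` features by LDA score; a marker enriched in the
    ``positive_class`` (IBD) is dysbiosis-enriched, otherwise depleted.
    Thresholds come from a ROC curve of the marker's abundance against
    the positive/negative labels, honouring the marker direction.

    If fewer than ``top_k`` discriminating features exist, the panel
    shrinks and ``min_markers`` is clamped to ``size - 1`` (floor 1)
    with a warning.
    """
    labels = np.asarray(labels)
    y = (labels == positive_class).astype(int)
    top = lefse_result.sort_values("lda_score", ascending=False).head(top_k)
    if len(top) == 0:
        raise ValueError("no discriminating features to build a panel from")
    if len(top) < top_k:
        min_markers = max(1, min(min_markers, len(top) - 1)) if len(top) > 1 else 1
        logger.warning(
            "only %d discriminating features; min_markers clamped to %d", len(top), min_markers
        )
    markers = []
    for species, row in top.iterrows():
        direction = ENRICHED if row["enriched_class"] == positive_class else DEPLETED
        scores = abundances[species].to_numpy(dtype=float)
        roc = roc_curve(scores, y, "greater" if direction == ENRICHED else "less")
        markers.append(Marker(str(species), direction, select_threshold(roc, policy)))
    return MarkerPanel(markers, min_markers=min(min_markers, len(markers)))


def classify_dysbiosis(sample_abundances: Mapping[str, float] | pd.Series, panel: MarkerPanel,
                       sample_id: str = "") -> DysbiosisCall:
    """Apply the >= min_markers-of-n rule to one sample.

    A marker species absent from the profile counts as abundance 0
    (logged): that meets a depleted criterion and fails an enriched one.
    """
    met = 0
    for m in panel.markers:
        if m.species in sample_abundances:
            a = float(sample_abundances[m.species])
        else:
            logger.info("sample %s: marker %s absent, treated as 0", sample_id, m.species)
            a = 0.0
        if m.direction == ENRICHED and a > m.threshold:
            met += 1
        elif m.direction == DEPLETED and a < m.threshold:
            met += 1
    label = "D" if met >= panel.min_markers else "ND"
    return DysbiosisCall(sample_id=sample_id, n_criteria_met=met, label=label)


def classify_all(abundances: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Classify every row of a samples x species table."""
    calls = [
        classify_dysbiosis(row, panel, sample_id=str(sid))
        for sid, row in abundances.iterrows()
    ]
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "n_criteria_met": [c.n_criteria_met for c in calls],
            "label": [c.label for c in calls],
        }
    ).set_index("sample_id")
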