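"""AHL identification from MRM peak tables.

Acyl-homoserine lactones fragment along two diagnostic channels in
positive-mode MS/MS: the neutral loss of the homoserine-lactone moiety
(101 Da, product at [M+H-101]+) and the protonated lactone fragment at
m/z 102. A candidate AHL (designated by its precursor [M+H]+ m/z M) is
confirmed in a sample when both product-ion transitions are observed
co-eluting: a peak with product m/z within ``mz_tol`` of M - 101 and a
peak within ``mz_tol`` of 102, their retention times within ``rt_tol``
of each other (and of the precursor trace's apex when one is recorded).
Confirmed AHLs are quantified by the neutral-loss (quantifier)
transition area normalised to a spiked deuterated internal standard
(C6-d3-HSL), giving relative concentrations.

Input is a post-integration peak table (one row per integrated
transition peak: precursor m/z, product m/z, retention time, area), as
exported by instrument software; raw chromatograms are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NEUTRAL_LOSS_DA = 101.048  # homoserine lactone neutral loss
LACTONE_MZ = 102.055  # protonated lactone fragment

PEAK_COLUMNS = ["precursor_mz", "product_mz", "rt_min", "area"]

__all__ = [
    "IstdSpec",
    "AhlCall",
    "call_ahls",
    "normalize_to_istd",
    "build_profile_matrix",
    "ahl_richness",
    "NEUTRAL_LOSS_DA",
    "LACTONE_MZ",
]


@dataclass(frozen=True)
class IstdSpec:
    """Internal-standard transition (C6-d3-HSL by default)."""

    precursor_mz: float = 203.15
    product_mz: float = 102.10
    spike_amount: float = 1.0  # known spike, scales relative concentrations


@dataclass
class AhlCall:
    precursor_mz: float
    confirmed: bool
    rt: float = np.nan  # area-weighted mean RT of matched peaks
    quantifier_area: float = 0.0
    relative_concentration: float = 0.0


def _match(peaks: pd.DataFrame, precursor: float, product: float, tol: float) -> pd.DataFrame:
    return peaks[
        (np.abs(peaks["precursor_mz"] - precursor) <= tol)
        & (np.abs(peaks["product_mz"] - product) <= tol)
    ]


def call_ahls(
    peaks: pd.DataFrame,
    candidates: Sequence[float],
    mz_tol: float = 0.3,
    rt_tol: float = 0.1,
    require_both_products: bool = True,
) -> list[AhlCall]:
    """Apply the two-product-ion co-elution rule to each candidate.

    ``require_both_products=False`` switches to the permissive reading
    in which either diagnostic product ion suffices.
    """
    if mz_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    calls = []
    for m in candidates:
        nl = _match(peaks, m, m - NEUTRAL_LOSS_DA, mz_tol)
        lact = _match(peaks, m, LACTONE_MZ, mz_tol)
        prec = _match(peaks, m, m, mz_tol)  # optional precursor trace
        best = None  # (total area, rt, quantifier area)
        nl_rows = list(nl.itertuples()) or ([None] if not require_both_products else [])
        lact_rows = list(lact.itertuples()) or ([None] if not require_both_products else [])
        for a in nl_rows:
            for b in lact_rows:
                if a is None and b is None:
                    continue
                rts = [r.rt_min for r in (a, b) if r is not None]
                if len(rts) == 2 and abs(rts[0] - rts[1]) > rt_tol:
                    continue
                if len(prec):
                    # precursor trace recorded: some precursor apex must co-elute
                    apexes = prec["rt_min"].to_numpy()
                    if not any(
                        all(abs(rt - apex) <= rt_tol for rt in rts) for apex in apexes
                    ):
                        continue
                areas = np.array([r.area for r in (a, b) if r is not None])
                rt = float(np.average(rts, weights=areas)) if areas.sum() > 0 else float(np.mean(rts))
                quant = a.area if a is not None else 0.0
                cand = (areas.sum(), rt, quant)
                if best is None or cand[0] > best[0]:
                    best = cand
        if best is None:
            calls.append(AhlCall(float(m), confirmed=False))
        else:
            calls.append(
                AhlCall(float(m), confirmed=True, rt=best[1], quantifier_area=float(best[2]))
            )
    return calls


def normalize_to_istd(
    areas: Sequence[float] | float, istd_area: float, spike_amount: float = 1.0
) -> np.ndarray | float:
    """Relative concentration: quantifier area / internal-standard area."""
    if istd_area <= 0:
        raise ValueError("internal-standard area must be > 0")
    out = np.asarray(areas, dtype=float) / istd_area * spike_amount
    return float(out) if np.ndim(areas) == 0 else out


def _istd_area(peaks: pd.DataFrame, istd: IstdSpec, mz_tol: float) -> float | None:
    rows = _match(peaks, istd.precursor_mz, istd.product_mz, mz_tol)
    if len(rows) == 0:
        return None
    return float(rows["area"].max())


def build_profile_matrix(
    peak_tables: Mapping[str, pd.DataFrame],
    candidates: Sequence[float],
    istd: IstdSpec | None = None,
    mz_tol: float = 0.3,
    rt_tol: float = 0.1,
    require_both_products: bool = True,
) -> pd.DataFrame:
    """Samples x AHL matrix of relative concentrations (0 = unconfirmed).

    Samples whose internal-standard peak is missing are dropped with a
    warning. Columns are kept only for AHLs confirmed in >= 1 sample.
    """
    istd = istd or IstdSpec()
    rows = {}
    for sid, peaks in sorted(peak_tables.items()):
        ia = _istd_area(peaks, istd, mz_tol)
        if ia is None:
            logger.warning("sample %s: internal-standard peak missing; sample dropped", sid)
            continue
        calls = call_ahls(peaks, candidates, mz_tol, rt_tol, require_both_products)
        rows[sid] = {
            f"{c.precursor_mz:.2f}": (
                normalize_to_istd(c.quantifier_area, ia, istd.spike_amount) if c.confirmed else 0.0
            )
            for c in calls
        }
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    if matrix.empty:
        return matrix
    return matrix.loc[:, (matrix > 0).any(axis=0)]


def ahl_richness(
    matrix: pd.DataFrame, groups: Mapping[str, str]
) -> tuple[dict[str, int], pd.Series]:
    """Distinct confirmed AHLs per group, and per-sample counts.

    ``groups`` maps sample id to group name. A group's richness is the
    number of AHL columns confirmed (> 0) in at least one of its
    samples.
    """
    per_sample = (matrix > 0).sum(axis=1)
    per_group: dict[str, int] = {}
    for g in sorted(set(groups.values())):
        members = [s for s in matrix.index if groups.get(s) == g]
        if members:
            per_group[g] = int((matrix.loc[members] > 0).any(axis=0).sum())
        else:
            per_group[g] = 0
    return per_group, per_sample
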