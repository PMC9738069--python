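"""Biomarker discovery by LDA effect size (LEfSe-style).

Two-stage procedure used to find group-discriminating species:

1. Kruskal-Wallis screen per feature at ``alpha`` (tie-corrected).
2. Bootstrapped linear-discriminant effect size on the survivors:
   samples are normalised so each sums to ``feature_scale``; on each
   bootstrap (a per-class subsample of ``bootstrap_fraction``) a
   one-dimensional Fisher discriminant is fitted on the candidate
   features with a ridge-regularised pooled covariance, and the
   per-feature effect is the mean over bootstraps of

       1/2 (|w_j * (m1_j - m0_j)| + |m1_j - m0_j|)

   where ``w`` is the unit-norm discriminant axis and ``m`` the class
   means. The reported LDA score is ``log10(max(effect, 1))``.

Features with score above ``lda_threshold`` (default 2) are returned as
discriminating, each tagged with the class in which it is enriched.
The subclass (pairwise Wilcoxon) stage of the original procedure is
omitted: only plain class labels are used here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LefseConfig", "kw_screen", "lda_effect_size", "run_lefse"]


@dataclass
class LefseConfig:
    alpha: float = 0.05
    lda_threshold: float = 2.0
    n_bootstrap: int = 30
    bootstrap_fraction: float = 2.0 / 3.0
    feature_scale: float = 1e6
    ridge: float = 1e-6
    max_retries: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")


def _normalise(table: pd.DataFrame, scale: float) -> pd.DataFrame:
    sums = table.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("every sample must have positive total abundance")
    return table.div(sums, axis=0) * scale


def kw_screen(
    table: pd.DataFrame,
    classes: Sequence[str],
    alpha: float = 0.05,
) -> tuple[list[str], pd.Series]:
    """Kruskal-Wallis screen; returns (candidate features, all p-values).

    A feature constant across all samples gets p = 1 (never a candidate).
    """
    classes = np.asarray(classes)
    uniq = np.unique(classes)
    if len(uniq) < 2:
        raise ValueError("need at least two classes")
    for u in uniq:
        if (classes == u).sum() < 2:
            raise ValueError(f"class {u!r} has fewer than 2 samples")
    pvals = {}
    groups_idx = [classes == u for u in uniq]
    values = table.to_numpy(dtype=float)
    for j, feature in enumerate(table.columns):
        col = values[:, j]
        if np.all(col == col[0]):
            pvals[feature] = 1.0
            continue
        _, p = stats.kruskal(*(col[idx] for idx in groups_idx))
        pvals[feature] = float(p)
    pser = pd.Series(pvals, name="kw_p")
    candidates = [f for f in table.columns if pser[f] < alpha]
    return candidates, pser


def _fisher_axis(x: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    """Unit-norm Fisher discriminant axis for binary classes."""
    x0, x1 = x[y == 0], x[y == 1]
    delta = x1.mean(axis=0) - x0.mean(axis=0)
    sw = np.cov(x0, rowvar=False, ddof=1) * (len(x0) - 1)
    sw = sw + np.cov(x1, rowvar=False, ddof=1) * (len(x1) - 1)
    sw = np.atleast_2d(sw) / max(len(x) - 2, 1)
    lam = ridge * max(np.trace(sw) / sw.shape[0], 1.0)
    w = np.linalg.solve(sw + lam * np.eye(sw.shape[0]), delta)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lda_effect_size(
    table: pd.DataFrame,
    classes: Sequence[str],
    config: LefseConfig,
    candidates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Bootstrapped LDA effect size for (pre-screened) features.

    Returns a frame indexed by feature with ``lda_score`` (log10 scale)
    and ``enriched_class`` (class with the higher mean on full data).
    Deterministic under ``config.seed``.
    """
    classes = np.asarray(classes)
    uniq = list(np.unique(classes))
    if len(uniq) != 2:
        raise ValueError("effect size requires exactly two classes")
    feats = list(table.columns if candidates is None else candidates)
    if not feats:
        return pd.DataFrame(columns=["lda_score", "enriched_class"])
    # canonical sample order: bootstrap draws depend only on sorted ids
    order = np.argsort(table.index.astype(str), kind="stable")
    table = table.iloc[order]
    classes = classes[order]
    scaled = _normalise(table, config.feature_scale)[feats]
    y = (classes == uniq[1]).astype(int)
    x = scaled.to_numpy(dtype=float)
    idx_by_class = [np.flatnonzero(y == k) for k in (0, 1)]
    take = [max(2, int(np.ceil(config.bootstrap_fraction * len(i)))) for i in idx_by_class]
    for k, t in zip((0, 1), take):
        if t > len(idx_by_class[k]):
            raise ValueError(f"class {uniq[k]!r} too small for bootstrapping")

    rng = np.random.default_rng(config.seed)
    effects = np.zeros((config.n_bootstrap, len(feats)))
    for b in range(config.n_bootstrap):
        for attempt in range(config.max_retries):
            sel = np.concatenate(
                [rng.choice(idx, size=t, replace=False) for idx, t in zip(idx_by_class, take)]
            )
            xb, yb = x[sel], y[sel]
            if min((yb == 0).sum(), (yb == 1).sum()) >= 2:
                break
        else:
            raise RuntimeError("bootstrap could not keep both classes populated")
        delta = xb[yb == 1].mean(axis=0) - xb[yb == 0].mean(axis=0)
        w = _fisher_axis(xb, yb, config.ridge)
        effects[b] = 0.5 * (np.abs(w * delta) + np.abs(delta))

    mean_effect = effects.mean(axis=0)
    scores = np.log10(np.maximum(mean_effect, 1.0))
    m0 = x[y == 0].mean(axis=0)
    m1 = x[y == 1].mean(axis=0)
    enriched = np.where(m1 >= m0, uniq[1], uniq[0])
    return pd.DataFrame(
        {"lda_score": scores, "enriched_class": enriched}, index=pd.Index(feats, name="feature")
    )


def run_lefse(
    table: pd.DataFrame,
    classes: Sequence[str],
    config: LefseConfig | None = None,
) -> pd.DataFrame:
    """Full screen + effect-size pipeline.

    Returns a frame (feature, kw_p, lda_score, enriched_class) restricted
    to lda_score > threshold, sorted by descending score; ties broken
    lexicographically by feature name.
    """
    config = config or LefseConfig()
    candidates, pvals = kw_screen(table, classes, config.alpha)
    if not candidates:
        return pd.DataFrame(columns=["kw_p", "lda_score", "enriched_class"])
    eff = lda_effect_size(table, classes, config, candidates)
    eff = eff[eff["lda_score"] > config.lda_threshold]
    out = eff.copy()
    out.insert(0, "kw_p", pvals[out.index])
    out = (
        out.reset_index()
        .sort_values(["lda_score", "feature"], ascending=[False, True])
        .set_index("feature")
    )
    return out
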