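"""Group construction, nonparametric comparisons, cohort summaries and
pipeline orchestration.

Samples are cross-classified by phenotype (non-IBD / CD / UC) and
dysbiosis call (D / ND) into the analysis groups ND, D, ND-non-IBD,
ND-IBD and D-IBD. Two-group comparisons use the two-tailed
Mann-Whitney U test (exact for small tie-free samples, normal
approximation with tie correction otherwise); multi-group comparisons
use Kruskal-Wallis with Dunn's post-hoc z-tests and Holm adjustment.
Clinical-activity summaries bucket Harvey-Bradshaw Index (CD) and
SCCAI (UC) scores into the usual activity categories.

``run_pipeline`` chains the whole synthetic analysis — simulate ->
diversity -> biomarkers -> dysbiosis classification -> gene
quantification -> group comparisons — and writes TSV/JSON artifacts
plus a manifest (inputs, seed, thresholds, artifact checksums)
sufficient to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import profiles_diversity as pdv
from . import synthetic_data as sd
from .dysbiosis import build_panel, classify_all, exclude_outliers
from .lefse import LefseConfig, run_lefse

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "CohortSummary",
    "PipelineConfig",
    "define_groups",
    "mann_whitney",
    "kruskal_dunn",
    "summarize_cohort",
    "run_pipeline",
]


@dataclass
class ComparisonResult:
    test: str
    groups: list[str]
    statistic: float
    p_two_sided: float
    pairwise: pd.DataFrame | None = None  # Dunn z, raw and adjusted p


# HBI (CD): non-active < 4, mild [4, 8), moderate [8, 12), severe >= 12
# SCCAI (UC): non-active [0, 2], mild [3, 5], moderate/severe > 5
def _hbi_category(score: float) -> str:
    if score < 4:
        return "non-active"
    if score < 8:
        return "mild"
    if score < 12:
        return "moderate"
    return "severe"


def _sccai_category(score: float) -> str:
    if score <= 2:
        return "non-active"
    if score <= 5:
        return "mild"
    return "moderate/severe"


@dataclass
class CohortSummary:
    group_n: dict[str, int]
    activity_counts: dict[str, dict[str, int]]  # phenotype -> category -> n
    activity_percent: dict[str, dict[str, int]]
    unknown: dict[str, int]


def define_groups(calls: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join dysbiosis calls onto sample metadata.

    Returns one row per called sample with its phenotype, D/ND label
    and derived-group memberships. Metadata samples without a call
    (e.g. excluded outliers) are omitted with a log entry.
    """
    calls = calls.reset_index() if "sample_id" not in calls.columns else calls
    meta = metadata.set_index("sample_id")
    rows = []
    for sid in meta.index:
        if sid not in set(calls["sample_id"]):
            logger.info("sample %s has no dysbiosis call; omitted from groups", sid)
            continue
        label = calls.set_index("sample_id").at[sid, "label"]
        pheno = meta.at[sid, "phenotype"]
        ibd = pheno in ("CD", "UC")
        groups = [label]
        if label == "ND":
            groups.append("ND-IBD" if ibd else "ND-non-IBD")
        elif ibd:
            groups.append("D-IBD")
        rows.append(
            {"sample_id": sid, "phenotype": pheno, "dysbiosis": label,
             "groups": ",".join(groups)}
        )
    return pd.DataFrame(rows)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Two-tailed Mann-Whitney U.

    Exact enumeration when n_x + n_y <= 12 and no ties are present;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(
        test="mann-whitney", groups=["x", "y"],
        statistic=float(res.statistic), p_two_sided=float(res.pvalue),
    )


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]], p_adjust: str = "holm"
) -> ComparisonResult:
    """Kruskal-Wallis with Dunn's pairwise z-tests.

    Dunn's statistic compares mean ranks over the pooled sample with
    the tie-corrected variance; pairwise p-values are adjusted with the
    chosen method (``holm`` default, ``bonferroni`` or ``none``).
    """
    names = list(groups.keys())
    if len(names) < 3:
        raise ValueError("kruskal_dunn expects >= 3 groups")
    values = [np.asarray(groups[g], dtype=float) for g in names]
    stat, p = stats.kruskal(*values)

    pooled = np.concatenate(values)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g, v in zip(names, values):
        mean_ranks[g] = ranks[start:start + len(v)].mean()
        sizes[g] = len(v)
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    pair_rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            praw = 2.0 * stats.norm.sf(abs(z))
            pair_rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(praw, 1.0)})
    pairwise = pd.DataFrame(pair_rows)
    if p_adjust == "none":
        pairwise["p_adj"] = pairwise["p_raw"]
    else:
        pairwise["p_adj"] = multipletests(pairwise["p_raw"], method=p_adjust)[1]
    return ComparisonResult(
        test="kruskal-wallis+dunn", groups=names,
        statistic=float(stat), p_two_sided=float(p), pairwise=pairwise,
    )


def _pct(count: int, denom: int) -> int:
    return int(np.floor(count / denom * 100.0 + 0.5)) if denom else 0


def summarize_cohort(metadata: pd.DataFrame) -> CohortSummary:
    """Activity-category counts and percentages per phenotype.

    Percentage denominators: CD uses all CD samples, UC uses only the
    samples with a known score (the two conventions the printed cohort
    arithmetic follows); both counts are reported.
    """
    group_n, counts, percent, unknown = {}, {}, {}, {}
    if len(metadata) == 0:
        return CohortSummary(group_n, counts, percent, unknown)
    for pheno, sub in metadata.groupby("phenotype"):
        group_n[str(pheno)] = len(sub)
        if pheno not in ("CD", "UC"):
            continue
        scores = sub["activity_score"]
        known = scores.dropna()
        unknown[str(pheno)] = int(scores.isna().sum())
        cat_fn = _hbi_category if pheno == "CD" else _sccai_category
        cats = known.map(cat_fn)
        order = (
            ["non-active", "mild", "moderate", "severe"]
            if pheno == "CD"
            else ["non-active", "mild", "moderate/severe"]
        )
        c = {k: int((cats == k).sum()) for k in order}
        denom = len(sub) if pheno == "CD" else len(known)
        counts[str(pheno)] = c
        percent[str(pheno)] = {k: _pct(v, denom) for k, v in c.items()}
    return CohortSummary(group_n, counts, percent, unknown)


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every threshold the pipeline applies, in one place."""

    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    rarefaction_depth: int = 50_000
    shannon_base: float = 2.0
    permanova_permutations: int = 9_999
    lefse_alpha: float = 0.05
    lda_threshold: float = 2.0
    n_bootstrap: int = 30
    top_k_markers: int = 4
    min_markers: int = 3
    threshold_policy: str = "youden"
    outlier_species_caps: dict[str, float] = field(default_factory=dict)
    outlier_exclude_ids: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        sim = sd.SimConfig(**sim_raw) if sim_raw else sd.SimConfig(seed=raw.get("seed", 0))
        return cls(sim=sim, **raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Synthetic end-to-end run; returns the manifest dict.

    Stages: simulate -> diversity -> biomarker discovery -> panel +
    classification -> gene quantification -> group comparisons.
    Artifacts are TSV/JSON under ``out_dir``; the manifest records the
    full configuration, seed and a sha256 per artifact.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = os.path.join(out_dir, name)
        df.to_csv(path, sep="\t", float_format="%.10g", **kw)
        paths[name] = path

    # -- simulate
    sim = dataclasses.replace(config.sim, seed=config.seed)
    profiles, truth = sd.simulate_community(sim)
    gene_hits = sd.simulate_gene_hits(sim, truth)
    sd.write_profiles_tsv(profiles, truth.lineages, os.path.join(out_dir, "profiles.tsv"))
    paths["profiles.tsv"] = os.path.join(out_dir, "profiles.tsv")
    sd.write_metadata_tsv(truth, os.path.join(out_dir, "metadata.tsv"))
    paths["metadata.tsv"] = os.path.join(out_dir, "metadata.tsv")

    # -- diversity
    counts = pdv.build_count_table(profiles)
    depth = min(config.rarefaction_depth, int(counts.data.sum(axis=1).min()))
    if depth < config.rarefaction_depth:
        logger.info("reducing rarefaction depth to %d (shallowest sample)", depth)
    rare = pdv.rarefy(counts, depth=depth, seed=np.random.default_rng([config.seed, 10]))
    alpha = pdv.alpha_diversity_table(rare, config.shannon_base)
    save(alpha, "alpha_diversity.tsv", index_label="sample_id")
    dist = pdv.bray_curtis_matrix(rare)
    save(pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids),
         "bray_curtis.tsv", index_label="sample_id")
    coords = pdv.pcoa(dist).coordinates
    save(coords, "pcoa.tsv", index_label="sample_id")
    meta = truth.metadata.set_index("sample_id").loc[rare.data.index]
    perm_pheno = pdv.permanova(
        dist, meta["phenotype"].to_numpy(), config.permanova_permutations,
        seed=np.random.default_rng([config.seed, 11]),
    )

    # -- biomarkers + dysbiosis panel (IBD vs non-IBD)
    rel = rare.data.div(rare.data.sum(axis=1), axis=0) * 100.0
    rel, outlier_report = exclude_outliers(
        rel, config.outlier_exclude_ids, config.outlier_species_caps
    )
    save(outlier_report, "outliers.tsv", index=False)
    pheno = meta.loc[rel.index, "phenotype"]
    classes = np.where(pheno.isin(["CD", "UC"]), "IBD", "non-IBD")
    lefse_cfg = LefseConfig(
        alpha=config.lefse_alpha, lda_threshold=config.lda_threshold,
        n_bootstrap=config.n_bootstrap, seed=config.seed + 101,
    )
    markers = run_lefse(rel, classes, lefse_cfg)
    save(markers, "lefse.tsv")
    panel = build_panel(
        markers, rel, classes, positive_class="IBD",
        top_k=config.top_k_markers, policy=config.threshold_policy,
        min_markers=config.min_markers,
    )
    with open(os.path.join(out_dir, "panel.json"), "w") as fh:
        fh.write(panel.to_json() + "\n")
    paths["panel.json"] = os.path.join(out_dir, "panel.json")
    calls = classify_all(rel, panel)
    save(calls, "dysbiosis_calls.tsv")
    groups = define_groups(calls, truth.metadata)
    save(groups, "groups.tsv", index=False)

    # -- gene quantification + comparisons
    save(gene_hits, "gene_metrics.tsv", index=False)
    labels = calls["label"]
    perm_dys = pdv.permanova(
        _subset_dist(dist, list(labels.index)), labels.to_numpy(),
        config.permanova_permutations, seed=np.random.default_rng([config.seed, 12]),
    )
    comparisons: dict[str, dict] = {
        "permanova_phenotype": {"pseudo_F": perm_pheno.pseudo_f, "p": perm_pheno.p_value},
        "permanova_dysbiosis": {"pseudo_F": perm_dys.pseudo_f, "p": perm_dys.p_value},
    }
    common = alpha.index.intersection(labels.index)
    for metric in ("observed", "shannon"):
        d = alpha.loc[common, metric][labels.loc[common] == "D"]
        nd = alpha.loc[common, metric][labels.loc[common] == "ND"]
        r = mann_whitney(d, nd)
        comparisons[f"alpha_{metric}_D_vs_ND"] = {"U": r.statistic, "p": r.p_two_sided}
    gh = gene_hits.set_index("sample_id")
    for gene in sorted(gh["gene_id"].unique()):
        sub = gh[gh["gene_id"] == gene]
        expr = sub.loc[~sub["excluded"], "expression"]
        lab = labels.reindex(expr.index)
        d, nd = expr[lab == "D"], expr[lab == "ND"]
        if len(d) and len(nd):
            r = mann_whitney(d, nd)
            comparisons[f"expression_{gene}_D_vs_ND"] = {"U": r.statistic, "p": r.p_two_sided}
    with open(os.path.join(out_dir, "comparisons.json"), "w") as fh:
        json.dump(comparisons, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["comparisons.json"] = os.path.join(out_dir, "comparisons.json")

    manifest = {
        "seed": config.seed,
        "config": _config_dict(config),
        "artifacts": {name: _sha256(path) for name, path in sorted(paths.items())},
        "n_samples": int(len(truth.sample_ids)),
        "n_rarefied": int(len(rare.data)),
        "rarefaction_depth": depth,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _subset_dist(dist: pdv.DistanceMatrix, ids: list[str]) -> pdv.DistanceMatrix:
    pos = [dist.ids.index(s) for s in ids]
    return pdv.DistanceMatrix(ids, dist.data[np.ix_(pos, pos)])


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"]["n_samples_per_group"] = dict(config.sim.n_samples_per_group)
    d["sim"]["dysbiosis_fraction"] = dict(config.sim.dysbiosis_fraction)
    d["sim"]["ahl_spec"]["n_samples"] = dict(config.sim.ahl_spec.n_samples)
    return d
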