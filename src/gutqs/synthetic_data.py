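"""Synthetic gut-multi-omics data with known ground truth.

Generates every input the analysis pipeline consumes, with planted
effects so each downstream stage can be validated against truth:

* per-sample species relative-abundance profiles (MetaPhlAn-style TSV)
  over three phenotype groups (non-IBD, CD, UC), with a configurable
  fraction of dysbiotic samples in which marker species are enriched
  or depleted by known fold changes;
* paired metagenome (MGX) / metatranscriptome (MTX) per-gene hit
  counts with planted expression fold changes in dysbiotic samples;
* outfmt-6-style BLAST hit tables whose post-filter unique-read counts
  equal the planted hit counts (decoy rows placed strictly outside the
  per-gene cut-offs);
* MRM peak tables containing true AHL transition triplets (neutral
  loss, lactone fragment, precursor trace, co-eluting) plus decoys
  that always violate the identification rule, and an internal
  standard in every sample.

The generative model is deliberately simple: log-normal baseline
species abundances (realistic rank-abundance curves) with log-normal
within-sample noise, closure to relative abundances, multinomial read
sampling; Poisson counts for gene reads at shallow coverage. A single
global seed fans out to per-stream, per-sample substreams, so adding
samples never perturbs earlier ones, and identical (seed, config)
yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles_diversity import TaxonomicProfile
from .qs_quant import GeneQuery, BlastHitTable, derive_gene_metrics
from .ahl_mrm import IstdSpec, NEUTRAL_LOSS_DA, LACTONE_MZ

PHENOTYPES = ["non-IBD", "CD", "UC"]

# substream tags
_S_GLOBAL, _S_COMMUNITY, _S_GENES, _S_MRM, _S_BLAST = 0, 1, 2, 3, 4

__all__ = [
    "MarkerSpec",
    "GeneSpec",
    "AhlSpec",
    "SimConfig",
    "SimTruth",
    "simulate_community",
    "simulate_gene_hits",
    "emit_blast_tab",
    "simulate_mrm",
    "write_profiles_tsv",
    "write_metadata_tsv",
    "write_truth_json",
    "write_peak_table_tsv",
]


@dataclass(frozen=True)
class MarkerSpec:
    species: str
    fold_change: float
    direction: str  # "dysbiosis-enriched" | "dysbiosis-depleted"


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    baseline_abundance: float  # expected fraction of reads hitting the gene
    expression_fold: float  # MTX fold change in dysbiotic samples


# default [M+H]+ m/z values for common AHLs (C4 ... C16:1, 3-oxo forms)
DEFAULT_AHL_MZ = (
    172.10, 200.13, 214.11, 228.16, 242.14, 256.19, 270.17,
    284.22, 294.17, 298.20, 312.25, 326.23, 338.27,
)


@dataclass(frozen=True)
class AhlSpec:
    true_mz: tuple[float, ...] = DEFAULT_AHL_MZ
    ibd_subset_size: int = 7
    decoy_count: int = 6
    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"non-IBD": 10, "IBD": 2}
    )
    presence_prob: float = 0.75
    rt_range: tuple[float, float] = (2.0, 12.0)
    mz_jitter: float = 0.05
    rt_jitter: float = 0.02
    rt_tol: float = 0.1  # generator-matched calling tolerance
    area_scale: float = 1e5
    istd: IstdSpec = field(default_factory=IstdSpec)

    @property
    def decoy_mz(self) -> tuple[float, ...]:
        return tuple(round(m + 3.7, 2) for m in self.true_mz[: self.decoy_count])


def _default_markers() -> tuple[MarkerSpec, ...]:
    # depletion-dominated panel: three mid-abundance commensals lost, one
    # bloom. The enriched fold is set so the mass gained by the bloom
    # offsets the mass lost by the depleted markers (mass-balanced
    # dysbiosis): closure then leaves non-marker species exchangeable
    # between groups instead of imprinting a spurious global shift.
    return (
        MarkerSpec("Species_0015", 10.0, "dysbiosis-depleted"),
        MarkerSpec("Species_0022", 12.0, "dysbiosis-depleted"),
        MarkerSpec("Species_0030", 15.0, "dysbiosis-depleted"),
        MarkerSpec("Species_0040", 9.1, "dysbiosis-enriched"),
    )


def diversity_contrast_markers() -> tuple[MarkerSpec, ...]:
    """Marker panel with strong community-level impact: three dominant
    commensals depleted plus one dominant bloom, so dysbiotic samples
    have visibly lower Shannon diversity and observed-species counts."""
    return (
        MarkerSpec("Species_0003", 10.0, "dysbiosis-depleted"),
        MarkerSpec("Species_0004", 15.0, "dysbiosis-enriched"),
        MarkerSpec("Species_0005", 10.0, "dysbiosis-depleted"),
        MarkerSpec("Species_0008", 10.0, "dysbiosis-depleted"),
    )


def _default_genes() -> tuple[GeneSpec, ...]:
    return (
        GeneSpec("luxR1_Bfragilis", 1.2e-4, 1.0),
        GeneSpec("luxR2_Bfragilis", 8.0e-5, 1.0),
        GeneSpec("luxR3_Bfragilis", 6.0e-5, 1.0),
        GeneSpec("luxR4_Bfragilis", 1.0e-4, 3.0),
        GeneSpec("luxR1_Bdorei", 1.5e-4, 1.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation settings.

    Defaults mirror the analysed cohort: 26 non-IBD / 50 CD / 27 UC
    samples, dysbiosis fractions matching the observed per-phenotype
    dysbiotic counts (4/26, 24/50, 17/27), 200 species and four marker
    species with fold changes 8-15.
    """

    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"non-IBD": 26, "CD": 50, "UC": 27}
    )
    n_species: int = 200
    marker_spec: tuple[MarkerSpec, ...] = field(default_factory=_default_markers)
    dysbiosis_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"non-IBD": 4 / 26, "CD": 24 / 50, "UC": 17 / 27}
    )
    reads_mean: int = 4_000_000
    reads_sigma: float = 0.25  # log-normal dispersion of total reads
    abundance_sigma: float = 3.5  # between-species log-normal spread
    within_sigma: float = 0.002  # within-group per-sample log-normal noise
    # baseline community share of each marker species (aligned with
    # marker_spec); None lets markers keep their random log-normal draw
    marker_shares: tuple[float, ...] | None = (0.0045, 0.0028, 0.0016, 0.0010)
    gene_spec: tuple[GeneSpec, ...] = field(default_factory=_default_genes)
    gene_jitter_sigma: float = 0.5
    ahl_spec: AhlSpec = field(default_factory=AhlSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_samples_per_group.items():
            if n < 1:
                raise ValueError(f"group {g}: need >= 1 sample")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_species < len(self.marker_spec):
            raise ValueError("n_species smaller than number of marker species")
        known = {f"Species_{i + 1:04d}" for i in range(self.n_species)}
        for m in self.marker_spec:
            if m.fold_change <= 0:
                raise ValueError("marker fold changes must be > 0")
            if m.direction not in ("dysbiosis-enriched", "dysbiosis-depleted"):
                raise ValueError(f"bad marker direction {m.direction!r}")
            if m.species not in known:
                raise ValueError(f"marker species {m.species} outside the simulated pool")
        for g, p in self.dysbiosis_fraction.items():
            if not 0 <= p <= 1:
                raise ValueError(f"dysbiosis fraction for {g} outside [0, 1]")
        for gs in self.gene_spec:
            if gs.expression_fold <= 0:
                raise ValueError("gene expression folds must be > 0")
            if gs.baseline_abundance < 0:
                raise ValueError("gene baseline abundance must be >= 0")
        if self.reads_mean < 1:
            raise ValueError("reads_mean must be >= 1")
        if self.marker_shares is not None:
            if len(self.marker_shares) != len(self.marker_spec):
                raise ValueError("marker_shares must align with marker_spec")
            if sum(self.marker_shares) >= 1 or any(s <= 0 for s in self.marker_shares):
                raise ValueError("marker shares must be positive and sum below 1")


@dataclass
class SimTruth:
    """Ground truth for one simulated cohort."""

    metadata: pd.DataFrame  # sample_id, phenotype, activity_score, total_reads
    dysbiosis: dict[str, bool]
    species_fold: dict[str, tuple[float, str]]
    gene_fold: dict[str, float]
    true_ahls: list[float]
    lineages: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata["sample_id"])


def _rng(config_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, *key])


_PHYLA = ["Bacteroidetes", "Firmicutes", "Proteobacteria", "Actinobacteria", "Verrucomicrobia"]
_PHYLUM_W = [0.35, 0.45, 0.10, 0.05, 0.05]


def simulate_community(config: SimConfig) -> tuple[list[TaxonomicProfile], SimTruth]:
    """Simulate the cohort's taxonomic profiles and ground-truth labels.

    Species are named ``Species_0001`` ... in decreasing order of their
    baseline mean abundance, so marker ids index the rank-abundance
    curve directly.
    """
    g = _rng(config.seed, _S_GLOBAL)
    base = np.sort(g.lognormal(0.0, config.abundance_sigma, config.n_species))[::-1]
    species = [f"Species_{i + 1:04d}" for i in range(config.n_species)]
    if config.marker_shares is not None:
        # plant marker species at fixed community shares: their baseline
        # (hence the mass their fold changes move) is exact, not a draw
        midx = [species.index(m.species) for m in config.marker_spec]
        non_marker_sum = base.sum() - base[midx].sum()
        t = sum(config.marker_shares)
        for i, s in zip(midx, config.marker_shares):
            base[i] = s * non_marker_sum / (1.0 - t)
    phylum = g.choice(_PHYLA, size=config.n_species, p=_PHYLUM_W)
    lineages = {
        sp: (
            f"k__Bacteria|p__{ph}|c__{ph}ia|o__{ph}ales|"
            f"f__{ph}aceae|g__Genus_{i + 1:04d}|s__{sp}"
        )
        for i, (sp, ph) in enumerate(zip(species, phylum))
    }
    marker_idx = {m.species: species.index(m.species) for m in config.marker_spec}

    profiles: list[TaxonomicProfile] = []
    meta_rows = []
    dysbiosis: dict[str, bool] = {}
    for gi, pheno in enumerate(PHENOTYPES):
        n = int(config.n_samples_per_group.get(pheno, 0))
        frac = float(config.dysbiosis_fraction.get(pheno, 0.0))
        for i in range(n):
            rng = _rng(config.seed, _S_COMMUNITY, gi, i)
            sid = f"{pheno.replace('-', '')}{i + 1:03d}"
            dys = bool(rng.uniform() < frac)
            abund = base * rng.lognormal(0.0, config.within_sigma, config.n_species)
            if dys:
                for m in config.marker_spec:
                    f = m.fold_change if m.direction == "dysbiosis-enriched" else 1.0 / m.fold_change
                    abund[marker_idx[m.species]] *= f
            p = abund / abund.sum()
            total = max(1, int(round(rng.lognormal(np.log(config.reads_mean), config.reads_sigma))))
            counts = rng.multinomial(total, p)
            pct = counts / total * 100.0
            sp_table = {sp: float(v) for sp, v in zip(species, pct)}
            ph_table: dict[str, float] = {}
            for sp, v in zip(species, pct):
                ph = lineages[sp].split("|")[1][3:]
                ph_table[ph] = ph_table.get(ph, 0.0) + float(v)
            profiles.append(
                TaxonomicProfile(
                    sid,
                    {"k": {"Bacteria": 100.0}, "p": ph_table, "s": sp_table},
                    total_reads=total,
                )
            )
            dysbiosis[sid] = dys
            if pheno == "CD":
                score = float(rng.poisson(2.0)) if rng.uniform() > 0.05 else np.nan
            elif pheno == "UC":
                score = float(rng.poisson(1.5)) if rng.uniform() > 0.05 else np.nan
            else:
                score = np.nan
            meta_rows.append(
                {"sample_id": sid, "phenotype": pheno, "activity_score": score,
                 "total_reads": total}
            )

    truth = SimTruth(
        metadata=pd.DataFrame(meta_rows),
        dysbiosis=dysbiosis,
        species_fold={m.species: (m.fold_change, m.direction) for m in config.marker_spec},
        gene_fold={gs.gene_id: gs.expression_fold for gs in config.gene_spec},
        true_ahls=list(config.ahl_spec.true_mz),
        lineages=lineages,
    )
    return profiles, truth


def simulate_gene_hits(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Paired MGX/MTX per-gene hit counts with planted expression folds.

    MGX hits ~ Poisson(total * abundance); MTX hits ~ Poisson(total *
    abundance * fold) in dysbiotic samples. A shared per-sample
    log-normal jitter on the gene's abundance cancels in the
    expression ratio.
    """
    records = []
    for i, sid in enumerate(truth.sample_ids):
        rng = _rng(config.seed, _S_GENES, i)
        mgx_total = int(round(rng.lognormal(np.log(config.reads_mean), config.reads_sigma)))
        mtx_total = int(round(rng.lognormal(np.log(config.reads_mean), config.reads_sigma)))
        dys = truth.dysbiosis[sid]
        for gs in config.gene_spec:
            a = gs.baseline_abundance * rng.lognormal(0.0, config.gene_jitter_sigma)
            fold = gs.expression_fold if dys else 1.0
            mgx = int(rng.poisson(mgx_total * a))
            mtx = int(rng.poisson(mtx_total * a * fold))
            records.append(
                {
                    "sample_id": sid,
                    "gene_id": gs.gene_id,
                    "mgx_hit_reads": mgx,
                    "mgx_total_reads": mgx_total,
                    "mtx_hit_reads": mtx,
                    "mtx_total_reads": mtx_total,
                }
            )
    return derive_gene_metrics(pd.DataFrame(records))


def emit_blast_tab(
    hit_table: pd.DataFrame,
    queries: Sequence[GeneQuery],
    decoy_rate: float = 0.0,
    seed: int = 0,
    hsp_dup_prob: float = 0.1,
) -> dict[tuple[str, str], BlastHitTable]:
    """Emit outfmt-6-style hit tables matching a per-gene hit table.

    For every (sample, sequencing type) a table is produced in which
    the number of unique read ids surviving the per-gene cut-offs
    equals the planted hit count. True hits are drawn strictly inside
    the cut-offs (identity at least 1 point above any floor, e-value at
    least a factor 10 below the ceiling); decoys strictly outside.
    Some true reads carry a second HSP row to exercise deduplication.
    """
    by_gene = {q.gene_id: q for q in queries}
    out: dict[tuple[str, str], list[list]] = {}
    for r, row in enumerate(hit_table.itertuples()):
        q = by_gene[row.gene_id]
        for st, n_true in (("MGX", row.mgx_hit_reads), ("MTX", row.mtx_hit_reads)):
            rng = _rng(seed, _S_BLAST, r, 0 if st == "MGX" else 1)
            rows = out.setdefault((row.sample_id, st), [])
            floor = q.min_pident
            for k in range(int(n_true)):
                rid = f"{row.sample_id}_{st}_{row.gene_id}_r{k}"
                if floor is not None:
                    pid = rng.uniform(floor + 1.0, min(floor + 20.0, 100.0))
                else:
                    pid = rng.uniform(70.0, 100.0)
                ev = q.evalue_max * 10.0 ** (-rng.uniform(1.0, 8.0))
                n_hsp = 2 if rng.uniform() < hsp_dup_prob else 1
                for h in range(n_hsp):
                    rows.append(_hit_row(rng, row.gene_id, rid, pid, ev))
            n_decoy = int(rng.poisson(decoy_rate * max(int(n_true), 1))) if decoy_rate > 0 else 0
            for k in range(n_decoy):
                rid = f"{row.sample_id}_{st}_{row.gene_id}_d{k}"
                if floor is not None and rng.uniform() < 0.5:
                    pid = rng.uniform(max(floor - 15.0, 0.0), floor - 1.0)
                    ev = q.evalue_max * 10.0 ** (-rng.uniform(1.0, 8.0))
                else:
                    pid = rng.uniform(70.0, 100.0) if floor is None else rng.uniform(floor + 1.0, 100.0)
                    ev = q.evalue_max * 10.0 ** rng.uniform(1.0, 3.0)
                rows.append(_hit_row(rng, row.gene_id, rid, pid, ev))
    return {
        key: BlastHitTable(
            pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident", "length", "mismatch",
                                        "gapopen", "qstart", "qend", "sstart", "send",
                                        "evalue", "bitscore"]),
            sample_id=key[0],
            sequencing_type=key[1],
        )
        for key, rows in out.items()
    }


def _hit_row(rng: np.random.Generator, gene: str, rid: str, pident: float, evalue: float) -> list:
    length = int(rng.integers(80, 151))
    mismatch = int(round(length * (100.0 - pident) / 100.0))
    sstart = int(rng.integers(1, 1000))
    return [gene, rid, round(float(pident), 3), length, mismatch, 0, 1, length,
            sstart, sstart + length - 1, float(f"{evalue:.3e}"), round(float(rng.uniform(60, 200)), 1)]


def simulate_mrm(config: SimConfig) -> tuple[dict[str, pd.DataFrame], dict[str, frozenset]]:
    """MRM peak tables for a small AHL-profiling cohort.

    Non-IBD samples draw from the full true-AHL repertoire, IBD samples
    from a fixed subset (first ``ibd_subset_size`` entries); the first
    sample of each group carries its complete repertoire so group
    richness equals the planted structure. Decoys always violate the
    identification rule: one product transition missing, or both
    present but separated by three times the retention tolerance. The
    internal standard is present in every sample. Returns the peak
    tables and the per-sample set of truly present AHL precursors.
    """
    spec = config.ahl_spec
    g = _rng(config.seed, _S_MRM, 0)
    char_rt = {
        m: g.uniform(*spec.rt_range) for m in list(spec.true_mz) + list(spec.decoy_mz)
    }
    repertoire = {
        "non-IBD": list(spec.true_mz),
        "IBD": list(spec.true_mz[: spec.ibd_subset_size]),
    }
    tables: dict[str, pd.DataFrame] = {}
    truths: dict[str, frozenset] = {}
    for gi, (group, n) in enumerate(sorted(spec.n_samples.items())):
        for i in range(n):
            rng = _rng(config.seed, _S_MRM, 1 + gi, i)
            sid = f"{group.replace('-', '')}-M{i + 1:02d}"
            rows = []
            present = []
            for m in repertoire[group]:
                if i > 0 and rng.uniform() > spec.presence_prob:
                    continue
                present.append(m)
                rows.extend(_ahl_peaks(rng, m, char_rt[m], spec))
            for k, dm in enumerate(spec.decoy_mz):
                if rng.uniform() > spec.presence_prob:
                    continue
                rows.extend(_decoy_peaks(rng, dm, char_rt[dm], spec, mode=k % 3))
            area = rng.lognormal(np.log(spec.area_scale), 0.2)
            rows.append(
                [spec.istd.precursor_mz, spec.istd.product_mz,
                 round(float(rng.uniform(*spec.rt_range)), 3), round(float(area), 2)]
            )
            tables[sid] = pd.DataFrame(rows, columns=["precursor_mz", "product_mz", "rt_min", "area"])
            truths[sid] = frozenset(present)
    return tables, truths


def _jit(rng: np.random.Generator, tol: float) -> float:
    return float(rng.uniform(-0.3 * tol, 0.3 * tol))


def _ahl_peaks(rng, m, rt, spec: AhlSpec) -> list[list]:
    area = rng.lognormal(np.log(spec.area_scale), 0.5)
    mj, rj = spec.mz_jitter, spec.rt_jitter
    rows = []
    for prod, factor in ((m - NEUTRAL_LOSS_DA, 1.0), (LACTONE_MZ, 0.6), (m, 1.5)):
        rows.append(
            [round(m + _jit(rng, mj), 4), round(prod + _jit(rng, mj), 4),
             round(rt + _jit(rng, rj), 3), round(float(area * factor), 2)]
        )
    return rows


def _decoy_peaks(rng, m, rt, spec: AhlSpec, mode: int) -> list[list]:
    area = rng.lognormal(np.log(spec.area_scale), 0.5)
    mj, rj = spec.mz_jitter, spec.rt_jitter
    rows = [[round(m + _jit(rng, mj), 4), round(m + _jit(rng, mj), 4),
             round(rt + _jit(rng, rj), 3), round(float(area * 1.5), 2)]]
    if mode == 0:  # lactone only, neutral-loss product missing
        rows.append([round(m + _jit(rng, mj), 4), round(LACTONE_MZ + _jit(rng, mj), 4),
                     round(rt + _jit(rng, rj), 3), round(float(area * 0.6), 2)])
    elif mode == 1:  # neutral loss only, lactone missing
        rows.append([round(m + _jit(rng, mj), 4), round(m - NEUTRAL_LOSS_DA + _jit(rng, mj), 4),
                     round(rt + _jit(rng, rj), 3), round(float(area), 2)])
    else:  # both products, but not co-eluting
        rows.append([round(m + _jit(rng, mj), 4), round(m - NEUTRAL_LOSS_DA + _jit(rng, mj), 4),
                     round(rt + _jit(rng, rj), 3), round(float(area), 2)])
        rows.append([round(m + _jit(rng, mj), 4), round(LACTONE_MZ + _jit(rng, mj), 4),
                     round(rt + 3.0 * spec.rt_tol + _jit(rng, rj), 3), round(float(area * 0.6), 2)])
    return rows


# ---------------------------------------------------------------------------
# Writers (plain-text external interfaces)
# ---------------------------------------------------------------------------

def write_profiles_tsv(profiles: Sequence[TaxonomicProfile], lineages: Mapping[str, str],
                       path: str) -> None:
    """MetaPhlAn-style TSV: lineage rows x sample columns, percent values."""
    sample_ids = [p.sample_id for p in profiles]
    lines = ["clade_name\t" + "\t".join(sample_ids)]
    # kingdom and phylum rows, then species rows
    lines.append("k__Bacteria\t" + "\t".join("100.0" for _ in profiles))
    phyla = sorted({ln.split("|")[1][3:] for ln in lineages.values()})
    for ph in phyla:
        vals = [p.rank_tables.get("p", {}).get(ph, 0.0) for p in profiles]
        lines.append(f"k__Bacteria|p__{ph}\t" + "\t".join(f"{v:.10g}" for v in vals))
    for sp in sorted(lineages):
        vals = [p.rank_tables.get("s", {}).get(sp, 0.0) for p in profiles]
        lines.append(lineages[sp] + "\t" + "\t".join(f"{v:.10g}" for v in vals))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_metadata_tsv(truth: SimTruth, path: str) -> None:
    truth.metadata.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_truth_json(truth: SimTruth, path: str) -> None:
    obj = {
        "dysbiosis": {k: bool(v) for k, v in sorted(truth.dysbiosis.items())},
        "species_fold": {k: list(v) for k, v in sorted(truth.species_fold.items())},
        "gene_fold": dict(sorted(truth.gene_fold.items())),
        "true_ahls": truth.true_ahls,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_peak_table_tsv(tables: Mapping[str, pd.DataFrame], path: str) -> None:
    frames = []
    for sid, df in sorted(tables.items()):
        d = df.copy()
        d.insert(0, "sample_id", sid)
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.10g")
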