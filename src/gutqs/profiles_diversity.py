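"""Taxonomic-profile parsing, rarefaction, and community diversity.

Profiles are MetaPhlAn-style tables: one row per lineage string
(``k__...|p__...|...|s__Species``), one column per sample, values in
percent of the community. Downstream analysis converts species-level
relative abundances to approximate read counts, rarefies all samples
to a common depth, and measures alpha diversity (observed species,
Shannon index) and beta diversity (Bray-Curtis dissimilarity, PCoA,
one-way PERMANOVA).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANK_ORDER = ["k", "p", "c", "o", "f", "g", "s"]

__all__ = [
    "TaxonomicProfile",
    "CountTable",
    "DistanceMatrix",
    "PcoaResult",
    "PermanovaResult",
    "parse_taxonomic_profiles",
    "species_table",
    "scale_to_counts",
    "build_count_table",
    "rarefy",
    "observed_species",
    "shannon",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "permanova",
]


@dataclass
class TaxonomicProfile:
    """Per-sample relative abundances, split by taxonomic rank.

    ``rank_tables`` maps a rank prefix (``"k"``, ``"p"``, ..., ``"s"``)
    to ``{taxon name: percent}``. ``total_reads`` is the sample's total
    sequencing depth; it is required to approximate absolute counts.
    """

    sample_id: str
    rank_tables: dict[str, dict[str, float]]
    total_reads: int | None = None

    def species(self) -> dict[str, float]:
        return dict(self.rank_tables.get("s", {}))


@dataclass
class CountTable:
    """Samples x species matrix of (approximate or rarefied) read counts."""

    data: pd.DataFrame  # integer counts, index = sample ids
    provenance: str = "raw-scaled"  # or "rarefied"
    depth: int | None = None


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.data, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        self.data = m


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    explained: np.ndarray  # fraction of positive-eigenvalue mass per axis
    negative_eigenvalues: np.ndarray


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    group_sizes: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _split_lineage(lineage: str) -> list[tuple[str, str]]:
    """Split ``k__A|p__B`` into [("k", "A"), ("p", "B")]."""
    parts = []
    for token in lineage.split("|"):
        if len(token) < 3 or token[1:3] != "__":
            raise ValueError(f"unparseable lineage token {token!r}")
        rank, name = token[0], token[3:]
        if rank not in RANK_ORDER:
            raise ValueError(f"unknown rank prefix {token!r}")
        parts.append((rank, name))
    return parts


def parse_taxonomic_profiles(
    source: str | io.TextIOBase,
    totals: Mapping[str, int] | pd.DataFrame | None = None,
) -> list[TaxonomicProfile]:
    """Parse a MetaPhlAn-style profile TSV into per-sample profiles.

    Each lineage row is assigned to its deepest rank. ``totals`` maps
    sample id to total read count (or is a metadata frame with
    ``sample_id``/``total_reads`` columns).

    Raises on duplicated sample columns, unparseable lineages and
    negative abundances.
    """
    if isinstance(totals, pd.DataFrame):
        totals = dict(zip(totals["sample_id"], totals["total_reads"]))

    buf = open(source) if isinstance(source, str) else source
    try:
        header = buf.readline()
        if not header.strip():
            return []
        columns = header.rstrip("\n").split("\t")
        sample_ids = columns[1:]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValueError(f"duplicated sample column(s): {dupes}")
        tables: dict[str, dict[str, dict[str, float]]] = {
            s: {} for s in sample_ids
        }
        for lineno, line in enumerate(buf, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(columns):
                raise ValueError(
                    f"line {lineno}: expected {len(columns)} fields, got {len(fields)}"
                )
            try:
                parts = _split_lineage(fields[0])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            rank, name = parts[-1]
            for sid, value in zip(sample_ids, fields[1:]):
                v = float(value)
                if v < 0:
                    raise ValueError(
                        f"line {lineno}: negative abundance {v} for sample {sid}"
                    )
                tables[sid].setdefault(rank, {})[name] = v
    finally:
        if isinstance(source, str):
            buf.close()

    profiles = []
    for sid in sample_ids:
        total = None if totals is None else int(totals.get(sid)) if sid in totals else None
        profiles.append(TaxonomicProfile(sid, tables[sid], total))
    return profiles


def species_table(profiles: Iterable[TaxonomicProfile]) -> pd.DataFrame:
    """Samples x species relative-abundance (percent) matrix."""
    rows = {p.sample_id: p.species() for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index(axis=1)


# ---------------------------------------------------------------------------
# Counts and rarefaction
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def scale_to_counts(profile: TaxonomicProfile, rank: str = "s") -> pd.Series:
    """Approximate absolute species counts: percent/100 x total reads.

    Rounding is half-away-from-zero.
    """
    if profile.total_reads is None:
        raise ValueError(f"sample {profile.sample_id}: total_reads unknown")
    rel = pd.Series(profile.rank_tables.get(rank, {}), dtype=float)
    counts = _round_half_away(rel.to_numpy() / 100.0 * profile.total_reads)
    return pd.Series(counts.astype(np.int64), index=rel.index, name=profile.sample_id)


def build_count_table(profiles: Iterable[TaxonomicProfile]) -> CountTable:
    rows = [scale_to_counts(p) for p in profiles]
    data = pd.DataFrame(rows).fillna(0).astype(np.int64).sort_index(axis=1)
    return CountTable(data, provenance="raw-scaled")


def rarefy(
    counts: CountTable,
    depth: int = 50_000,
    seed: int | np.random.Generator | None = None,
) -> CountTable:
    """Subsample every sample without replacement to ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a
    logged warning. Uses the multivariate hypergeometric distribution,
    which is exactly uniform subsampling without replacement.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kept_rows = {}
    for sid, row in counts.data.iterrows():
        total = int(row.sum())
        if total < depth:
            logger.warning(
                "dropping sample %s: %d reads < rarefaction depth %d", sid, total, depth
            )
            continue
        if total == depth:
            kept_rows[sid] = row.to_numpy(dtype=np.int64)
        else:
            kept_rows[sid] = rng.multivariate_hypergeometric(
                row.to_numpy(dtype=np.int64), depth
            )
    data = pd.DataFrame.from_dict(kept_rows, orient="columns").T
    if not kept_rows:
        data = pd.DataFrame(columns=counts.data.columns)
    else:
        data.columns = counts.data.columns
    return CountTable(data.astype(np.int64), provenance="rarefied", depth=depth)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def observed_species(row: Sequence[float]) -> int:
    r = np.asarray(row, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative counts")
    if r.sum() == 0:
        raise ValueError("all-zero row")
    return int(np.count_nonzero(r))


def shannon(row: Sequence[float], log_base: float = 2.0) -> float:
    """Shannon entropy H = -sum p_i log_b p_i over species with p_i > 0."""
    r = np.asarray(row, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative counts")
    total = r.sum()
    if total == 0:
        raise ValueError("all-zero row")
    p = r[r > 0] / total
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


def alpha_diversity_table(counts: CountTable, log_base: float = 2.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "observed": [observed_species(row) for _, row in counts.data.iterrows()],
            "shannon": [shannon(row, log_base) for _, row in counts.data.iterrows()],
        },
        index=counts.data.index,
    )


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """BC = 1 - 2 sum(min(x_i, y_i)) / sum(x_i + y_i)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    denom = (xv + yv).sum()
    if denom == 0:
        raise ValueError("both rows are all-zero")
    return float(1.0 - 2.0 * np.minimum(xv, yv).sum() / denom)


def bray_curtis_matrix(counts: CountTable | pd.DataFrame) -> DistanceMatrix:
    data = counts.data if isinstance(counts, CountTable) else counts
    m = data.to_numpy(dtype=float)
    n = m.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(m[i], m[j])
    return DistanceMatrix(list(data.index), out)


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinates via Gower double-centering + eigendecomposition.

    Axes are ordered by decreasing eigenvalue; negative eigenvalues are
    reported but excluded from the explained-fraction denominator.
    """
    d2 = dist.data ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    coordinates = pd.DataFrame(
        coords,
        index=dist.ids,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    explained = lam / lam.sum() if lam.size else lam
    return PcoaResult(coordinates, lam, explained, eigvals[eigvals < 0])


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    sst = d2.sum() / (2.0 * n)
    ssw = 0.0
    for g in range(n_groups):
        idx = codes == g
        ng = int(idx.sum())
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * ng)
    return sst, ssw


def permanova(
    dist: DistanceMatrix,
    labels: Sequence[str],
    n_permutations: int = 9_999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with a permutation p-value.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations), so the
    observed labelling counts as one permutation and p is never zero.
    """
    labels = np.asarray(labels)
    if len(labels) != len(dist.ids):
        raise ValueError("labels length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError("every group needs at least two samples")
    n, a = len(labels), len(uniq)
    d2 = dist.data ** 2

    def f_stat(c: np.ndarray) -> float:
        sst, ssw = _permanova_ss(d2, c, a)
        ssa = sst - ssw
        return (ssa / (a - 1)) / (ssw / (n - a))

    f_obs = f_stat(codes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if f_stat(rng.permutation(codes)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed if isinstance(seed, int) else None,
        group_sizes={str(u): int(s) for u, s in zip(uniq, sizes)},
    )
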