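"""Count-table statistics for the amplicon part of the experiment.

Operates on ASV count tables (samples x features) with taxonomy and sample
metadata: rarefaction to even depth, alpha diversity (observed richness and
Shannon index in nats), Bray-Curtis dissimilarity on relative abundances,
DNA-vs-RNA community divergence per condition, qPCR transcript-to-gene
activity ratios, taxonomic aggregation with unclassified-rank fallback
labels, row z-scoring for heatmaps, and thresholded Pearson co-occurrence
networks (edges kept at |r| above a threshold and p below alpha, with no
multiple-testing correction by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis

RANKS = ("phylum", "class", "order", "family", "genus")
RANK_PREFIX = {"phylum": "p", "class": "c", "order": "o", "family": "f", "genus": "g"}


@dataclass
class CountTable:
    """Samples x features integer counts with taxonomy and sample metadata."""

    counts: pd.DataFrame  # samples x features, nonnegative integers
    taxonomy: pd.DataFrame  # features x ranks (subset of RANKS), NaN = unassigned
    sample_meta: pd.DataFrame  # samples x {fraction, ammonium, modality, replicate}

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("sample ids must be unique")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        missing = self.counts.columns.difference(self.taxonomy.index)
        if len(missing):
            raise ValueError(f"features without taxonomy: {list(missing)[:5]}")
        tax = self.taxonomy.loc[self.counts.columns]
        if tax.isna().all(axis=1).any():
            bad = tax.index[tax.isna().all(axis=1)][:5]
            raise ValueError(f"features with no assigned rank at all: {list(bad)}")

    def select_samples(self, mask: pd.Series) -> "CountTable":
        samples = self.counts.index[mask.reindex(self.counts.index, fill_value=False)]
        return CountTable(
            counts=self.counts.loc[samples],
            taxonomy=self.taxonomy,
            sample_meta=self.sample_meta.loc[samples],
        )


@dataclass(frozen=True)
class QpcrAbundance:
    """16S copies per gram of sludge for one sample (DNA and cDNA assays)."""

    sample: str
    gene_copies: float
    transcript_copies: float

    def __post_init__(self) -> None:
        if self.gene_copies < 0 or self.transcript_copies < 0:
            raise ValueError("copy numbers must be >= 0")


@dataclass(frozen=True)
class NetworkEdge:
    family_a: str
    family_b: str
    r: float
    p: float
    sign: str  # "positive" | "negative"


@dataclass
class NetworkResult:
    edges: list[NetworkEdge]
    graph: nx.Graph
    degrees: dict[str, int]
    components: list[set[str]]

    @property
    def hubs(self) -> list[tuple[str, int]]:
        return sorted(self.degrees.items(), key=lambda kv: (-kv[1], kv[0]))


def rarefy(table: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Exact multivariate-hypergeometric subsampling; deterministic given the
    seed (recorded by callers for reproducibility).  Features that end up
    all-zero are dropped.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    totals = table.counts.sum(axis=1)
    shallow = totals[totals < depth]
    if len(shallow):
        raise ValueError(
            f"sample {shallow.index[0]!r} has only {int(shallow.iloc[0])} counts, "
            f"below the requested depth {depth}"
        )
    rng = np.random.default_rng(seed)
    rarefied = pd.DataFrame(
        [
            rng.multivariate_hypergeometric(row.to_numpy(), depth)
            for _, row in table.counts.iterrows()
        ],
        index=table.counts.index,
        columns=table.counts.columns,
        dtype=np.int64,
    )
    keep = rarefied.columns[rarefied.sum(axis=0) > 0]
    return CountTable(
        counts=rarefied[keep],
        taxonomy=table.taxonomy.loc[keep],
        sample_meta=table.sample_meta,
    )


def alpha_diversity(profile) -> tuple[int, float]:
    """(observed richness, Shannon index in nats) of one sample's counts."""
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero profile has no diversity")
    richness = int(np.count_nonzero(x))
    p = x[x > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    return richness, shannon


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity of two profiles on relative abundances."""
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if not a.index.equals(b.index):
            raise ValueError("profiles must share the same feature space")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share the same feature space")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("profiles must have positive totals")
    return float(braycurtis(a / a.sum(), b / b.sum()))


def dna_rna_divergence(
    table: CountTable, condition_keys: tuple[str, ...] = ("modality", "ammonium")
) -> tuple[pd.DataFrame, dict]:
    """Mean DNA-vs-RNA Bray-Curtis divergence per condition, plus its trend.

    For every condition (default: modality x ammonium level) the divergence
    is the mean Bray-Curtis dissimilarity over all DNA x RNA sample pairs.
    The returned trend is the OLS line of divergence vs ammonium.
    """
    meta = table.sample_meta
    rows = []
    for keys, group in meta.groupby(list(condition_keys)):
        dna = group.index[group["fraction"] == "DNA"]
        rna = group.index[group["fraction"] == "RNA"]
        if len(dna) == 0 or len(rna) == 0:
            warnings.warn(f"condition {keys}: missing DNA or RNA samples, skipped", stacklevel=2)
            continue
        pairs = [
            bray_curtis(table.counts.loc[d], table.counts.loc[r])
            for d in dna
            for r in rna
        ]
        row = dict(zip(condition_keys, keys if isinstance(keys, tuple) else (keys,)))
        row["divergence"] = float(np.mean(pairs))
        row["n_pairs"] = len(pairs)
        rows.append(row)
    result = pd.DataFrame(rows)
    trend: dict = {}
    if len(result) >= 2 and "ammonium" in result:
        slope, intercept = np.polyfit(result["ammonium"], result["divergence"], 1)
        r = np.corrcoef(result["ammonium"], result["divergence"])[0, 1]
        trend = {"slope": float(slope), "intercept": float(intercept), "r_squared": float(r**2)}
    return result, trend


def activity_ratio(q: QpcrAbundance) -> float:
    """Transcript-to-gene copy ratio (cDNA/DNA), a proxy for activity."""
    if q.gene_copies <= 0:
        raise ValueError(f"sample {q.sample}: gene copies must be > 0")
    return q.transcript_copies / q.gene_copies


def _fallback_label(tax_row: pd.Series, rank: str) -> str:
    if rank in tax_row and pd.notna(tax_row[rank]):
        return str(tax_row[rank])
    # walk towards phylum; prefix with the level code of the rank found
    start = RANKS.index(rank) - 1
    for r in RANKS[start::-1]:
        if r in tax_row and pd.notna(tax_row[r]):
            return f"{RANK_PREFIX[r]}_{tax_row[r]}"
    raise ValueError("feature has no assigned rank at all")


def aggregate_taxa(table: CountTable, rank: str = "genus", top_k: int = 50) -> pd.DataFrame:
    """Sum the top-k features' counts by taxon label at the requested rank.

    Features are ranked by mean relative abundance across samples (ties
    broken lexicographically by feature id).  Features unclassified at the
    requested rank are labelled with their lowest available rank prefixed by
    its level code (f_ family, o_ order, c_ class, p_ phylum).
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    if rank not in table.taxonomy.columns:
        raise ValueError(f"rank {rank!r} absent from the taxonomy schema")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    rel = table.counts.div(table.counts.sum(axis=1), axis=0)
    mean_rel = rel.mean(axis=0)
    selected = sorted(table.counts.columns, key=lambda f: (-mean_rel[f], f))[:top_k]
    labels = {f: _fallback_label(table.taxonomy.loc[f], rank) for f in selected}
    return table.counts[selected].T.groupby(labels).sum().T


def zscore_rows(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Per-row z-scores (population sd by default; configurable via ddof).

    Constant rows map to all-zero with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("each row needs at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) z-scored to zeros", stacklevel=2
        )
    sd[sd == 0] = 1.0
    out = (values - mean) / sd
    out[constant, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_edges(
    profiles: pd.DataFrame,
    r_threshold: float = 0.8,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[NetworkEdge]:
    """All-pairs Pearson edges of a samples x taxa profile matrix.

    Retains pairs with |r| > r_threshold and p < alpha.  The optional
    Benjamini-Hochberg correction (off by default) adjusts the p-values
    before thresholding.
    """
    cols = list(profiles.columns)
    raw = []
    for a, b in itertools.combinations(cols, 2):
        try:
            r, p = pearson_with_p(profiles[a], profiles[b])
        except ValueError:
            continue  # constant taxon: no defined correlation
        raw.append((a, b, r, p))
    if bh_correct and raw:
        pvals = np.array([e[3] for e in raw])
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, pvals[i] * m / (rank_idx + 1))
            adj[i] = running
        raw = [(a, b, r, q) for (a, b, r, _), q in zip(raw, adj)]
    return [
        NetworkEdge(a, b, r, p, "positive" if r > 0 else "negative")
        for a, b, r, p in raw
        if abs(r) > r_threshold and p < alpha
    ]


def cooccurrence_network(
    table: CountTable,
    rank: str = "family",
    top_k: int = 50,
    r_threshold: float = 0.8,
    alpha: float = 0.05,
    use_relative: bool = True,
    bh_correct: bool = False,
) -> NetworkResult:
    """Thresholded Pearson co-occurrence network of aggregated taxa.

    Aggregates the top-k features at the requested rank, correlates taxa
    across the stratum's samples on relative abundances (configurable), and
    keeps edges with |r| > r_threshold and p < alpha.  No multiple-testing
    correction by default.  Also reports per-node degree (hub detection)
    and connected components.
    """
    if len(table.counts) < 3:
        raise ValueError("need at least 3 samples in the stratum")
    agg = aggregate_taxa(table, rank=rank, top_k=top_k)
    if agg.shape[1] < 2:
        raise ValueError("fewer than 2 aggregated taxa; nothing to correlate")
    profiles = agg.div(agg.sum(axis=1), axis=0) if use_relative else agg.astype(float)
    edges = correlation_edges(profiles, r_threshold, alpha, bh_correct)
    graph = nx.Graph()
    graph.add_nodes_from(agg.columns)
    for e in edges:
        graph.add_edge(e.family_a, e.family_b, r=e.r, p=e.p, sign=e.sign)
    return NetworkResult(
        edges=edges,
        graph=graph,
        degrees=dict(graph.degree()),
        components=[set(c) for c in nx.connected_components(graph)],
    )
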