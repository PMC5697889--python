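"""Taxon-table community structure: filtering, Bray-Curtis, clustering.

Operations follow the usual order for amplicon/metagenome taxon profiles:
drop lineages below the minimum relative abundance, renormalise, compute
abundance-weighted Bray-Curtis dissimilarities, cluster samples with UPGMA
and rank host-discriminating lineages by effect size among lineages that
differ significantly between hosts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .model import SampleGroup, TaxonProfile, ValidationError
from .stats import DifferentialResult, differential_features

logger = logging.getLogger(__name__)

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


def filter_taxa(profile: TaxonProfile, min_abundance: float | None = None) -> TaxonProfile:
    """Drop lineages below ``min_abundance`` in every sample; log removed mass."""
    threshold = profile.min_abundance if min_abundance is None else min_abundance
    kept = {
        lineage: vals
        for lineage, vals in profile.rows.items()
        if any(v >= threshold for v in vals)
    }
    removed = len(profile.rows) - len(kept)
    if removed:
        mass = [
            sum(vals[j] for lin, vals in profile.rows.items() if lin not in kept)
            for j in range(len(profile.samples))
        ]
        logger.info(
            "filter_taxa: removed %d lineages below %.4g (max removed mass %.4g)",
            removed,
            threshold,
            max(mass),
        )
    return TaxonProfile(
        samples=list(profile.samples), rows=kept, min_abundance=threshold
    )


def aggregate_at_rank(profile: TaxonProfile, rank: str) -> TaxonProfile:
    """Sum abundances of descendant lineages at the requested rank.

    Lineages unclassified at the rank aggregate under their deepest
    classified ancestor with an ``unc_`` label.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; choose from {RANKS}")
    depth = RANKS.index(rank)
    rows: dict[tuple[str, ...], list[float]] = {}
    for lineage, vals in profile.rows.items():
        if len(lineage) > depth:
            key = lineage[: depth + 1]
        else:
            key = lineage[:-1] + ("unc_" + lineage[-1],) if lineage else lineage
        acc = rows.setdefault(key, [0.0] * len(profile.samples))
        for j, v in enumerate(vals):
            acc[j] += v
    return TaxonProfile(
        samples=list(profile.samples), rows=rows, min_abundance=profile.min_abundance
    )


def renormalize(profile: TaxonProfile) -> TaxonProfile:
    """Rescale each sample column to sum to 1 (columns with zero sum stay 0)."""
    totals = [
        sum(vals[j] for vals in profile.rows.values())
        for j in range(len(profile.samples))
    ]
    rows = {
        lin: [v / t if t > 0 else 0.0 for v, t in zip(vals, totals)]
        for lin, vals in profile.rows.items()
    }
    return TaxonProfile(
        samples=list(profile.samples), rows=rows, min_abundance=profile.min_abundance
    )


def bray_curtis(x, y) -> float:
    """Abundance-weighted Bray-Curtis dissimilarity: 1 - 2*sum(min)/sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must share a taxon index")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("abundances must be non-negative")
    denom = float(np.sum(x + y))
    if denom == 0.0:
        logger.warning("bray_curtis: both vectors are zero; returning 0")
        return 0.0
    return 1.0 - 2.0 * float(np.sum(np.minimum(x, y))) / denom


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValidationError("distance matrix must be symmetric, zero diagonal")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValidationError("Bray-Curtis distances must lie in [0, 1]")
        self.values = v


def distance_matrix(profile: TaxonProfile) -> DistanceMatrix:
    """Pairwise weighted Bray-Curtis distances between samples."""
    sample_ids = list(profile.samples)
    mat = np.array([vals for vals in profile.rows.values()], dtype=float)
    n = len(sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            col_i = mat[:, i] if mat.size else np.zeros(0)
            col_j = mat[:, j] if mat.size else np.zeros(0)
            d[i, j] = d[j, i] = bray_curtis(col_i, col_j)
    return DistanceMatrix(sample_ids=sample_ids, values=d)


def hierarchical_cluster(dm: DistanceMatrix):
    """Average-linkage (UPGMA) agglomeration of the distance matrix.

    Samples are ordered lexicographically before linkage so that ties in
    merge height break on the smallest lexicographic pair, making the
    dendrogram invariant to input order.
    """
    if len(dm.sample_ids) < 2:
        raise ValidationError("clustering needs >= 2 samples")
    order = sorted(range(len(dm.sample_ids)), key=lambda i: dm.sample_ids[i])
    ids = [dm.sample_ids[i] for i in order]
    values = dm.values[np.ix_(order, order)]
    condensed = squareform(values, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return ids, linkage


def dendrogram_newick(dm: DistanceMatrix) -> str:
    """UPGMA dendrogram as a Newick string with branch lengths."""
    ids, linkage = hierarchical_cluster(dm)
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> tuple[str, float]:
        # returns (newick fragment, node height)
        if node.is_leaf():
            return ids[node.id], 0.0
        left, hl = walk(node.get_left())
        right, hr = walk(node.get_right())
        h = node.dist / 2.0  # ultrametric height of this node
        return f"({left}:{h - hl:.6g},{right}:{h - hr:.6g})", h

    newick, _ = walk(tree)
    return newick + ";"


def top_split(dm: DistanceMatrix) -> tuple[frozenset[str], frozenset[str]]:
    """The two sample groups separated by the root of the UPGMA dendrogram."""
    ids, linkage = hierarchical_cluster(dm)
    tree = hierarchy.to_tree(linkage)
    left = frozenset(ids[i] for i in tree.get_left().pre_order())
    right = frozenset(ids[i] for i in tree.get_right().pre_order())
    return left, right


def discriminating_lineages(
    profile: TaxonProfile,
    groups: tuple[SampleGroup, SampleGroup],
    p_threshold: float = 0.05,
) -> list[DifferentialResult]:
    """Host-discriminating lineages ranked by absolute difference in means.

    Uses raw Welch p < threshold (no FDR correction) for flagging; the effect
    reported is the absolute difference in mean relative abundance.
    """
    feat_profile = {
        ";".join(lineage): dict(zip(profile.samples, vals))
        for lineage, vals in profile.rows.items()
    }
    return differential_features(
        feat_profile, groups, mode="taxon_p", threshold=p_threshold
    )


def write_distance_matrix(dm: DistanceMatrix, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["sample"] + dm.sample_ids) + "\n")
        for i, s in enumerate(dm.sample_ids):
            fh.write(
                "\t".join([s] + [f"{v:.6g}" for v in dm.values[i]]) + "\n"
            )
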