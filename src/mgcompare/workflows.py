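"""High-level two-community workflows composed from the core modules."""

from __future__ import annotations

from .model import FunctionCatalog, SampleGroup, TaxonProfile
from .profiles import pathway_profile_matrix
from .simulate import HostDataset, SyntheticCommunity
from .stats import DifferentialResult, differential_features


def two_host_pathway_matrix(
    ds_a: HostDataset, ds_b: HostDataset, catalog: FunctionCatalog
) -> dict[str, dict[str, float]]:
    """pathway -> sample -> proportion across both host assemblies."""
    matrix: dict[str, dict[str, float]] = {}
    for ds in (ds_a, ds_b):
        part = pathway_profile_matrix(ds.cds, ds.coverage, catalog)
        for pw, row in part.items():
            matrix.setdefault(pw, {}).update(row)
    for row in matrix.values():
        for s in list(ds_a.samples) + list(ds_b.samples):
            row.setdefault(s, 0.0)
    return matrix


def differential_pathways(
    community: SyntheticCommunity, q_threshold: float = 0.05
) -> list[DifferentialResult]:
    """Host-differential KEGG pathways (Welch + BH, q < threshold)."""
    ds_a = community.hosts["hostA"]
    ds_b = community.hosts["hostB"]
    matrix = two_host_pathway_matrix(ds_a, ds_b, community.catalog)
    return differential_features(
        matrix, (ds_a.group, ds_b.group), mode="pathway_q", threshold=q_threshold
    )


def genome_taxon_profile(community: SyntheticCommunity) -> TaxonProfile:
    """Treat each synthetic genome as a lineage: abundance table per sample.

    Host communities have disjoint genome sets, so a joint profile over all
    samples is zero outside a genome's own host.
    """
    samples: list[str] = []
    for ds in community.hosts.values():
        samples += list(ds.samples)
    rows: dict[tuple[str, ...], list[float]] = {}
    for host, table in community.truth.abundance.items():
        ds = community.hosts[host]
        from .genomes import genome_abundance

        for b in community.truth.true_bins[host]:
            vals = [
                genome_abundance(b, ds.coverage, s) if s in ds.samples else 0.0
                for s in samples
            ]
            rows[tuple(b.taxonomy.split(";"))] = vals
    return TaxonProfile(samples=samples, rows=rows, min_abundance=0.0)
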