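"""Shared fixtures: hand-built micro-communities and small catalogs."""

from __future__ import annotations

import pytest

from mgcompare import (
    AnnotatedCDS,
    CoverageTable,
    FunctionCatalog,
    SampleGroup,
)
from mgcompare.catalog import default_catalog


def make_cds(cds_id, contig, ko=None, cazy=(), start=1, end=300):
    return AnnotatedCDS(
        cds_id=cds_id,
        contig_id=contig,
        start=start,
        end=end,
        strand="+",
        ko=ko,
        cazy_domains=tuple(cazy),
    )


def make_coverage(depths, lengths=None, samples=("s1",)):
    """depths: {contig: depth} (one sample) or {contig: {sample: depth}}."""
    samples = list(samples)
    depth = {}
    for contig, d in depths.items():
        if isinstance(d, dict):
            depth[contig] = dict(d)
        else:
            depth[contig] = {s: float(d) for s in samples}
    lengths = lengths or {c: 1000 for c in depth}
    return CoverageTable(samples=samples, depth=depth, contig_lengths=lengths)


@pytest.fixture
def gh_catalog():
    """Bundled GH role map, no KO->pathway content."""
    return default_catalog()


@pytest.fixture
def toy_pathway_catalog():
    """Three pathways: pwX {K1,K2,K3}, pwY {K3,K4,K5}, pwZ {K6,K7} (too small)."""
    ko_map = {
        "K1": frozenset({"pwX"}),
        "K2": frozenset({"pwX"}),
        "K3": frozenset({"pwX", "pwY"}),
        "K4": frozenset({"pwY"}),
        "K5": frozenset({"pwY"}),
        "K6": frozenset({"pwZ"}),
        "K7": frozenset({"pwZ"}),
    }
    categories = {"pwX": "1.1", "pwY": "1.2", "pwZ": "1.3"}
    return default_catalog(ko_map, categories)


@pytest.fixture
def two_groups():
    return (
        SampleGroup("A", ("a1", "a2", "a3")),
        SampleGroup("B", ("b1", "b2", "b3", "b4", "b5")),
    )
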