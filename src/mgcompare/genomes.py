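"""Population-genome analytics: quality filtering, abundance, pathway
coverage, PCA, the differential-metabolism contributor score and the
urea-processing screen.

Genome abundance is the bin's share of length-weighted contig coverage, i.e.
the fraction of sequenced bases attributable to the bin, which is the
quantity community-representation figures report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    AnnotatedCDS,
    CoverageTable,
    FunctionCatalog,
    GenomeBin,
    ValidationError,
)

logger = logging.getLogger(__name__)


def filter_bins(
    bins: Sequence[GenomeBin],
    completeness_min: float = 50.0,
    contamination_max: float = 10.0,
) -> list[GenomeBin]:
    """Inclusive quality thresholds: completeness >= min, contamination <= max."""
    passing: list[GenomeBin] = []
    for b in bins:
        if b.completeness < completeness_min:
            logger.info(
                "bin %s rejected: completeness %.1f < %.1f",
                b.bin_id, b.completeness, completeness_min,
            )
        elif b.contamination > contamination_max:
            logger.info(
                "bin %s rejected: contamination %.1f > %.1f",
                b.bin_id, b.contamination, contamination_max,
            )
        else:
            passing.append(b)
    return passing


def genome_abundance(bin_: GenomeBin, cov: CoverageTable, sample: str) -> float:
    """Bin's fraction of total length-weighted contig coverage in a sample."""
    cov.require_contigs(bin_.contig_ids)
    total = sum(
        cov.contig_lengths[c] * cov.get(c, sample) for c in cov.depth
    )
    if total == 0:
        raise ValidationError(f"sample {sample}: total contig coverage is zero")
    in_bin = sum(
        cov.contig_lengths[c] * cov.get(c, sample) for c in bin_.contig_ids
    )
    return in_bin / total


def abundance_table(
    bins: Sequence[GenomeBin], cov: CoverageTable
) -> dict[str, dict[str, float]]:
    """bin_id -> sample -> relative abundance."""
    return {
        b.bin_id: {s: genome_abundance(b, cov, s) for s in cov.samples}
        for b in bins
    }


def top_n_genomes(
    bins: Sequence[GenomeBin],
    abundances: Mapping[str, Mapping[str, float]],
    n: int = 15,
) -> list[GenomeBin]:
    """Top n bins by median per-sample abundance.

    Ties break by mean abundance descending (a genome with median abundance 0
    still ranks by its mean), then by bin id.
    """
    if n > len(bins):
        warnings.warn(
            f"requested top {n} genomes but only {len(bins)} available",
            stacklevel=2,
        )

    def key(b: GenomeBin):
        vals = list(abundances[b.bin_id].values())
        return (-float(np.median(vals)), -float(np.mean(vals)), b.bin_id)

    return sorted(bins, key=key)[: max(n, 0)]


def bin_ko_sets(
    bins: Sequence[GenomeBin], cds_list: Sequence[AnnotatedCDS]
) -> dict[str, frozenset[str]]:
    """Distinct KOs annotated on each bin's contigs."""
    contig_owner: dict[str, str] = {}
    for b in bins:
        for c in b.contig_ids:
            contig_owner[c] = b.bin_id
    kos: dict[str, set[str]] = {b.bin_id: set() for b in bins}
    for cds in cds_list:
        owner = contig_owner.get(cds.contig_id)
        if owner is not None and cds.ko:
            kos[owner].add(cds.ko)
    return {k: frozenset(v) for k, v in kos.items()}


def pathway_universe(
    ko_sets: Mapping[str, frozenset[str]], catalog: FunctionCatalog
) -> dict[str, frozenset[str]]:
    """Per pathway, the union of its member KOs observed across ALL bins.

    The universe spans every passing bin from both host datasets, so pathway
    coverages are comparable across communities.
    """
    universe: dict[str, set[str]] = {}
    for kos in ko_sets.values():
        for ko in kos:
            for pw in catalog.pathways_of(ko):
                universe.setdefault(pw, set()).add(ko)
    return {pw: frozenset(kos) for pw, kos in universe.items() if kos}


def pathway_coverage(
    bin_kos: frozenset[str], pathway_kos: frozenset[str]
) -> float:
    """|bin KOs within the pathway universe| / |universe|."""
    if not pathway_kos:
        raise ValidationError("empty pathway universe")
    return len(bin_kos & pathway_kos) / len(pathway_kos)


def pathway_coverage_matrix(
    ko_sets: Mapping[str, frozenset[str]], catalog: FunctionCatalog
) -> dict[str, dict[str, float]]:
    """bin_id -> pathway -> relative pathway coverage in [0, 1]."""
    universe = pathway_universe(ko_sets, catalog)
    return {
        bin_id: {pw: pathway_coverage(kos, upw) for pw, upw in universe.items()}
        for bin_id, kos in ko_sets.items()
    }


def pathway_proportions(
    ko_sets: Mapping[str, frozenset[str]], catalog: FunctionCatalog
) -> dict[str, dict[str, float]]:
    """Each genome as a composition of pathways (KO counts, normalised).

    Pathways with fewer than ``catalog.min_kos_per_pathway`` observed KOs in
    a genome are excluded for that genome, matching the gene-centric filter.
    """
    out: dict[str, dict[str, float]] = {}
    for bin_id, kos in ko_sets.items():
        counts: dict[str, int] = {}
        for ko in kos:
            for pw in catalog.pathways_of(ko):
                counts[pw] = counts.get(pw, 0) + 1
        counts = {
            pw: c for pw, c in counts.items() if c >= catalog.min_kos_per_pathway
        }
        total = sum(counts.values())
        out[bin_id] = (
            {pw: c / total for pw, c in counts.items()} if total else {}
        )
    return out


@dataclass
class PCAResult:
    bin_ids: list[str]
    pathways: list[str]
    coordinates: np.ndarray  # genomes x components
    explained_variance: np.ndarray  # fraction per component


def genome_pathway_pca(
    proportions: Mapping[str, Mapping[str, float]]
) -> PCAResult:
    """Column-centered SVD of the genome x pathway proportion matrix.

    Sign convention: within each component the largest-magnitude pathway
    loading is positive, making coordinates deterministic.
    """
    bin_ids = sorted(proportions)
    if len(bin_ids) < 3:
        raise ValidationError("PCA needs >= 3 genomes")
    pathways = sorted({pw for row in proportions.values() for pw in row})
    x = np.array(
        [[proportions[b].get(pw, 0.0) for pw in pathways] for b in bin_ids]
    )
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for j in range(len(s)):
        k = int(np.argmax(np.abs(vt[j])))
        if vt[j, k] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    total_var = float(np.sum(s**2))
    explained = s**2 / total_var if total_var > 0 else np.zeros_like(s)
    return PCAResult(
        bin_ids=bin_ids,
        pathways=pathways,
        coordinates=u * s,
        explained_variance=explained,
    )


def contributor_score(
    bin_kos: frozenset[str],
    differential_pathways: frozenset[str],
    catalog: FunctionCatalog,
    completeness: float,
) -> float:
    """Completeness-adjusted count of KOs relevant to differential pathways.

    score = |unique bin KOs belonging to >= 1 differential pathway| divided by
    completeness as a fraction, so an incomplete genome's observed count is
    scaled up to an estimated-complete value.  Higher means a greater
    inferred contribution to host-differential metabolism.
    """
    if not 0.0 < completeness <= 100.0:
        raise ValidationError(f"completeness {completeness} outside (0, 100]")
    qualifying = {
        ko for ko in bin_kos if catalog.pathways_of(ko) & differential_pathways
    }
    return len(qualifying) / (completeness / 100.0)


@dataclass(frozen=True)
class UreaScreenResult:
    status: str  # transport_only | ureolysis_only | full_suite | none
    transport_capable: bool
    ureolysis_capable: bool
    accessory_fraction: float  # completeness of the urease accessory set


def urea_screen(
    bin_kos: frozenset[str], urea_config: Mapping[str, frozenset[str]]
) -> UreaScreenResult:
    """Classify a genome's urea-processing capacity from its KO content.

    Transport requires the complete five-subunit Urt complex or the monomeric
    Utp protein; ureolysis requires all three structural urease subunits.
    Urease accessory (maturation) completeness is reported separately.
    """
    for key in ("urt_subunits", "utp", "urease_structural", "urease_accessory"):
        if key not in urea_config:
            raise ValidationError(f"urea config missing {key!r}")
    urt = urea_config["urt_subunits"]
    utp = urea_config["utp"]
    structural = urea_config["urease_structural"]
    accessory = urea_config["urease_accessory"]
    if not urt or not structural:
        raise ValidationError("urea config: empty required KO set")
    transport = urt <= bin_kos or (bool(utp) and bool(utp & bin_kos))
    ureolysis = structural <= bin_kos
    status = {
        (True, True): "full_suite",
        (True, False): "transport_only",
        (False, True): "ureolysis_only",
        (False, False): "none",
    }[(transport, ureolysis)]
    acc_frac = len(accessory & bin_kos) / len(accessory) if accessory else 0.0
    return UreaScreenResult(
        status=status,
        transport_capable=transport,
        ureolysis_capable=ureolysis,
        accessory_fraction=acc_frac,
    )


def community_genome_size_summary(
    bins: Sequence[GenomeBin], abundances: Mapping[str, float]
) -> float:
    """Abundance-weighted mean estimated-complete genome size (bp).

    Each bin's size is corrected to an estimated-complete size by dividing by
    its completeness fraction before weighting by abundance.
    """
    if not bins:
        raise ValidationError("no passing bins")
    num = 0.0
    den = 0.0
    for b in bins:
        if b.completeness <= 0:
            raise ValidationError(f"bin {b.bin_id}: completeness must be > 0")
        a = abundances[b.bin_id]
        num += a * (b.size_bp / (b.completeness / 100.0))
        den += a
    if den == 0:
        raise ValidationError("total abundance of passing bins is zero")
    return num / den


def bin_gh_category_counts(
    bins: Sequence[GenomeBin],
    cds_list: Sequence[AnnotatedCDS],
    catalog: FunctionCatalog,
) -> dict[str, dict[str, int]]:
    """Unique-CDS counts per broad CAZy category for each bin (heat-map rows)."""
    contig_owner: dict[str, str] = {}
    for b in bins:
        for c in b.contig_ids:
            contig_owner[c] = b.bin_id
    counts: dict[str, dict[str, int]] = {b.bin_id: {} for b in bins}
    for cds in cds_list:
        owner = contig_owner.get(cds.contig_id)
        if owner is None:
            continue
        cats = {catalog.classify_family(f) for f in cds.cazy_families}
        for cat in cats:
            counts[owner][cat] = counts[owner].get(cat, 0) + 1
    return counts
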