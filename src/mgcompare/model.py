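"""Core domain types for comparative metagenome profiling.

The atomic unit of every gene-centric computation is an annotated coding
sequence (CDS) tied to its parent contig; the weighting signal is the contig's
mean read depth per sample.  Genome bins group contigs into population
genomes with externally estimated completeness/contamination.  All relative
abundances are stored as fractions in [0, 1]; percent formatting happens only
at write time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class AnnotatedCDS:
    """One predicted coding sequence with functional labels.

    Coordinates are 1-based inclusive base-pair positions on the contig.
    ``cazy_domains`` may repeat a family only when the CDS genuinely carries
    multiple domains of it; profile computations collapse repeats per family.
    """

    cds_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    ko: str | None = None
    cazy_domains: tuple[str, ...] = ()
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"CDS {self.cds_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"CDS {self.cds_id}: strand must be + or -")

    @property
    def cazy_families(self) -> frozenset[str]:
        """Distinct CAZy families on this CDS (repeat domains collapse)."""
        return frozenset(self.cazy_domains)


def validate_cds_list(cds_list: Sequence[AnnotatedCDS]) -> None:
    seen: set[str] = set()
    for cds in cds_list:
        if cds.cds_id in seen:
            raise ValidationError(f"duplicate cds_id: {cds.cds_id}")
        seen.add(cds.cds_id)


@dataclass
class CoverageTable:
    """Contig x sample mean read depth plus contig lengths.

    ``samples`` preserves the column order of the source file; depth values
    are mean reads-per-base over the contig and must be >= 0.
    """

    samples: list[str]
    depth: dict[str, dict[str, float]]  # contig_id -> sample_id -> depth
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValidationError("coverage table has no samples")
        for contig, row in self.depth.items():
            if contig not in self.contig_lengths:
                raise ValidationError(f"contig {contig} has no length")
            for sample, d in row.items():
                if d < 0:
                    raise ValidationError(
                        f"negative depth for contig {contig}, sample {sample}"
                    )

    @property
    def contigs(self) -> list[str]:
        return list(self.depth)

    def get(self, contig_id: str, sample_id: str) -> float:
        try:
            return self.depth[contig_id][sample_id]
        except KeyError:
            if contig_id not in self.depth:
                raise ValidationError(f"unknown contig: {contig_id}") from None
            raise ValidationError(f"unknown sample: {sample_id}") from None

    def require_contigs(self, contig_ids: Iterable[str]) -> None:
        missing = sorted(set(contig_ids) - set(self.depth))
        if missing:
            raise ValidationError(f"contigs absent from coverage table: {missing[:5]}")


@dataclass
class GenomeBin:
    """A population genome: a disjoint contig set with quality estimates."""

    bin_id: str
    contig_ids: frozenset[str]
    completeness: float
    contamination: float
    size_bp: int = 0
    taxonomy: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValidationError(
                f"bin {self.bin_id}: completeness {self.completeness} outside [0, 100]"
            )
        if not 0.0 <= self.contamination <= 100.0:
            raise ValidationError(
                f"bin {self.bin_id}: contamination {self.contamination} outside [0, 100]"
            )


def validate_bins(bins: Sequence[GenomeBin], cov: CoverageTable | None = None) -> None:
    """Assert pairwise contig disjointness and size consistency."""
    owner: dict[str, str] = {}
    for b in bins:
        for c in b.contig_ids:
            if c in owner:
                raise ValidationError(
                    f"contig {c} assigned to both {owner[c]} and {b.bin_id}"
                )
            owner[c] = b.bin_id
    if cov is not None:
        for b in bins:
            cov.require_contigs(b.contig_ids)
            expected = sum(cov.contig_lengths[c] for c in b.contig_ids)
            if b.size_bp and b.size_bp != expected:
                raise ValidationError(
                    f"bin {b.bin_id}: size_bp {b.size_bp} != sum of contig lengths {expected}"
                )


@dataclass(frozen=True)
class SampleGroup:
    """Named host group over an ordered list of sample time-points."""

    group_id: str
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError(f"group {self.group_id}: duplicate sample ids")


def validate_groups(groups: Sequence[SampleGroup], min_per_group: int = 2) -> None:
    seen: set[str] = set()
    for g in groups:
        if len(g.sample_ids) < min_per_group:
            raise ValidationError(
                f"group {g.group_id} needs >= {min_per_group} samples for testing"
            )
        overlap = seen & set(g.sample_ids)
        if overlap:
            raise ValidationError(f"samples shared across groups: {sorted(overlap)}")
        seen |= set(g.sample_ids)


@dataclass
class TaxonProfile:
    """Lineage x sample relative-abundance table (fractions in [0, 1]).

    Rows are lineage tuples with single-letter rank prefixes
    ("k__Bacteria", "p__Firmicutes", ...).  Per-sample column sums may be
    below 1; an explicit "unmapped" row may absorb the remainder.
    """

    samples: list[str]
    rows: dict[tuple[str, ...], list[float]]
    min_abundance: float = 0.0005

    def __post_init__(self) -> None:
        n = len(self.samples)
        for lineage, vals in self.rows.items():
            if len(vals) != n:
                raise ValidationError(f"lineage {lineage}: expected {n} values")
            for v in vals:
                if v < 0 or v > 1:
                    raise ValidationError(
                        f"lineage {lineage}: abundance {v} outside [0, 1]"
                    )
        for j, s in enumerate(self.samples):
            total = sum(vals[j] for vals in self.rows.values())
            if total > 1 + 1e-9:
                raise ValidationError(f"sample {s}: column sum {total} > 1")


@dataclass
class FunctionCatalog:
    """KO -> pathway universe plus the GH-family -> lignocellulose-role map.

    A KO may belong to several KEGG metabolism pathways (hierarchy categories
    1.1-1.11) and contributes fully to each.  GH families outside the bundled
    four-role map classify as ``other_gh``; auxiliary-activity (AA) families
    classify as ``auxiliary_activity``.
    """

    ko_to_pathways: dict[str, frozenset[str]]
    pathway_category: dict[str, str] = field(default_factory=dict)
    gh_category: dict[str, str] = field(default_factory=dict)
    min_kos_per_pathway: int = 3

    LIGNO_CATEGORIES = (
        "cellulase",
        "endohemicellulase",
        "accessory_hemicellulase",
        "oligosaccharide_degrading",
    )

    def pathways_of(self, ko: str) -> frozenset[str]:
        return self.ko_to_pathways.get(ko, frozenset())

    def classify_family(self, family: str) -> str:
        if family in self.gh_category:
            return self.gh_category[family]
        if family.startswith("AA"):
            return "auxiliary_activity"
        return "other_gh"

    @property
    def pathways(self) -> frozenset[str]:
        out: set[str] = set()
        for ps in self.ko_to_pathways.values():
            out |= ps
        return frozenset(out)
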