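"""Coverage-weighted functional profiles of an assembled community.

Every gene-centric profile uses the same weighting rule: a functional label
observed on a CDS is weighted by the mean read depth of the CDS's parent
contig in a sample, normalised to the summed depth over *all* CDSs (annotated
or not).  Scaling all depths by a constant therefore never changes a profile.

A CDS carrying k domains from distinct CAZy families contributes its contig
depth once to each family; repeated domains of the same family within one CDS
count once, which keeps multi-domain genes from inflating family weights and
mirrors the unique-CDS correction used for counting lignocellulolytic genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .model import (
    AnnotatedCDS,
    CoverageTable,
    FunctionCatalog,
    SampleGroup,
    ValidationError,
)
from .stats import DifferentialResult, differential_features


@dataclass
class WeightedProfile:
    """feature -> normalized weight for one sample."""

    sample: str
    weights: dict[str, float]
    normalization_scope: Literal["all_cds", "lignocellulolytic_gh"] = "all_cds"


def _total_depth(cds_list: Sequence[AnnotatedCDS], cov: CoverageTable, sample: str) -> float:
    return sum(cov.get(c.contig_id, sample) for c in cds_list)


def weighted_feature_profile(
    cds_list: Sequence[AnnotatedCDS],
    cov: CoverageTable,
    sample: str,
    feature_of: Literal["cazy", "ko"] = "cazy",
) -> WeightedProfile:
    """Depth-weighted share of each observed feature among all CDS coverage."""
    if not cds_list:
        raise ValidationError("empty CDS list")
    if sample not in cov.samples:
        raise ValidationError(f"unknown sample: {sample}")
    denom = _total_depth(cds_list, cov, sample)
    weights: dict[str, float] = {}
    for cds in cds_list:
        depth = cov.get(cds.contig_id, sample)
        if feature_of == "ko":
            features: Sequence[str] = (cds.ko,) if cds.ko else ()
        else:
            features = sorted(cds.cazy_families)
        for f in features:
            weights[f] = weights.get(f, 0.0) + depth
    if denom > 0:
        weights = {f: w / denom for f, w in weights.items()}
    return WeightedProfile(sample=sample, weights=weights)


@dataclass
class GHTable:
    """Community lignocellulolytic GH profile in the cross-biome table layout."""

    family_percent: dict[str, float]  # mean % of lignocellulolytic GH coverage
    subtotals: dict[str, float]  # category -> % (1-decimal presentation)
    total_ligno_cds: int  # unique lignocellulolytic CDSs
    percent_of_all_cds: float


def category_subtotal(
    family_percentages: Mapping[str, float],
    catalog: FunctionCatalog,
    category: str,
) -> float:
    """Sum of family percentages over one lignocellulose role, at 1 decimal.

    Families the catalog cannot place in one of the four roles are excluded.
    """
    total = sum(
        pct
        for fam, pct in family_percentages.items()
        if catalog.gh_category.get(fam) == category
    )
    return round(total, 1)


def gh_relative_profile(
    cds_list: Sequence[AnnotatedCDS],
    cov: CoverageTable,
    catalog: FunctionCatalog,
    samples: Sequence[str] | None = None,
) -> GHTable:
    """Per-family percentages renormalised over the four lignocellulose roles.

    Family shares are computed per sample against total lignocellulolytic GH
    coverage, averaged across samples (unweighted arithmetic mean), and
    reported as percentages; the four category subtotals sum to 100 up to
    rounding.  Counting uses unique CDSs so multi-domain genes count once.
    """
    samples = list(samples) if samples is not None else list(cov.samples)
    ligno_families = set(catalog.gh_category)

    # share of lignocellulolytic GH coverage per family, one dict per sample
    # with nonzero lignocellulolytic coverage
    sample_shares: list[dict[str, float]] = []
    for sample in samples:
        fam_depth: dict[str, float] = {}
        for cds in cds_list:
            fams = cds.cazy_families & ligno_families
            if not fams:
                continue
            depth = cov.get(cds.contig_id, sample)
            for f in fams:
                fam_depth[f] = fam_depth.get(f, 0.0) + depth
        total = sum(fam_depth.values())
        if total > 0:
            sample_shares.append({f: d / total for f, d in fam_depth.items()})
    if not sample_shares:
        raise ValidationError("no lignocellulolytic GH CDS in the community")

    all_fams = sorted({f for shares in sample_shares for f in shares})
    family_percent = {
        f: 100.0 * float(np.mean([shares.get(f, 0.0) for shares in sample_shares]))
        for f in all_fams
    }
    subtotals = {
        cat: category_subtotal(family_percent, catalog, cat)
        for cat in FunctionCatalog.LIGNO_CATEGORIES
    }
    ligno_cds = {c.cds_id for c in cds_list if c.cazy_families & ligno_families}
    return GHTable(
        family_percent=family_percent,
        subtotals=subtotals,
        total_ligno_cds=len(ligno_cds),
        percent_of_all_cds=100.0 * len(ligno_cds) / len(cds_list),
    )


CAZY_CLASSES = (
    "cellulose_gh",
    "hemicellulose_gh",
    "oligosaccharide_gh",
    "auxiliary_activity",
    "other_gh",
)

_CLASS_OF_CATEGORY = {
    "cellulase": "cellulose_gh",
    "endohemicellulase": "hemicellulose_gh",
    "accessory_hemicellulase": "hemicellulose_gh",
    "oligosaccharide_degrading": "oligosaccharide_gh",
    "auxiliary_activity": "auxiliary_activity",
    "other_gh": "other_gh",
}


def cazy_class_fractions(
    cds_list: Sequence[AnnotatedCDS],
    cov: CoverageTable,
    catalog: FunctionCatalog,
    samples: Sequence[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Broad CAZyme-class coverage fractions (all-CDS scope) per sample.

    Classes: cellulose GHs, hemicellulose GHs (backbone + side chain),
    oligosaccharide-degrading GHs, auxiliary-activity (lignin/polyphenol)
    enzymes, and any other GH family.
    """
    samples = list(samples) if samples is not None else list(cov.samples)
    fractions: dict[str, dict[str, float]] = {c: {} for c in CAZY_CLASSES}
    for sample in samples:
        denom = _total_depth(cds_list, cov, sample)
        totals = {c: 0.0 for c in CAZY_CLASSES}
        for cds in cds_list:
            classes = {
                _CLASS_OF_CATEGORY[catalog.classify_family(f)]
                for f in cds.cazy_families
                if f.startswith(("GH", "AA"))
            }
            if not classes:
                continue
            depth = cov.get(cds.contig_id, sample)
            for cl in classes:
                totals[cl] += depth
        for cl in CAZY_CLASSES:
            fractions[cl][sample] = totals[cl] / denom if denom > 0 else 0.0
    return fractions


def cazy_class_comparison(
    communities: Sequence[tuple[Sequence[AnnotatedCDS], CoverageTable]],
    catalog: FunctionCatalog,
    groups: tuple[SampleGroup, SampleGroup],
    p_threshold: float = 0.05,
) -> tuple[dict[str, dict[str, float]], list[DifferentialResult]]:
    """Two-group Welch comparison of broad CAZyme-class fractions.

    ``communities`` holds one ``(cds_list, coverage)`` pair per group (a
    single pair may also serve both groups when the samples come from one
    assembly).  Returns ``(class -> sample -> fraction, results)``.
    """
    fractions: dict[str, dict[str, float]] = {c: {} for c in CAZY_CLASSES}
    for (cds_list, cov), group in zip(communities, groups):
        part = cazy_class_fractions(cds_list, cov, catalog, group.sample_ids)
        for cl, row in part.items():
            fractions[cl].update(row)
    if len(communities) == 1:
        part = cazy_class_fractions(
            communities[0][0], communities[0][1], catalog, groups[1].sample_ids
        )
        for cl, row in part.items():
            fractions[cl].update(row)
    results = differential_features(
        fractions, groups, mode="taxon_p", threshold=p_threshold
    )
    return fractions, results


def pathway_cumulative_profile(
    cds_list: Sequence[AnnotatedCDS],
    cov: CoverageTable,
    catalog: FunctionCatalog,
    sample: str,
) -> dict[str, float]:
    """Cumulative normalized KO coverage per KEGG metabolism pathway.

    Each KO weight is assigned to all pathways containing the KO (a KO in m
    pathways contributes fully to each).  Pathways with fewer than
    ``catalog.min_kos_per_pathway`` distinct observed KOs are excluded.
    """
    ko_profile = weighted_feature_profile(cds_list, cov, sample, feature_of="ko")
    observed_kos: dict[str, set[str]] = {}
    for cds in cds_list:
        if cds.ko:
            for pw in catalog.pathways_of(cds.ko):
                observed_kos.setdefault(pw, set()).add(cds.ko)
    out: dict[str, float] = {}
    for pw, kos in observed_kos.items():
        if len(kos) < catalog.min_kos_per_pathway:
            continue
        out[pw] = sum(ko_profile.weights.get(ko, 0.0) for ko in kos)
    return out


def pathway_profile_matrix(
    cds_list: Sequence[AnnotatedCDS],
    cov: CoverageTable,
    catalog: FunctionCatalog,
    samples: Sequence[str] | None = None,
) -> dict[str, dict[str, float]]:
    """pathway -> sample -> cumulative normalized abundance, over samples."""
    samples = list(samples) if samples is not None else list(cov.samples)
    out: dict[str, dict[str, float]] = {}
    for s in samples:
        prof = pathway_cumulative_profile(cds_list, cov, catalog, s)
        for pw, w in prof.items():
            out.setdefault(pw, {})[s] = w
    for pw, row in out.items():
        for s in samples:
            row.setdefault(s, 0.0)
    return out


def write_gh_table(
    tables: Mapping[str, GHTable],
    catalog: FunctionCatalog,
    path: str,
    literature_columns: Mapping[str, Mapping[str, float]] | None = None,
) -> None:
    """Cross-biome GH table: one column per community plus literature columns."""
    lit = dict(literature_columns or {})
    columns = list(tables) + list(lit)
    by_cat: dict[str, list[str]] = {c: [] for c in FunctionCatalog.LIGNO_CATEGORIES}
    for fam, cat in catalog.gh_category.items():
        by_cat[cat].append(fam)
    for fams in by_cat.values():
        fams.sort(key=lambda f: (len(f), f))

    def value(col: str, fam: str) -> float:
        if col in tables:
            return tables[col].family_percent.get(fam, 0.0)
        return lit[col].get(fam, 0.0)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["family"] + columns) + "\n")
        for cat in FunctionCatalog.LIGNO_CATEGORIES:
            fh.write(f"# {cat}\n")
            for fam in by_cat[cat]:
                fh.write(
                    "\t".join([fam] + [f"{value(c, fam):.1f}" for c in columns]) + "\n"
                )
            subtot = [
                f"{category_subtotal({f: value(c, f) for f in by_cat[cat]}, catalog, cat):.1f}"
                for c in columns
            ]
            fh.write("\t".join([f"subtotal_{cat}"] + subtot) + "\n")
        totals = [
            str(tables[c].total_ligno_cds) if c in tables else "" for c in columns
        ]
        fh.write("\t".join(["total_lignocellulolytic_ghs"] + totals) + "\n")
        pcts = [
            f"{tables[c].percent_of_all_cds:.2f}" if c in tables else ""
            for c in columns
        ]
        fh.write("\t".join(["percent_of_all_orfs"] + pcts) + "\n")
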