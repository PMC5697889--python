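"""Two-group differential testing: Welch's t, BH-FDR, effect-size ranking.

Compositional profiles routinely contain all-zero and zero-variance features,
so the degenerate cases carry explicit conventions: two zero-variance groups
with equal means are "no evidence" (p = 1); with unequal means they are
"certain difference" (p = 0).  All-zero features are dropped before testing
and the count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .model import SampleGroup, ValidationError, validate_groups

logger = logging.getLogger(__name__)


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, df, p)`` with the Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t requires >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, float(
            a.size + b.size - 2
        ), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class DifferentialResult:
    """Per-feature two-group comparison on relative proportions."""

    feature: str
    mean_a: float
    mean_b: float
    effect: float  # difference in mean proportions (a - b)
    p: float
    q: float
    flagged: bool

    @property
    def enriched_in(self) -> str:
        return "A" if self.effect > 0 else ("B" if self.effect < 0 else "-")


def differential_features(
    profile: Mapping[str, Mapping[str, float]],
    groups: tuple[SampleGroup, SampleGroup],
    mode: Literal["pathway_q", "taxon_p"] = "pathway_q",
    threshold: float = 0.05,
) -> list[DifferentialResult]:
    """Rank features by absolute difference in group mean proportions.

    ``profile`` maps feature -> sample -> proportion.  Flagging uses BH
    q < threshold in ``pathway_q`` mode and raw Welch p < threshold in
    ``taxon_p`` mode.  The returned list contains every tested feature,
    flagged ones first, sorted by \\|effect\\| descending with a lexicographic
    feature-id tie-break; both directions of enrichment are reported.
    """
    ga, gb = groups
    validate_groups([ga, gb], min_per_group=2)
    features = sorted(profile)
    kept: list[str] = []
    n_dropped = 0
    for f in features:
        row = profile[f]
        vals = [row.get(s, 0.0) for s in ga.sample_ids + gb.sample_ids]
        if all(v == 0.0 for v in vals):
            n_dropped += 1
            continue
        kept.append(f)
    if n_dropped:
        logger.info("differential_features: dropped %d all-zero features", n_dropped)
    if not kept:
        return []

    means_a, means_b, pvals = [], [], []
    for f in kept:
        row = profile[f]
        a = [row.get(s, 0.0) for s in ga.sample_ids]
        b = [row.get(s, 0.0) for s in gb.sample_ids]
        _, _, p = welch_t(a, b)
        means_a.append(float(np.mean(a)))
        means_b.append(float(np.mean(b)))
        pvals.append(p)
    qvals = bh_adjust(pvals)

    results = []
    for f, ma, mb, p, q in zip(kept, means_a, means_b, pvals, qvals):
        crit = q if mode == "pathway_q" else p
        results.append(
            DifferentialResult(
                feature=f,
                mean_a=ma,
                mean_b=mb,
                effect=ma - mb,
                p=p,
                q=float(q),
                flagged=bool(crit < threshold),
            )
        )
    results.sort(key=lambda r: (not r.flagged, -abs(r.effect), r.feature))
    return results


def write_differential_table(
    results: Sequence[DifferentialResult], path: str, group_names: tuple[str, str]
) -> None:
    na, nb = group_names
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"feature\tmean_{na}\tmean_{nb}\teffect\tp\tq\tflagged\tenriched_in\n"
        )
        for r in results:
            enriched = {"A": na, "B": nb, "-": "-"}[r.enriched_in]
            fh.write(
                f"{r.feature}\t{r.mean_a:.6g}\t{r.mean_b:.6g}\t{r.effect:.6g}\t"
                f"{r.p:.6g}\t{r.q:.6g}\t{int(r.flagged)}\t{enriched}\n"
            )
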