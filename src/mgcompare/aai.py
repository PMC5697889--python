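"""Aggregate amino-acid identity (AAI) between population-genome proteomes.

Orthologs are reciprocal best-scoring hits under exact affine-gap local
(Smith-Waterman) alignment with BLOSUM62, gap open 11 / extend 1, subject to
minimum thresholds of 30% identity and 70% coverage of the alignable region
across the shorter sequence.  AAI is the mean (and population SD) percent
identity over those ortholog pairs.

Exact local alignment replaces heuristically seeded database search: the
semantics are deterministic and self-contained, and the scoring parameters
match the common protein-search defaults so results stay comparable.  Because
the substitution matrix and gap penalties are symmetric, the optimal local
alignment score of a pair is direction-independent; the all-vs-all score
matrix is computed once (score-only, upper triangle) and tracebacks are done
only for the per-query candidates needed to check identity/coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import ValidationError


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    identity: float  # percent of aligned columns that are exact matches
    coverage: float  # aligned columns / length of the shorter sequence


def local_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Optimal affine-gap local alignment of two protein sequences.

    Identity is exact residue matches over aligned columns (gap columns count
    toward coverage, not identity).  Returns ``None`` when no positive-scoring
    local alignment exists.
    """
    if not a or not b:
        raise ValidationError("empty protein sequence")
    aligner = _aligner(matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return None
    alignment = next(iter(aligner.align(a, b)))
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    coverage = min(1.0, columns / min(len(a), len(b)))
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        identity=identity,
        coverage=coverage,
    )


def _score_matrix(
    seqs_a: list[str],
    seqs_b: list[str],
    aligner: Align.PairwiseAligner,
    symmetric: bool,
) -> np.ndarray:
    scores = np.zeros((len(seqs_a), len(seqs_b)))
    for i, sa in enumerate(seqs_a):
        start = i if symmetric else 0
        for j in range(start, len(seqs_b)):
            scores[i, j] = aligner.score(sa, seqs_b[j])
            if symmetric:
                scores[j, i] = scores[i, j]
    return scores


def best_hits(
    queryome: dict[str, str],
    subjectome: dict[str, str],
    identity_min: float = 0.30,
    coverage_min: float = 0.70,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    _scores: np.ndarray | None = None,
) -> dict[str, AlignmentHit]:
    """Per query, the best-scoring subject passing identity/coverage floors.

    Ties in score break by higher identity, then subject id.  Queries with no
    passing hit are absent from the result.
    """
    if not queryome or not subjectome:
        raise ValidationError("both proteomes must be non-empty")
    q_ids, s_ids = list(queryome), list(subjectome)
    q_seqs = [queryome[q] for q in q_ids]
    s_seqs = [subjectome[s] for s in s_ids]
    aligner = _aligner(matrix, gap_open, gap_extend)
    scores = (
        _scores
        if _scores is not None
        else _score_matrix(q_seqs, s_seqs, aligner, symmetric=False)
    )
    out: dict[str, AlignmentHit] = {}
    for i, q in enumerate(q_ids):
        candidates: list[AlignmentHit] = []
        best_score = None
        # walk subjects from highest score down; once a passing hit is found,
        # only equal-scoring subjects can still tie
        for j in np.argsort(-scores[i], kind="stable"):
            s = scores[i, j]
            if s <= 0 or (best_score is not None and s < best_score):
                break
            hit = local_align(
                q_seqs[i], s_seqs[j], matrix, gap_open, gap_extend,
                query_id=q, subject_id=s_ids[j],
            )
            if hit is None:
                continue
            if hit.identity >= 100.0 * identity_min and hit.coverage >= coverage_min:
                candidates.append(hit)
                best_score = hit.score
        if candidates:
            out[q] = min(
                candidates, key=lambda h: (-h.score, -h.identity, h.subject_id)
            )
    return out


@dataclass(frozen=True)
class AAIResult:
    genome_a: str
    genome_b: str
    mean_identity: float | None  # None when no orthologs were found
    sd_identity: float
    n_orthologs: int


def aai(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    identity_min: float = 0.30,
    coverage_min: float = 0.70,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    genome_a: str = "A",
    genome_b: str = "B",
) -> AAIResult:
    """Mean and population SD of percent identity over reciprocal best hits.

    Symmetric in its genome arguments.  With zero orthologs the mean is
    ``None`` (flagged, not silently 0).
    """
    if not proteome_a or not proteome_b:
        raise ValidationError("both proteomes must be non-empty")
    a_ids, b_ids = list(proteome_a), list(proteome_b)
    a_seqs = [proteome_a[k] for k in a_ids]
    b_seqs = [proteome_b[k] for k in b_ids]
    aligner = _aligner(matrix, gap_open, gap_extend)
    # scoring is symmetric, so one score matrix serves both directions
    same = a_ids == b_ids and a_seqs == b_seqs
    scores = _score_matrix(a_seqs, b_seqs, aligner, symmetric=same)
    fwd = best_hits(
        proteome_a, proteome_b, identity_min, coverage_min,
        matrix, gap_open, gap_extend, _scores=scores,
    )
    rev = best_hits(
        proteome_b, proteome_a, identity_min, coverage_min,
        matrix, gap_open, gap_extend, _scores=scores.T,
    )
    identities = [
        hit.identity
        for q, hit in fwd.items()
        if rev.get(hit.subject_id) is not None
        and rev[hit.subject_id].subject_id == q
    ]
    n = len(identities)
    if n == 0:
        return AAIResult(genome_a, genome_b, None, 0.0, 0)
    mean = float(np.mean(identities))
    sd = float(np.std(identities)) if n > 1 else 0.0
    return AAIResult(genome_a, genome_b, mean, sd, n)
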