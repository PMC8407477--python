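"""Conserved-gene identification via self-score-normalized global alignment.

A reference strain's CDS set is aligned against every other strain's CDS set
with a global aligner (match +1, mismatch -1, linear gap -1).  Raw scores are
normalized by the self-alignment scores of the two sequences (geometric mean
by default), giving a score of 1 for identical sequences and <= 1 otherwise;
negative raw scores clamp to 0.  A reference CDS whose best hit scores
strictly above 0.5 in *every* annotated strain is designated conserved.
Gene-level cluster distances (1 - normalized score) then summarize how much a
conserved gene differs within versus between strain clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

__all__ = [
    "GeneFamily",
    "normalized_alignment_score",
    "find_conserved_genes",
    "cluster_distance_table",
]

_NORMALIZATIONS = {
    "geometric_mean": lambda a, b: float(np.sqrt(a * b)),
    "min": min,
    "max": max,
    "mean": lambda a, b: (a + b) / 2.0,
}


def _make_aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def normalized_alignment_score(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
    normalization: str = "geometric_mean",
) -> float:
    """Global-alignment score normalized by the two self-alignment scores.

    Symmetric, <= 1, equal to 1 for identical sequences; negative results
    clamp to 0.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    try:
        combine = _NORMALIZATIONS[normalization]
    except KeyError:
        raise ValueError(f"unknown normalization {normalization!r}") from None
    aligner = _make_aligner(match, mismatch, gap)
    raw = aligner.score(seq_a, seq_b)
    denom = combine(match * len(seq_a), match * len(seq_b))
    if denom <= 0:
        raise ValueError("self-alignment scores must be positive")
    return max(0.0, min(1.0, raw / denom))


@dataclass
class GeneFamily:
    """Best hits of one reference CDS across a strain panel."""

    reference_cds_id: str
    reference_sequence: str
    hits: dict  # strain id -> (cds_id, sequence, normalized score)
    conserved: bool


def find_conserved_genes(
    reference_cds: Mapping[str, str],
    strain_cds: Mapping[str, Mapping[str, str]],
    threshold: float = 0.5,
    **score_kwargs,
) -> list[GeneFamily]:
    """Score every reference CDS against every annotated strain's CDS set.

    Strains contributing no CDS are treated as unannotated and excluded with
    a warning.  For each reference CDS the best-scoring CDS per strain is
    recorded (ties broken by longer CDS, then lexicographic id); the family is
    conserved iff its normalized score exceeds ``threshold`` in every included
    strain.
    """
    if not reference_cds:
        raise ValueError("reference CDS set must be non-empty")
    annotated = {}
    for strain, cds_map in strain_cds.items():
        if not cds_map:
            warnings.warn(
                f"strain {strain!r} has no CDS annotation and is excluded",
                stacklevel=2,
            )
            continue
        annotated[strain] = cds_map
    families = []
    for ref_id in sorted(reference_cds):
        ref_seq = reference_cds[ref_id]
        hits = {}
        conserved = True
        for strain, cds_map in annotated.items():
            best = None  # (score, length, cds_id, seq); iterate ids ascending so
            # exact (score, length) ties keep the lexicographically smallest id
            for cds_id in sorted(cds_map):
                seq = cds_map[cds_id]
                score = normalized_alignment_score(ref_seq, seq, **score_kwargs)
                if best is None or (score, len(seq)) > (best[0], best[1]):
                    best = (score, len(seq), cds_id, seq)
            hits[strain] = (best[2], best[3], best[0])
            if best[0] <= threshold:
                conserved = False
        families.append(
            GeneFamily(
                reference_cds_id=ref_id,
                reference_sequence=ref_seq,
                hits=hits,
                conserved=conserved,
            )
        )
    return families


def cluster_distance_table(
    gene_families: Sequence[GeneFamily],
    cluster_assignment: Mapping[str, str],
    **score_kwargs,
) -> pd.DataFrame:
    """Average intra- and inter-cluster distances per conserved gene.

    Distance between two gene copies is ``1 - normalized_alignment_score``.
    Intra averages over within-cluster strain pairs (clusters with >= 2
    carriers), inter over between-cluster pairs; difference = inter - intra.
    Sorted by difference.
    """
    clusters = dict(cluster_assignment)
    rows = []
    for family in gene_families:
        if not family.conserved:
            continue
        carriers = [s for s in family.hits if s in clusters]
        present_clusters = {clusters[s] for s in carriers}
        if len(present_clusters) < 2:
            raise ValueError(
                f"gene {family.reference_cds_id!r}: need carriers in >= 2 clusters"
            )
        intra, inter = [], []
        cache: dict[tuple, float] = {}
        for s1, s2 in combinations(sorted(carriers), 2):
            seq1, seq2 = family.hits[s1][1], family.hits[s2][1]
            key = (seq1, seq2) if seq1 <= seq2 else (seq2, seq1)
            if key not in cache:
                cache[key] = 1.0 - normalized_alignment_score(
                    seq1, seq2, **score_kwargs
                )
            d = cache[key]
            (intra if clusters[s1] == clusters[s2] else inter).append(d)
        if not intra:
            raise ValueError(
                f"gene {family.reference_cds_id!r}: no cluster has >= 2 carriers, "
                "intra-cluster distance undefined"
            )
        rows.append(
            {
                "gene_id": family.reference_cds_id,
                "intra_cluster_distance": float(np.mean(intra)),
                "inter_cluster_distance": float(np.mean(inter)),
                "difference": float(np.mean(inter) - np.mean(intra)),
            }
        )
    if not rows:
        raise ValueError("no conserved gene families supplied")
    return (
        pd.DataFrame(rows)
        .sort_values("difference", kind="stable")
        .reset_index(drop=True)
    )
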