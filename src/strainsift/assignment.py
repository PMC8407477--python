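"""Two-pass competitive/exclusive read reassignment (T1/T2/T3 rules).

Reads surviving the background filter are considered candidates for every
focal genome they validly align to (exclusive mapping).  Competitive
comparison across the focal panel then classifies each candidate alignment:

* **T1** — the read's fewest-mismatch alignment is achieved by this genome
  alone: retained.
* **T2** — some other genome aligns the read with strictly fewer mismatches:
  discarded for this genome.
* **T3** — the minimum mismatch count is achieved by this genome jointly with
  at least one other: assigned conditionally.  A T3 alignment carrying
  mismatches is rejected when it overlaps (shares >= 1 genome base with) a T1
  alignment on the same genome that has strictly fewer mismatches; in every
  other case it is assigned, possibly to several genomes at once.

Alignments with >= 5 mismatches per 100 aligned bases are never considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from .alignment import AlignmentRecord, PanelIndex, _as_read_pairs, _encode_block
from .synthetic import StrainGenome

__all__ = [
    "validity_filter",
    "filter_background",
    "classify_read",
    "resolve_t3",
    "assign_sample",
    "AssignedRead",
    "ReadAssignmentTable",
]

VALIDITY_CUTOFF = 0.05  # "five mismatches per 100 aligned bases"


def validity_filter(
    alignment: AlignmentRecord, max_mismatch_fraction: float = VALIDITY_CUTOFF
) -> bool:
    """True iff the alignment's mismatch rate is strictly below the cutoff."""
    if alignment.aligned_length <= 0:
        raise ValueError("aligned_length must be positive")
    return alignment.n_mismatches / alignment.aligned_length < max_mismatch_fraction


def filter_background(
    read_ids: Iterable[str],
    background_alignments: Iterable[AlignmentRecord],
    max_mismatch_fraction: float = VALIDITY_CUTOFF,
) -> list[str]:
    """Retain exactly the reads with zero valid background alignments."""
    hit = {
        a.read_id
        for a in background_alignments
        if validity_filter(a, max_mismatch_fraction)
    }
    return [r for r in read_ids if r not in hit]


def classify_read(
    read_id: str,
    alignments: Iterable[AlignmentRecord],
    genome_id: str,
    max_mismatch_fraction: float = VALIDITY_CUTOFF,
) -> str:
    """Class of ``read_id`` with respect to ``genome_id``: T1, T2, T3 or none.

    ``alignments`` are the read's candidate alignments across *all* focal
    genomes (at most one per genome); invalid ones are ignored.
    """
    per_genome: dict[str, int] = {}
    for a in alignments:
        if a.read_id != read_id or not validity_filter(a, max_mismatch_fraction):
            continue
        if a.genome_id not in per_genome or a.n_mismatches < per_genome[a.genome_id]:
            per_genome[a.genome_id] = a.n_mismatches
    if not per_genome:
        return "none"
    m_star = min(per_genome.values())
    winners = [g for g, m in per_genome.items() if m == m_star]
    if genome_id not in winners:
        return "T2"
    return "T1" if len(winners) == 1 else "T3"


def resolve_t3(
    t3_alignment: AlignmentRecord,
    t1_alignments: Iterable[AlignmentRecord],
    min_overlap: int = 1,
) -> bool:
    """Whether a T3 alignment on G is assigned to G.

    Rejected only when it carries at least one mismatch *and* some T1
    alignment on the same genome overlaps it by >= ``min_overlap`` bases with
    strictly fewer mismatches; assigned in all other cases (in particular, a
    perfect T3 alignment is always assigned).
    """
    if t3_alignment.n_mismatches == 0:
        return True
    for t1 in t1_alignments:
        if t1.genome_id != t3_alignment.genome_id:
            continue
        overlap = min(t1.end, t3_alignment.end) - max(t1.start, t3_alignment.start)
        if overlap >= min_overlap and t1.n_mismatches < t3_alignment.n_mismatches:
            return False
    return True


@dataclass(frozen=True)
class AssignedRead:
    read_id: str
    alignment: AlignmentRecord
    label: str  # "T1" or "T3"


@dataclass
class ReadAssignmentTable:
    """Final per-genome read assignments of one sample."""

    assignments: dict[str, list[AssignedRead]]
    total_reads: int = 0

    def key_set(self) -> set:
        """Hashable identity of the table (for exact comparisons)."""
        return {
            (g, a.read_id, a.label, a.alignment.start, a.alignment.strand,
             a.alignment.n_mismatches)
            for g, lst in self.assignments.items()
            for a in lst
        }

    def to_frame(self, sample_id: str = "S0") -> pd.DataFrame:
        rows = [
            {
                "sample_id": sample_id,
                "genome_id": g,
                "read_id": a.read_id,
                "class": a.label,
                "start": a.alignment.start,
                "aligned_length": a.alignment.aligned_length,
                "strand": a.alignment.strand,
                "n_mismatches": a.alignment.n_mismatches,
            }
            for g, lst in self.assignments.items()
            for a in lst
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id", "genome_id", "read_id", "class", "start",
                "aligned_length", "strand", "n_mismatches",
            ],
        )


def _best_per_read_genome(cols: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Reduce all valid placements to one candidate per (read, genome).

    Order of preference: fewest mismatches, then leftmost start, then plus
    strand — a deterministic total order.
    """
    read, genome = cols["read"], cols["genome"]
    if read.size == 0:
        return {k: v for k, v in cols.items()}
    order = np.lexsort((cols["strand"], cols["start"], cols["nmm"], genome, read))
    read_o, genome_o = read[order], genome[order]
    first = np.ones(read_o.size, dtype=bool)
    first[1:] = (read_o[1:] != read_o[:-1]) | (genome_o[1:] != genome_o[:-1])
    keep = order[first]
    return {k: v[keep] for k, v in cols.items()}


def _assign_columns(
    cols: Mapping[str, np.ndarray], read_length: int, n_genomes: int,
    genome_lengths: np.ndarray,
) -> dict[str, np.ndarray]:
    """Columnar T1/T2/T3 classification and T3 resolution.

    ``cols`` holds one candidate alignment per (read, genome); returns the
    assigned subset with an extra ``label`` array (1 = T1, 3 = T3).
    Assumes every alignment spans exactly ``read_length`` bases, which lets
    the overlap test reduce to a sliding-window minimum over T1 start
    positions.
    """
    read, genome, nmm = cols["read"], cols["genome"], cols["nmm"]
    if read.size == 0:
        return {**{k: v for k, v in cols.items()}, "label": np.empty(0, dtype=np.int64)}
    n_reads = int(read.max()) + 1
    m_star = np.full(n_reads, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(m_star, read, nmm)
    at_min = nmm == m_star[read]
    n_winners = np.zeros(n_reads, dtype=np.int64)
    np.add.at(n_winners, read[at_min], 1)
    is_t1 = at_min & (n_winners[read] == 1)
    is_t3 = at_min & (n_winners[read] > 1)

    keep = is_t1.copy()
    t3_keep_global = np.zeros(read.size, dtype=bool)
    L = read_length
    for gi in range(n_genomes):
        g_mask = genome == gi
        t3_idx = np.flatnonzero(g_mask & is_t3)
        if t3_idx.size == 0:
            continue
        t1_idx = np.flatnonzero(g_mask & is_t1)
        glen = int(genome_lengths[gi])
        # min T1 mismatch count by start position, then sliding minimum over
        # every start within +/- (L-1), i.e. every potentially overlapping T1.
        # sentinel L+1 exceeds any possible mismatch count (and survives the
        # filter's internal float round trip, unlike INT64_MAX)
        sentinel = np.int64(L + 1)
        a = np.full(glen, sentinel, dtype=np.int64)
        if t1_idx.size:
            np.minimum.at(a, cols["start"][t1_idx], nmm[t1_idx])
        window_min = minimum_filter1d(a, size=2 * L - 1, mode="constant", cval=sentinel)
        t3_nmm = nmm[t3_idx]
        t3_start = cols["start"][t3_idx]
        rejected = (t3_nmm > 0) & (window_min[t3_start] < t3_nmm)
        t3_keep_global[t3_idx[~rejected]] = True
    keep |= t3_keep_global
    out = {k: v[keep] for k, v in cols.items()}
    out["label"] = np.where(is_t1[keep], 1, 3).astype(np.int64)
    return out


def assign_sample_arrays(
    read_codes: np.ndarray,
    focal_index: PanelIndex,
    background_index: PanelIndex | None = None,
    max_mismatch_fraction: float = VALIDITY_CUTOFF,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Columnar end-to-end assignment for one sample.

    Returns ``(assigned, background_hit)`` where ``assigned`` holds the
    columnar assigned alignments (read, genome, start, strand, nmm, label)
    and ``background_hit`` flags reads removed by the background filter.
    """
    n_reads, L = read_codes.shape
    background_hit = np.zeros(n_reads, dtype=bool)
    if background_index is not None:
        bg = background_index.find_valid(read_codes, max_mismatch_fraction)
        background_hit[np.unique(bg["read"])] = True
    survivors = np.flatnonzero(~background_hit)
    if survivors.size == 0:
        empty = {
            k: np.empty(0, dtype=np.int64)
            for k in ("read", "genome", "start", "strand", "nmm", "label")
        }
        return empty, background_hit
    cols = focal_index.find_valid(read_codes[survivors], max_mismatch_fraction)
    cols = _best_per_read_genome(cols)
    assigned = _assign_columns(
        cols, L, len(focal_index.genome_ids), focal_index.lengths
    )
    assigned["read"] = survivors[assigned["read"]]  # back to original indices
    return assigned, background_hit


def assign_sample(
    reads: Iterable,
    focal_genomes: Sequence[StrainGenome],
    background_genomes: Sequence[StrainGenome] = (),
    max_mismatch_fraction: float = VALIDITY_CUTOFF,
    k: int = 21,
) -> ReadAssignmentTable:
    """Run background filtering plus T1/T2/T3 assignment on one sample.

    ``reads`` may be :class:`~strainsift.synthetic.SimulatedRead` objects or
    ``(read_id, sequence)`` pairs of equal length.  The result is a pure
    function of the inputs (no randomness).
    """
    if not focal_genomes:
        raise ValueError("focal genome panel must be non-empty")
    ids, seqs = _as_read_pairs(reads)
    if not ids:
        return ReadAssignmentTable(
            assignments={g.id: [] for g in focal_genomes}, total_reads=0
        )
    codes = _encode_block(seqs, len(seqs[0]))
    focal_index = PanelIndex(focal_genomes, k=k)
    background_index = PanelIndex(background_genomes, k=k) if background_genomes else None
    assigned, _ = assign_sample_arrays(
        codes, focal_index, background_index, max_mismatch_fraction
    )
    L = codes.shape[1]
    table: dict[str, list[AssignedRead]] = {g.id: [] for g in focal_genomes}
    order = np.lexsort((assigned["start"], assigned["read"], assigned["genome"]))
    for i in order:
        gid = focal_index.genome_ids[assigned["genome"][i]]
        rec = AlignmentRecord(
            read_id=ids[assigned["read"][i]],
            genome_id=gid,
            start=int(assigned["start"][i]),
            aligned_length=L,
            n_mismatches=int(assigned["nmm"][i]),
            strand="+" if assigned["strand"][i] == 0 else "-",
        )
        table[gid].append(
            AssignedRead(
                read_id=rec.read_id,
                alignment=rec,
                label="T1" if assigned["label"][i] == 1 else "T3",
            )
        )
    return ReadAssignmentTable(assignments=table, total_reads=len(ids))
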