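"""Mismatch-tolerant ungapped read mapping.

The built-in mapper is exact-seed / ungapped-extend: disjoint seed k-mers are
looked up in a panel-wide index and every implied end-to-end placement is
verified by a full Hamming count.  Because the number of disjoint seeds always
exceeds the largest mismatch count an alignment may carry and still pass the
validity cutoff (< 5 mismatches per 100 aligned bases by default), at least
one seed of any valid placement is exact, so the mapper reports *every* valid
placement on both strands — the property the reassignment rules downstream
rely on.  External aligners can substitute through the SAM reader in
:mod:`strainsift.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import encode, kmer_values, kmers_at
from .synthetic import SimulatedRead, StrainGenome

__all__ = ["AlignmentRecord", "PanelIndex", "map_reads", "max_valid_mismatches"]


@dataclass(frozen=True)
class AlignmentRecord:
    """One end-to-end read-to-genome placement.

    ``start`` is 0-based on the forward strand of the genome;
    ``strand`` is "+" or "-" (read sequence reverse-complemented before
    comparison); ``n_mismatches`` is the exact Hamming distance of the
    strand-resolved read against the genome window.
    """

    read_id: str
    genome_id: str
    start: int
    aligned_length: int
    n_mismatches: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.aligned_length <= 0:
            raise ValueError("aligned_length must be positive")
        if self.n_mismatches > self.aligned_length:
            raise ValueError("n_mismatches cannot exceed aligned_length")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def end(self) -> int:
        """0-based exclusive end on the genome."""
        return self.start + self.aligned_length


def max_valid_mismatches(aligned_length: int, max_mismatch_fraction: float = 0.05) -> int:
    """Largest mismatch count strictly below ``fraction * length`` (may be -1)."""
    return math.ceil(max_mismatch_fraction * aligned_length) - 1


def _as_read_pairs(
    reads: Iterable,
) -> tuple[list[str], list[str]]:
    ids, seqs = [], []
    for r in reads:
        if isinstance(r, SimulatedRead):
            ids.append(r.read_id)
            seqs.append(r.sequence)
        elif isinstance(r, tuple):
            ids.append(r[0])
            seqs.append(r[1])
        else:  # anything with .read_id/.id and .sequence
            ids.append(getattr(r, "read_id", None) or r.id)
            seqs.append(r.sequence)
    return ids, seqs


class PanelIndex:
    """k-mer index over a panel of genomes (all overlapping k-mer positions)."""

    def __init__(self, genomes: Sequence[StrainGenome], k: int = 21):
        if not genomes:
            raise ValueError("cannot index an empty genome panel")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.genome_ids = [g.id for g in genomes]
        self.lengths = np.array([len(g) for g in genomes], dtype=np.int64)
        if self.lengths.min() < k:
            raise ValueError("every genome must be at least k bases long")
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.concat = np.concatenate([encode(g.sequence) for g in genomes])
        self._index_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._build(k)

    def _build(self, k: int) -> None:
        if k in self._index_cache:
            return
        kmers, positions = [], []
        for gi in range(len(self.genome_ids)):
            lo, hi = self.offsets[gi], self.offsets[gi + 1]
            vals = kmer_values(self.concat[lo:hi], k)
            kmers.append(vals)
            positions.append(np.arange(lo, lo + vals.size, dtype=np.int64))
        kmers = np.concatenate(kmers)
        positions = np.concatenate(positions)
        order = np.argsort(kmers, kind="stable")
        self._index_cache[k] = (kmers[order], positions[order])

    def _genome_of(self, global_pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, global_pos, side="right") - 1

    def find_valid(
        self,
        read_codes: np.ndarray,
        max_mismatch_fraction: float = 0.05,
        chunk: int = 1_000_000,
    ) -> dict[str, np.ndarray]:
        """All valid end-to-end placements of a (n_reads, L) code matrix.

        Returns columnar arrays: read (row index), genome (panel index),
        start (0-based, genome-local), strand (0 plus / 1 minus), nmm.
        """
        n_reads, L = read_codes.shape
        m_max = max_valid_mismatches(L, max_mismatch_fraction)
        if m_max < 0:
            return {
                key: np.empty(0, dtype=np.int64)
                for key in ("read", "genome", "start", "strand", "nmm")
            }
        n_seeds = m_max + 1
        k_eff = min(self.k, L // n_seeds)
        if k_eff < 1:
            raise ValueError(
                f"reads of length {L} cannot host {n_seeds} disjoint seeds; "
                "lower max_mismatch_fraction or use longer reads"
            )
        self._build(k_eff)
        sorted_kmers, sorted_pos = self._index_cache[k_eff]
        seed_offsets = np.arange(n_seeds, dtype=np.int64) * k_eff

        out = {key: [] for key in ("read", "genome", "start", "strand", "nmm")}
        total_len = int(self.offsets[-1])
        for strand in (0, 1):
            codes = read_codes if strand == 0 else (3 - read_codes[:, ::-1])
            seed_vals = kmers_at(codes, seed_offsets, k_eff)  # (n_reads, n_seeds)
            flat = seed_vals.ravel()
            lo = np.searchsorted(sorted_kmers, flat, side="left")
            hi = np.searchsorted(sorted_kmers, flat, side="right")
            counts = hi - lo
            if counts.sum() == 0:
                continue
            seed_idx = np.repeat(np.arange(flat.size), counts)
            total_hits = int(counts.sum())
            cum = np.concatenate([[0], np.cumsum(counts)])
            within = np.arange(total_hits) - np.repeat(cum[:-1], counts)
            hit_pos = sorted_pos[np.repeat(lo, counts) + within]
            read_idx = seed_idx // n_seeds
            offs = seed_offsets[seed_idx % n_seeds]
            diag = hit_pos - offs  # global start of the implied placement
            gi = self._genome_of(np.clip(diag, 0, total_len - 1))
            ok = (diag >= self.offsets[gi]) & (diag + L <= self.offsets[gi + 1])
            read_idx, diag, gi = read_idx[ok], diag[ok], gi[ok]
            # dedupe candidates implied by several seeds
            key = read_idx * total_len + diag
            _, keep = np.unique(key, return_index=True)
            read_idx, diag, gi = read_idx[keep], diag[keep], gi[keep]
            # verify by exact Hamming count, in chunks
            for c0 in range(0, read_idx.size, chunk):
                sl = slice(c0, c0 + chunk)
                windows = self.concat[diag[sl, None] + np.arange(L)[None, :]]
                nmm = (windows != codes[read_idx[sl]]).sum(axis=1)
                valid = nmm <= m_max
                out["read"].append(read_idx[sl][valid])
                out["genome"].append(gi[sl][valid])
                out["start"].append(diag[sl][valid] - self.offsets[gi[sl][valid]])
                out["strand"].append(np.full(int(valid.sum()), strand, dtype=np.int64))
                out["nmm"].append(nmm[valid].astype(np.int64))
        return {
            key: (np.concatenate(v) if v else np.empty(0, dtype=np.int64))
            for key, v in out.items()
        }


def encode_reads(seqs: Sequence[str]) -> np.ndarray:
    """Stack equal-length read sequences into an (n, L) uint8 code matrix."""
    if not seqs:
        raise ValueError("no reads supplied")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all reads in one batch must have equal length")
    return _encode_block(seqs, L)


def _encode_block(seqs: Sequence[str], L: int) -> np.ndarray:
    flat = encode("".join(seqs))
    return flat.reshape(len(seqs), L)


def map_reads(
    reads: Iterable,
    genome: StrainGenome | Sequence[StrainGenome],
    max_mismatch_fraction: float = 0.05,
    k: int = 21,
) -> list[AlignmentRecord]:
    """Report every valid end-to-end placement of each read on the genome(s).

    A placement is valid when its exact Hamming distance is strictly below
    ``max_mismatch_fraction * aligned_length``.  Both strands are searched.
    Records are ordered by (read, genome, n_mismatches, start, strand).
    """
    genomes = [genome] if isinstance(genome, StrainGenome) else list(genome)
    if not genomes:
        raise ValueError("empty genome panel")
    ids, seqs = _as_read_pairs(reads)
    if not ids:
        raise ValueError("no reads supplied")
    index = PanelIndex(genomes, k=k)
    codes = _encode_block(seqs, len(seqs[0]))
    cols = index.find_valid(codes, max_mismatch_fraction)
    L = codes.shape[1]
    order = np.lexsort(
        (cols["strand"], cols["start"], cols["nmm"], cols["genome"], cols["read"])
    )
    return [
        AlignmentRecord(
            read_id=ids[cols["read"][i]],
            genome_id=index.genome_ids[cols["genome"][i]],
            start=int(cols["start"][i]),
            aligned_length=L,
            n_mismatches=int(cols["nmm"][i]),
            strand="+" if cols["strand"][i] == 0 else "-",
        )
        for i in order
    ]
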