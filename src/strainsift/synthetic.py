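"""Synthetic strain communities with known ground truth.

This module is the in-silico stand-in for a real shotgun experiment: a panel
of closely related focal strain genomes (descendants of a shared ancestor at a
controlled per-site divergence), a set of unrelated background genomes, random
community compositions (1-10 focal strains mixed with 1-100 background genomes
at Dirichlet read fractions), and 100 bp single-end reads carrying at most
five substitutions each.  Because every read records its genome of origin, the
simulator also emits the true per-genome coverage, depth, and abundance that
the profiling pipeline is benchmarked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import decode, encode

__all__ = [
    "StrainGenome",
    "CommunityComposition",
    "SimulatedRead",
    "generate_strain_panel",
    "sample_community",
    "simulate_reads",
    "simulate_profile_cohort",
]

FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class StrainGenome:
    """A named nucleotide sequence, optionally annotated with CDS intervals.

    ``cds_intervals`` entries are (start, end, strand, gene_id) in 0-based
    half-open coordinates on the forward strand.
    """

    id: str
    sequence: str
    is_focal: bool = True
    cds_intervals: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.id!r}: sequence must be non-empty")
        encode(self.sequence)  # validates the alphabet
        if self.cds_intervals is not None:
            object.__setattr__(self, "cds_intervals", tuple(self.cds_intervals))
            for start, end, strand, gene_id in self.cds_intervals:
                if not (0 <= start < end <= len(self.sequence)):
                    raise ValueError(
                        f"genome {self.id!r}: CDS {gene_id!r} interval "
                        f"[{start}, {end}) outside [0, {len(self.sequence)})"
                    )
                if strand not in "+-":
                    raise ValueError(f"CDS {gene_id!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CommunityComposition:
    """Ground-truth recipe of one simulated sample."""

    focal_ids: tuple
    background_ids: tuple
    read_fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "focal_ids", tuple(self.focal_ids))
        object.__setattr__(self, "background_ids", tuple(self.background_ids))
        object.__setattr__(self, "read_fractions", dict(self.read_fractions))
        total = sum(self.read_fractions.values())
        if abs(total - 1.0) > FRACTION_TOL:
            raise ValueError(f"read fractions sum to {total!r}, expected 1")
        focal, background = set(self.focal_ids), set(self.background_ids)
        if focal & background:
            raise ValueError("a genome id appears in both the focal and background lists")
        if set(self.read_fractions) != focal | background:
            raise ValueError("read_fractions keys must be exactly the selected genome ids")
        if not 1 <= len(self.focal_ids) <= 10:
            raise ValueError("between 1 and 10 focal strains per sample")
        if not 1 <= len(self.background_ids) <= 100:
            raise ValueError("between 1 and 100 background genomes per sample")

    @property
    def genome_ids(self) -> tuple:
        return self.focal_ids + self.background_ids


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    true_genome_id: str
    true_position: int
    n_substitutions: int
    strand: str = "+"


def generate_strain_panel(
    ancestor_length: int,
    n_strains: int,
    divergence: float,
    seed: int,
    *,
    id_prefix: str = "strain",
    is_focal: bool = True,
) -> list[StrainGenome]:
    """Derive ``n_strains`` genomes from one random ancestor.

    Each genome receives independent per-site substitutions at rate
    ``divergence`` (so two panel members differ at roughly
    ``2 * divergence`` of their sites).  The ancestor is i.i.d. uniform over
    A/C/G/T.  Deterministic for a fixed seed.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if ancestor_length < 1:
        raise ValueError("ancestor_length must be positive")
    if not 0.0 <= divergence <= 0.25:
        raise ValueError("divergence must lie in [0, 0.25]")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=ancestor_length, dtype=np.uint8)
    panel = []
    for i in range(n_strains):
        codes = ancestor.copy()
        mask = rng.random(ancestor_length) < divergence
        n_mut = int(mask.sum())
        if n_mut:
            shifts = rng.integers(1, 4, size=n_mut, dtype=np.uint8)
            codes[mask] = (codes[mask] + shifts) % 4
        panel.append(
            StrainGenome(id=f"{id_prefix}{i:03d}", sequence=decode(codes), is_focal=is_focal)
        )
    return panel


def sample_community(
    focal_panel: Sequence[StrainGenome],
    background_panel: Sequence[StrainGenome],
    seed: int,
    *,
    max_focal: int = 10,
    max_background: int = 100,
) -> CommunityComposition:
    """Draw one random community: 1-10 focal strains, 1-100 background genomes
    (capped by panel sizes), with symmetric Dirichlet(1) read fractions."""
    if not focal_panel:
        raise ValueError("focal panel must contain at least one genome")
    if not background_panel:
        raise ValueError("background panel must contain at least one genome")
    rng = np.random.default_rng(seed)
    n_focal = int(rng.integers(1, min(max_focal, len(focal_panel)) + 1))
    n_background = int(rng.integers(1, min(max_background, len(background_panel)) + 1))
    focal_ids = tuple(
        focal_panel[i].id for i in rng.choice(len(focal_panel), size=n_focal, replace=False)
    )
    background_ids = tuple(
        background_panel[i].id
        for i in rng.choice(len(background_panel), size=n_background, replace=False)
    )
    ids = focal_ids + background_ids
    fractions = rng.dirichlet(np.ones(len(ids)))
    while fractions.min() <= 0.0:  # astronomically rare; keeps fractions strictly positive
        fractions = rng.dirichlet(np.ones(len(ids)))
    return CommunityComposition(
        focal_ids=focal_ids,
        background_ids=background_ids,
        read_fractions=dict(zip(ids, fractions.tolist())),
    )


def _resolve_genomes(
    genomes: Iterable[StrainGenome] | Mapping[str, StrainGenome],
) -> dict[str, StrainGenome]:
    if isinstance(genomes, Mapping):
        return dict(genomes)
    return {g.id: g for g in genomes}


def _simulate_read_arrays(
    composition: CommunityComposition,
    genome_codes: Mapping[str, np.ndarray],
    n_reads: int,
    read_length: int,
    max_substitutions: int,
    substitution_rate: float,
    rng: np.random.Generator,
):
    """Columnar core of the read simulator.

    Returns (codes (n_reads, L) uint8, origin_index, starts, strands, n_subs)
    where origin_index indexes ``composition.genome_ids``.  Substitutions are
    applied on the forward-strand window; minus-strand reads are then
    reverse-complemented into sequencing orientation.
    """
    ids = list(composition.genome_ids)
    fractions = np.array([composition.read_fractions[g] for g in ids])
    for g in ids:
        if genome_codes[g].size < read_length:
            raise ValueError(f"genome {g!r} is shorter than the read length {read_length}")
    counts = rng.multinomial(n_reads, fractions)
    origin = np.repeat(np.arange(len(ids)), counts)
    starts = np.empty(n_reads, dtype=np.int64)
    pos = 0
    for gi, c in enumerate(counts):
        if c:
            hi = genome_codes[ids[gi]].size - read_length + 1
            starts[pos : pos + c] = rng.integers(0, hi, size=c)
        pos += c
    strands = rng.random(n_reads) < 0.5  # True = minus strand
    n_subs = np.minimum(
        rng.binomial(read_length, substitution_rate, size=n_reads), max_substitutions
    ).astype(np.int64)

    codes = np.empty((n_reads, read_length), dtype=np.uint8)
    offs = np.arange(read_length)
    pos = 0
    for gi, c in enumerate(counts):
        if c:
            codes[pos : pos + c] = genome_codes[ids[gi]][starts[pos : pos + c, None] + offs]
        pos += c

    # distinct substitution positions per read, grouped by substitution count
    for s in range(1, max_substitutions + 1):
        rows = np.flatnonzero(n_subs == s)
        if rows.size == 0:
            continue
        scores = rng.random((rows.size, read_length), dtype=np.float32)
        sub_pos = np.argpartition(scores, s - 1, axis=1)[:, :s]
        shifts = rng.integers(1, 4, size=sub_pos.shape, dtype=np.uint8)
        r = np.repeat(rows, s)
        p = sub_pos.ravel()
        codes[r, p] = (codes[r, p] + shifts.ravel()) % 4

    minus = np.flatnonzero(strands)
    codes[minus] = 3 - codes[minus][:, ::-1]
    return codes, origin, starts, strands, n_subs


def _truth_from_origins(
    composition: CommunityComposition,
    genome_codes: Mapping[str, np.ndarray],
    origin: np.ndarray,
    starts: np.ndarray,
    read_length: int,
    n_reads: int,
    sample_id: str,
) -> pd.DataFrame:
    rows = []
    ids = list(composition.genome_ids)
    for gi, gid in enumerate(ids):
        length = genome_codes[gid].size
        g_starts = starts[origin == gi]
        diff = np.zeros(length + 1, dtype=np.int64)
        np.add.at(diff, g_starts, 1)
        np.add.at(diff, g_starts + read_length, -1)
        pile = np.cumsum(diff[:-1])
        rows.append(
            {
                "sample_id": sample_id,
                "genome_id": gid,
                "true_coverage": float((pile > 0).mean()),
                "true_depth": float(pile.mean()),
                "true_abundance": g_starts.size / n_reads,
            }
        )
    return pd.DataFrame(rows)


def simulate_reads(
    composition: CommunityComposition,
    genomes: Iterable[StrainGenome] | Mapping[str, StrainGenome],
    n_reads: int,
    *,
    read_length: int = 100,
    max_substitutions: int = 5,
    substitution_rate: float = 0.01,
    seed: int = 0,
    sample_id: str = "S0",
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate one sample's shotgun reads plus its ground-truth table.

    Reads are drawn multinomially across the composition's genomes, start
    positions uniformly, strands with probability 1/2 each; every read carries
    Binomial(read_length, substitution_rate) substitutions capped at
    ``max_substitutions``, at distinct positions, each to a different base.

    The truth table has one row per composition genome with columns
    sample_id, genome_id, true_coverage, true_depth, true_abundance.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    registry = _resolve_genomes(genomes)
    genome_codes = {g: encode(registry[g].sequence) for g in composition.genome_ids}
    rng = np.random.default_rng(seed)
    codes, origin, starts, strands, n_subs = _simulate_read_arrays(
        composition, genome_codes, n_reads, read_length, max_substitutions,
        substitution_rate, rng,
    )
    ids = list(composition.genome_ids)
    reads = [
        SimulatedRead(
            read_id=f"{sample_id}:r{i:06d}",
            sequence=decode(codes[i]),
            true_genome_id=ids[origin[i]],
            true_position=int(starts[i]),
            n_substitutions=int(n_subs[i]),
            strand="-" if strands[i] else "+",
        )
        for i in range(n_reads)
    ]
    truth = _truth_from_origins(
        composition, genome_codes, origin, starts, read_length, n_reads, sample_id
    )
    return reads, truth


def simulate_profile_cohort(
    n_clusters: int = 5,
    strains_per_cluster: int = 4,
    n_samples_per_group: int = 50,
    depleted_clusters: Sequence[int] = (0, 1, 2, 4),
    depletion: float = 0.3,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Simulate a two-group cohort of strain profiles with cluster structure.

    Emulates a case/control design in which strains fall into coverage
    clusters: member strains of one cluster rise and fall together across
    samples, clusters listed in ``depleted_clusters`` have their presence
    intensity multiplied by ``depletion`` in the disease group, and the
    remaining clusters are insensitive to disease status.  Returns
    ``(profile, true_clusters)`` where ``profile`` is a
    :class:`~strainsift.profiling.StrainProfileMatrix` with group labels
    "HC"/"LC" and ``true_clusters`` maps strain id -> cluster label.
    """
    from .profiling import StrainProfileMatrix

    rng = np.random.default_rng(seed)
    strain_ids, clusters = [], {}
    for c in range(n_clusters):
        for s in range(strains_per_cluster):
            sid = f"c{c}s{s}"
            strain_ids.append(sid)
            clusters[sid] = f"C{c + 1}"
    samples = [f"HC{i:03d}" for i in range(n_samples_per_group)] + [
        f"LC{i:03d}" for i in range(n_samples_per_group)
    ]
    groups = pd.Series(
        ["HC"] * n_samples_per_group + ["LC"] * n_samples_per_group, index=samples
    )
    cov = np.empty((len(samples), len(strain_ids)))
    dep = np.empty_like(cov)
    for j, sample in enumerate(samples):
        is_lc = groups[sample] == "LC"
        for c in range(n_clusters):
            base = rng.beta(5, 2)
            if is_lc and c in depleted_clusters:
                base *= depletion
            for s in range(strains_per_cluster):
                col = c * strains_per_cluster + s
                cov[j, col] = np.clip(base + rng.normal(0, noise_sd), 0.0, 1.0)
                dep[j, col] = cov[j, col] * rng.uniform(8, 15)
    totals = dep.sum(axis=1, keepdims=True) + 20.0  # background share of the sample
    abundance = dep / totals
    coverage = pd.DataFrame(cov, index=samples, columns=strain_ids)
    depth = pd.DataFrame(dep, index=samples, columns=strain_ids)
    abund = pd.DataFrame(abundance, index=samples, columns=strain_ids)
    profile = StrainProfileMatrix(coverage=coverage, depth=depth, abundance=abund, groups=groups)
    return profile, pd.Series(clusters)
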