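"""Pileup SNP calling, strain prevalence filtering, and SNP-density statistics.

The caller mirrors the threshold semantics of the common external callers
rather than their genotype-likelihood machinery: a variant is emitted at a
column when, counting only bases at or above the pileup's base-quality floor,
total depth >= 10, the most frequent non-reference base is seen >= 4 times,
and its frequency is >= 0.2 (all inclusive, all configurable).  Users running
two external callers can intersect their call sets with
:func:`intersect_calls`, keeping the dual-caller confirmation step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from ._seq import BASES, encode
from .alignment import AlignmentRecord
from .profiling import StrainProfileMatrix
from .synthetic import StrainGenome

__all__ = [
    "SNPCall",
    "Pileup",
    "call_snps",
    "intersect_calls",
    "prevalence_filter",
    "snp_density_per_sample",
    "density_group_test",
    "downsample_reads",
    "storey_qvalues",
]


@dataclass(frozen=True)
class SNPCall:
    genome_id: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int
    alt_frequency: float

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        if self.alt_count > self.depth:
            raise ValueError("alt_count cannot exceed depth")

    @property
    def key(self) -> tuple:
        return (self.genome_id, self.position, self.ref_base, self.alt_base)


@dataclass
class Pileup:
    """Per-position base counts over one genome.

    ``counts`` is (L, 4) in A/C/G/T order; only bases whose quality met
    ``min_base_quality`` at construction time are counted.
    """

    genome_id: str
    ref_codes: np.ndarray
    counts: np.ndarray
    min_base_quality: int = 15

    @classmethod
    def from_alignments(
        cls,
        genome: StrainGenome,
        alignments: Iterable[AlignmentRecord],
        read_sequences: Mapping[str, str],
        read_qualities: Mapping[str, str] | None = None,
        min_base_quality: int = 15,
    ) -> "Pileup":
        """Stack ungapped alignments into base counts.

        Read sequences are given in sequencing orientation; minus-strand
        alignments are reverse-complemented (and their quality strings
        reversed) before stacking.  Bases with Phred quality below
        ``min_base_quality`` are dropped.
        """
        ref = encode(genome.sequence)
        counts = np.zeros((ref.size, 4), dtype=np.int64)
        for a in alignments:
            if a.genome_id != genome.id:
                continue
            seq = read_sequences[a.read_id]
            qual = read_qualities[a.read_id] if read_qualities else None
            codes = encode(seq)
            if a.strand == "-":
                codes = (3 - codes)[::-1]
                qual = qual[::-1] if qual else None
            if codes.size != a.aligned_length or a.end > ref.size:
                raise ValueError(f"alignment of {a.read_id!r} out of bounds")
            pos = np.arange(a.start, a.end)
            if qual is not None:
                phred = np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33
                mask = phred >= min_base_quality
                pos, codes = pos[mask], codes[mask]
            np.add.at(counts, (pos, codes), 1)
        return cls(
            genome_id=genome.id, ref_codes=ref, counts=counts,
            min_base_quality=min_base_quality,
        )

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def callable_length(self, min_depth: int = 10) -> int:
        """Number of positions with depth >= ``min_depth`` (the density
        denominator)."""
        return int((self.depth >= min_depth).sum())


def call_snps(
    pileup: Pileup,
    min_depth: int = 10,
    min_alt_reads: int = 4,
    min_var_freq: float = 0.2,
) -> list[SNPCall]:
    """Emit a call wherever the depth / alt-count / alt-frequency thresholds
    are all met (inclusive).

    The alternate allele is the most frequent non-reference base (ties broken
    in A<C<G<T order).  Base-quality filtering happens when the pileup is
    built.
    """
    counts = pileup.counts
    if counts.ndim != 2 or counts.shape[1] != 4 or (counts < 0).any():
        raise ValueError("malformed pileup: counts must be (L, 4) and non-negative")
    depth = counts.sum(axis=1)
    alt_counts = counts.copy()
    alt_counts[np.arange(counts.shape[0]), pileup.ref_codes] = 0
    alt_base = alt_counts.argmax(axis=1)
    alt_n = alt_counts[np.arange(counts.shape[0]), alt_base]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, alt_n / np.maximum(depth, 1), 0.0)
    hit = (depth >= min_depth) & (alt_n >= min_alt_reads) & (freq >= min_var_freq)
    return [
        SNPCall(
            genome_id=pileup.genome_id,
            position=int(i),
            ref_base=BASES[pileup.ref_codes[i]],
            alt_base=BASES[alt_base[i]],
            depth=int(depth[i]),
            alt_count=int(alt_n[i]),
            alt_frequency=float(freq[i]),
        )
        for i in np.flatnonzero(hit)
    ]


def intersect_calls(
    calls_a: Iterable[SNPCall], calls_b: Iterable[SNPCall]
) -> list[SNPCall]:
    """Calls confirmed by both callers: matching (genome, position, ref, alt);
    fields taken from ``calls_a``."""
    keys_b = {c.key for c in calls_b}
    return [c for c in calls_a if c.key in keys_b]


def prevalence_filter(
    profile: StrainProfileMatrix,
    min_coverage: float = 0.40,
    min_depth: float = 10.0,
    min_samples_per_group: int = 20,
) -> list[str]:
    """Strains prevalent enough to anchor SNP comparisons.

    A strain is retained when it exceeds *both* thresholds (strictly:
    coverage > 40%, depth > 10x) in at least ``min_samples_per_group`` samples
    within **each** group.
    """
    if profile.groups is None:
        raise ValueError("profile matrix must carry group labels")
    levels = sorted(profile.groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, found {levels}")
    qualifies = (profile.coverage > min_coverage) & (profile.depth > min_depth)
    retained = []
    for strain in profile.strains:
        ok = all(
            int(qualifies.loc[profile.groups == g, strain].sum())
            >= min_samples_per_group
            for g in levels
        )
        if ok:
            retained.append(strain)
    return retained


def snp_density_per_sample(n_calls: int, covered_length_bp: int) -> float:
    """SNPs per kilobase of callable sequence."""
    if covered_length_bp <= 0:
        raise ValueError("covered_length_bp must be positive")
    if n_calls < 0:
        raise ValueError("n_calls must be >= 0")
    return 1000.0 * n_calls / covered_length_bp


def storey_qvalues(p_values: Sequence[float], lambda_: float = 0.5) -> np.ndarray:
    """Storey-style q-values with a single-lambda pi0 estimate."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    pi0 = min(1.0, (p > lambda_).mean() / (1.0 - lambda_)) if m else 1.0
    pi0 = max(pi0, 1.0 / m) if m else 1.0
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, pi0 * p[i] * m / (rank + 1))
        q[i] = running
    return q


def density_group_test(
    densities: pd.DataFrame,
    group_labels: pd.Series,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-strain two-sided Mann-Whitney comparison of SNP densities.

    ``densities`` is samples x strains; ``fdr_method`` is "bh"
    (Benjamini-Hochberg, default) or "storey".  Returns a DataFrame with
    columns strain_id, p_value, q_value.
    """
    groups = pd.Series(group_labels).reindex(densities.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, found {levels}")
    if densities.shape[1] < 1:
        raise ValueError("at least one strain required")
    rows = []
    for strain in densities.columns:
        x = densities.loc[groups == levels[0], strain].dropna()
        y = densities.loc[groups == levels[1], strain].dropna()
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"strain {strain!r}: empty group")
        p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append({"strain_id": strain, "p_value": p})
    out = pd.DataFrame(rows)
    if fdr_method == "bh":
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    elif fdr_method == "storey":
        out["q_value"] = storey_qvalues(out["p_value"].to_numpy())
    else:
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    return out


def downsample_reads(
    reads_by_sample: Mapping[str, Sequence],
    outlier_threshold: int,
    seed: int,
) -> dict[str, list]:
    """Downsample outlier samples to the pre-downsampling population mean.

    Samples whose read count exceeds ``outlier_threshold`` are subsampled
    uniformly without replacement to ``round(mean read count over all
    samples)``; other samples pass through unchanged.  Deterministic for a
    fixed seed; original read order is preserved.
    """
    if outlier_threshold <= 0:
        raise ValueError("outlier_threshold must be positive")
    counts = {s: len(r) for s, r in reads_by_sample.items()}
    if not counts:
        return {}
    target = int(round(float(np.mean(list(counts.values())))))
    rng = np.random.default_rng(seed)
    out: dict[str, list] = {}
    for sample in reads_by_sample:  # iterate in input order for determinism
        reads = list(reads_by_sample[sample])
        if counts[sample] > outlier_threshold:
            if target > counts[sample]:
                raise RuntimeError(
                    f"sample {sample!r}: target mean {target} exceeds its "
                    f"read count {counts[sample]}"
                )
            keep = np.sort(rng.choice(counts[sample], size=target, replace=False))
            out[sample] = [reads[i] for i in keep]
        else:
            out[sample] = reads
    return out
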