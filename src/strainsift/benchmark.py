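"""End-to-end simulation benchmark: estimated vs true strain profiles.

Generates a panel of related focal strains plus unrelated background genomes,
simulates multi-strain samples with known ground truth, runs background
filtering and T1/T2/T3 assignment, and correlates the estimated coverage,
depth, and abundance of every (focal strain, sample) pair against the truth.
Problem sizes default to a desk-scale reduction of the original in-silico
community study: 20 focal strains from a 10 kb ancestor at 2% per-site
divergence, 10 background genomes, 30 samples of 100,000 100 bp reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ._seq import encode
from .alignment import PanelIndex
from .assignment import assign_sample_arrays
from .synthetic import (
    _simulate_read_arrays,
    _truth_from_origins,
    generate_strain_panel,
    sample_community,
)

__all__ = ["BenchmarkResult", "run_simulation_benchmark"]


@dataclass
class BenchmarkResult:
    """Estimated-vs-true profile pairs and their Pearson correlations."""

    pairs: pd.DataFrame  # sample_id, genome_id, est_*, true_* columns
    correlations: dict  # quantity -> Pearson r over all (strain, sample) pairs
    n_pairs: int

    @property
    def min_correlation(self) -> float:
        return min(self.correlations.values())


def run_simulation_benchmark(
    seed: int,
    n_focal: int = 20,
    n_background: int = 10,
    ancestor_length: int = 10_000,
    divergence: float = 0.02,
    n_samples: int = 30,
    reads_per_sample: int = 100_000,
    read_length: int = 100,
    substitution_rate: float = 0.01,
    max_substitutions: int = 5,
    max_mismatch_fraction: float = 0.05,
    k: int = 21,
) -> BenchmarkResult:
    """Run the full simulate-assign-profile loop and score the recovery.

    All randomness derives from ``seed``.  Correlations are computed per
    quantity across every (focal strain, sample) pair, absent strains
    contributing true values of zero.
    """
    root = np.random.SeedSequence(seed)
    panel_seed, bg_seed, *sample_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2 + n_samples)
    ]
    focal = generate_strain_panel(
        ancestor_length, n_focal, divergence, panel_seed, id_prefix="fp", is_focal=True
    )
    # background genomes stand in for unrelated species: each is an
    # independent random sequence (its own ancestor, zero divergence)
    background = [
        generate_strain_panel(
            ancestor_length, 1, 0.0, bg_seed + i + 1, id_prefix=f"bg{i:03d}_",
            is_focal=False,
        )[0]
        for i in range(n_background)
    ]
    focal_codes = {g.id: encode(g.sequence) for g in focal}
    background_codes = {g.id: encode(g.sequence) for g in background}
    focal_index = PanelIndex(focal, k=k)
    background_index = PanelIndex(background, k=k)

    rows = []
    for si in range(n_samples):
        sample_id = f"S{si:03d}"
        srng = np.random.default_rng(sample_seeds[si])
        comp = sample_community(
            focal, background, int(srng.integers(0, 2**31)),
            max_background=n_background,
        )
        genome_codes = {**focal_codes, **background_codes}
        codes, origin, starts, strands, n_subs = _simulate_read_arrays(
            comp, genome_codes, reads_per_sample, read_length, max_substitutions,
            substitution_rate, srng,
        )
        truth = _truth_from_origins(
            comp, genome_codes, origin, starts, read_length, reads_per_sample,
            sample_id,
        ).set_index("genome_id")
        assigned, _ = assign_sample_arrays(
            codes, focal_index, background_index, max_mismatch_fraction
        )
        est = _profile_from_arrays(
            assigned, focal_index, read_length, reads_per_sample
        )
        for gi, gid in enumerate(focal_index.genome_ids):
            true_row = truth.loc[gid] if gid in truth.index else None
            rows.append(
                {
                    "sample_id": sample_id,
                    "genome_id": gid,
                    "est_coverage": est["coverage"][gi],
                    "est_depth": est["depth"][gi],
                    "est_abundance": est["abundance"][gi],
                    "true_coverage": float(true_row["true_coverage"]) if true_row is not None else 0.0,
                    "true_depth": float(true_row["true_depth"]) if true_row is not None else 0.0,
                    "true_abundance": float(true_row["true_abundance"]) if true_row is not None else 0.0,
                }
            )
    pairs = pd.DataFrame(rows)
    correlations = {
        q: float(pearsonr(pairs[f"est_{q}"], pairs[f"true_{q}"]).statistic)
        for q in ("coverage", "depth", "abundance")
    }
    return BenchmarkResult(pairs=pairs, correlations=correlations, n_pairs=len(pairs))


def _profile_from_arrays(
    assigned: dict, index: PanelIndex, read_length: int, total_reads: int
) -> dict[str, np.ndarray]:
    n_genomes = len(index.genome_ids)
    coverage = np.zeros(n_genomes)
    depth = np.zeros(n_genomes)
    abundance = np.zeros(n_genomes)
    for gi in range(n_genomes):
        sel = assigned["genome"] == gi
        length = int(index.lengths[gi])
        starts = assigned["start"][sel]
        diff = np.zeros(length + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + read_length, -1)
        pile = np.cumsum(diff[:-1])
        coverage[gi] = float((pile > 0).mean())
        depth[gi] = float(pile.mean())
        abundance[gi] = float(sel.sum()) / total_reads
    return {"coverage": coverage, "depth": depth, "abundance": abundance}
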