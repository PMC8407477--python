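"""Per-strain coverage/depth/abundance estimates and coverage-based clustering.

Definitions (per strain, per sample):

* coverage — fraction of genome positions hit by at least one assigned base;
* depth — total assigned bases divided by genome length (averaged over *all*
  positions, covered or not);
* abundance — assigned reads divided by the sample's total read count.

Because near-identical co-occurring strains legitimately contribute to each
other's T3 assignments, estimated values act as indicators of the probability
that a database strain is present rather than as exact compositions; in
particular estimated coverage tends to sit slightly above the truth when
sibling strains co-occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .assignment import ReadAssignmentTable

__all__ = [
    "StrainProfileMatrix",
    "compute_profile",
    "cluster_strains",
    "adjusted_rand_index",
    "compare_cluster_groups",
]


@dataclass
class StrainProfileMatrix:
    """samples x strains matrices of estimated coverage, depth and abundance."""

    coverage: pd.DataFrame
    depth: pd.DataFrame
    abundance: pd.DataFrame
    groups: pd.Series | None = None  # sample -> group label

    def __post_init__(self) -> None:
        for name in ("depth", "abundance"):
            m = getattr(self, name)
            if not m.index.equals(self.coverage.index) or not m.columns.equals(
                self.coverage.columns
            ):
                raise ValueError(f"{name} matrix axes differ from the coverage matrix")
        if ((self.coverage.values < 0) | (self.coverage.values > 1)).any():
            raise ValueError("coverage values must lie in [0, 1]")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.coverage.index)
            if self.groups.isna().any():
                raise ValueError("every sample needs a group label")

    @property
    def samples(self) -> list:
        return list(self.coverage.index)

    @property
    def strains(self) -> list:
        return list(self.coverage.columns)

    def to_long(self) -> pd.DataFrame:
        frames = []
        for name in ("coverage", "depth", "abundance"):
            m = getattr(self, name).stack().rename(name)
            frames.append(m)
        long = pd.concat(frames, axis=1).reset_index()
        long.columns = ["sample_id", "strain_id", "coverage", "depth", "abundance"]
        if self.groups is not None:
            long["group"] = long["sample_id"].map(self.groups)
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "StrainProfileMatrix":
        mats = {
            name: long.pivot(index="sample_id", columns="strain_id", values=name)
            for name in ("coverage", "depth", "abundance")
        }
        groups = None
        if "group" in long.columns:
            groups = long.drop_duplicates("sample_id").set_index("sample_id")["group"]
        return cls(groups=groups, **mats)

    def write_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "StrainProfileMatrix":
        return cls.from_long(pd.read_csv(path, sep="\t"))


def compute_profile(
    assignment_table: ReadAssignmentTable,
    genome_lengths: Mapping[str, int],
    total_sample_reads: int,
) -> pd.DataFrame:
    """One profile row per strain from a sample's assignment table.

    Returns a DataFrame indexed by genome id with columns coverage, depth,
    abundance.
    """
    if total_sample_reads < 1:
        raise ValueError("total_sample_reads must be >= 1")
    rows = {}
    for gid, assigned in assignment_table.assignments.items():
        length = int(genome_lengths[gid])
        if length <= 0:
            raise ValueError(f"genome {gid!r} has non-positive length")
        diff = np.zeros(length + 1, dtype=np.int64)
        for a in assigned:
            if a.alignment.end > length:
                raise ValueError(
                    f"alignment of {a.read_id!r} exceeds genome {gid!r} bounds"
                )
            diff[a.alignment.start] += 1
            diff[a.alignment.end] -= 1
        pile = np.cumsum(diff[:-1])
        rows[gid] = {
            "coverage": float((pile > 0).mean()),
            "depth": float(pile.mean()),
            "abundance": len(assigned) / total_sample_reads,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "genome_id"
    return out[["coverage", "depth", "abundance"]] if len(out) else pd.DataFrame(
        columns=["coverage", "depth", "abundance"]
    )


def _correlation_distances(vectors: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson distances between rows, tolerating constant rows.

    Two zero-variance rows are at distance 0 from each other and 1 from any
    non-constant row (an absent-everywhere strain clusters with its kind).
    """
    n = vectors.shape[0]
    sd = vectors.std(axis=1)
    constant = sd == 0
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    var_idx = np.flatnonzero(~constant)
    if var_idx.size >= 2:
        corr = np.corrcoef(vectors[var_idx])
        dist[np.ix_(var_idx, var_idx)] = 1.0 - corr
    const_idx = np.flatnonzero(constant)
    if const_idx.size >= 2:
        dist[np.ix_(const_idx, const_idx)] = 0.0
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def cluster_strains(coverage_matrix: pd.DataFrame, n_clusters: int = 5) -> pd.Series:
    """Agglomerative (average-linkage, correlation-distance) clustering of
    strain coverage vectors.

    ``coverage_matrix`` is samples x strains; strains are clustered by their
    coverage profile across samples.  Cluster labels are C1..Ck, numbered by
    first appearance in column order; the result is deterministic and
    invariant to sample (row) permutations.
    """
    n_strains = coverage_matrix.shape[1]
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > n_strains:
        raise ValueError(
            f"cannot form {n_clusters} clusters from {n_strains} strains"
        )
    strains = list(coverage_matrix.columns)
    if n_clusters == 1:
        return pd.Series({s: "C1" for s in strains})
    vectors = coverage_matrix.to_numpy().T
    dist = _correlation_distances(vectors)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=n_clusters, criterion="maxclust")
    relabel: dict[int, str] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = f"C{len(relabel) + 1}"
        labels.append(relabel[r])
    return pd.Series(labels, index=strains)


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two labelings of the same strains."""
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(list(labels_a), list(labels_b)))


def compare_cluster_groups(
    profile: StrainProfileMatrix,
    cluster_assignment: Mapping[str, str] | pd.Series,
    group_labels: pd.Series | None = None,
    quantity: str = "coverage",
) -> pd.DataFrame:
    """Per-cluster two-group comparison of mean member-strain values.

    For every cluster, member-strain values (coverage by default) are averaged
    per sample and the two groups compared with a two-sided Mann-Whitney test;
    q-values are Benjamini-Hochberg across clusters.
    """
    groups = group_labels if group_labels is not None else profile.groups
    if groups is None:
        raise ValueError("group labels are required")
    groups = pd.Series(groups).reindex(profile.coverage.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, found {levels}")
    if (groups == levels[0]).sum() < 2 or (groups == levels[1]).sum() < 2:
        raise ValueError("each group needs at least two samples")
    values = getattr(profile, quantity)
    clusters = pd.Series(dict(cluster_assignment))
    rows = []
    for c in sorted(clusters.unique()):
        members = clusters.index[clusters == c]
        per_sample = values[members].mean(axis=1)
        x = per_sample[groups == levels[0]]
        y = per_sample[groups == levels[1]]
        p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append({"cluster": c, "p_value": p})
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
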