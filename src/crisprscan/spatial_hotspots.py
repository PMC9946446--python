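"""Structure-guided (3D) hotspot analysis via proximity-weighted enrichment.

For sgRNAs i and j with resistance scores x_i, x_j and structure
residues at centroid distance d_ij, the pairwise score is

    pw_ij   = tanh((x_ij - x_bar) / s_x),   x_ij = x_i + x_j,
    PWES_ij = pw_ij * exp(-d_ij^2 / (2 t^2)),  t = 16 Angstrom,

where x_bar and s_x are the mean and (population) SD of the summed
scores over all unordered pairs.  The tanh bounds jackpotted sgRNAs to
(-1, 1); the Gaussian kernel attenuates pairs that are far apart in
the folded structure.  sgRNAs are grouped by hierarchical (Ward)
clustering of their PWES profile vectors, and each cluster's spatial
coherence is tested by shuffling targeted positions across the
residues targeted by resolved sgRNAs while keeping scores fixed, with
the summed intra-cluster |PWES| as statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

DEFAULT_T = 16.0


# ---------------------------------------------------------------------------
# structure handling
# ---------------------------------------------------------------------------


@dataclass
class StructureModel:
    """Residue-number -> centroid coordinate map for one chain."""

    centroids: dict[int, np.ndarray]
    chain: str = "A"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.centroids:
            raise ValueError("structure model has no residues")

    def __contains__(self, residue: int) -> bool:
        return residue in self.centroids

    def distance(self, res_i: int, res_j: int) -> float:
        return float(np.linalg.norm(self.centroids[res_i] - self.centroids[res_j]))

    def distance_matrix(self, residues: Sequence[int]) -> np.ndarray:
        coords = np.array([self.centroids[r] for r in residues])
        return cdist(coords, coords)


def load_structure_centroids(
    pdb_path: str | Path, chain: str = "A", ca_only: bool = False
) -> StructureModel:
    """Per-residue centroids (mean of atom coordinates) from a PDB file.

    Heteroatoms and waters are excluded; disordered atoms contribute
    their highest-occupancy altloc (Bio.PDB's default selection).  Set
    ``ca_only`` to use the alpha-carbon position instead of the all-atom
    centroid.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(pdb_path))
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not present in {pdb_path}")
    centroids: dict[int, np.ndarray] = {}
    for residue in model[chain]:
        hetflag, resseq, _ = residue.get_id()
        if hetflag.strip() or not is_aa(residue, standard=False):
            continue
        if ca_only:
            if "CA" not in residue:
                continue
            coords = residue["CA"].get_coord()[None, :]
        else:
            coords = np.array([atom.get_coord() for atom in residue.get_atoms()])
        centroids[resseq] = coords.mean(axis=0).astype(float)
    if not centroids:
        raise ValueError(f"no protein residues in chain {chain!r} of {pdb_path}")
    return StructureModel(centroids, chain=chain, source=str(pdb_path))


# ---------------------------------------------------------------------------
# PWES
# ---------------------------------------------------------------------------


def pairwise_scores(scores: np.ndarray) -> tuple[np.ndarray, float, float]:
    """tanh-scaled pairwise score matrix and its normalization constants.

    x_ij = x_i + x_j over unordered pairs i != j; x_bar and s_x are the
    mean and population SD of those sums; pw_ij = tanh((x_ij - x_bar)/s_x)
    with zero diagonal.  All scores equal (s_x = 0) degenerates to
    pw = 0 with a warning.
    """
    x = np.asarray(scores, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 resolved sgRNAs")
    sums = x[:, None] + x[None, :]
    iu = np.triu_indices(n, k=1)
    pair_sums = sums[iu]
    x_bar = float(pair_sums.mean())
    s_x = float(pair_sums.std(ddof=0))
    if s_x == 0.0:
        warnings.warn("all pairwise score sums equal; pw set to 0")
        pw = np.zeros((n, n))
    else:
        pw = np.tanh((sums - x_bar) / s_x)
    np.fill_diagonal(pw, 0.0)
    return pw, x_bar, s_x


def gaussian_kernel(distances: np.ndarray, t: float = DEFAULT_T) -> np.ndarray:
    if t <= 0:
        raise ValueError("bandwidth t must be positive")
    return np.exp(-np.square(distances) / (2.0 * t * t))


@dataclass
class PWESMatrix:
    """Symmetric PWES matrix over an ordered list of resolved sgRNAs."""

    sgrna_ids: list[str]
    residues: np.ndarray  # structure residue per sgRNA
    scores: np.ndarray
    distances: np.ndarray
    pw: np.ndarray
    matrix: np.ndarray
    t: float = DEFAULT_T
    x_bar: float = 0.0
    s_x: float = 1.0
    dropped: list[str] = field(default_factory=list)

    def to_long(self) -> pd.DataFrame:
        """Edge list (i, j, d, pw, PWES) over unordered pairs."""
        iu = np.triu_indices(len(self.sgrna_ids), k=1)
        ids = np.asarray(self.sgrna_ids)
        return pd.DataFrame(
            {
                "i": ids[iu[0]],
                "j": ids[iu[1]],
                "d": self.distances[iu],
                "pw": self.pw[iu],
                "PWES": self.matrix[iu],
            }
        )


def compute_pwes(
    scores: Mapping[str, float],
    structure_residues: Mapping[str, int],
    structure: StructureModel,
    t: float = DEFAULT_T,
) -> PWESMatrix:
    """PWES over the sgRNAs whose structure residue is resolved.

    sgRNAs missing from the structure are dropped (recorded in
    ``dropped``); they remain usable in the 1D analyses.
    """
    ids = [s for s in scores if structure_residues.get(s) in structure.centroids]
    dropped = [s for s in scores if s not in ids]
    if len(ids) < 2:
        raise ValueError("fewer than 2 sgRNAs resolved in the structure")
    residues = np.array([structure_residues[s] for s in ids])
    x = np.array([scores[s] for s in ids], dtype=float)
    pw, x_bar, s_x = pairwise_scores(x)
    d = structure.distance_matrix(list(residues))
    pwes = pw * gaussian_kernel(d, t)
    np.fill_diagonal(pwes, 0.0)
    return PWESMatrix(
        sgrna_ids=ids,
        residues=residues,
        scores=x,
        distances=d,
        pw=pw,
        matrix=pwes,
        t=t,
        x_bar=x_bar,
        s_x=s_x,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# clustering and significance
# ---------------------------------------------------------------------------


@dataclass
class SpatialCluster:
    """One PWES-profile cluster, numbered by descending mean member score."""

    cluster_id: int
    members: list[str]
    mean_score: float
    summed_pwes: float
    p_value: float | None = None


def summed_abs_pwes(matrix: np.ndarray, member_idx: np.ndarray) -> float:
    """Sum of |PWES| over intra-cluster unordered pairs."""
    sub = matrix[np.ix_(member_idx, member_idx)]
    iu = np.triu_indices(len(member_idx), k=1)
    return float(np.abs(sub[iu]).sum())


def cluster_pwes(
    pwes: PWESMatrix,
    n_clusters: int,
    method: str = "ward",
    metric: str = "euclidean",
) -> list[SpatialCluster]:
    """Agglomerative clustering of sgRNAs by their PWES profile rows.

    Clusters are relabeled 1..k in descending order of mean member
    resistance score (cluster 1 = most enriched).
    """
    n = len(pwes.sgrna_ids)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    if n_clusters == n:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(pwes.matrix, method=method, metric=metric)
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    clusters = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        clusters.append(
            (
                float(pwes.scores[idx].mean()),
                [pwes.sgrna_ids[i] for i in idx],
                summed_abs_pwes(pwes.matrix, idx),
            )
        )
    clusters.sort(key=lambda c: -c[0])
    return [
        SpatialCluster(cluster_id=k + 1, members=m, mean_score=s, summed_pwes=w)
        for k, (s, m, w) in enumerate(clusters)
    ]


def cluster_significance(
    cluster: SpatialCluster,
    pwes: PWESMatrix,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Empirical p for a cluster's summed |PWES| under position shuffling.

    All resolved sgRNAs' targeted positions are permuted (without
    replacement) over the resolved-position multiset while scores stay
    attached to their sgRNAs; the cluster's summed |PWES| is recomputed
    per permutation.  p = (1 + #{null >= observed}) / (1 + n_perm).
    Singleton clusters have statistic 0 and p = 1.
    """
    member_idx = np.array([pwes.sgrna_ids.index(m) for m in cluster.members])
    if member_idx.size < 2:
        return 1.0
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    observed = summed_abs_pwes(pwes.matrix, member_idx)
    # |pw| for member pairs is invariant under position shuffles
    sub_pw = np.abs(pwes.pw[np.ix_(member_idx, member_idx)])
    iu = np.triu_indices(member_idx.size, k=1)
    pw_pairs = sub_pw[iu]
    n = len(pwes.sgrna_ids)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        new_idx = perm[member_idx]
        d = pwes.distances[np.ix_(new_idx, new_idx)][iu]
        stat = float((pw_pairs * gaussian_kernel(d, pwes.t)).sum())
        if stat >= observed:
            exceed += 1
    return (1.0 + exceed) / (1.0 + n_perm)


def spatial_scan(
    scores: Mapping[str, float],
    structure_residues: Mapping[str, int],
    structure: StructureModel,
    n_clusters: int,
    t: float = DEFAULT_T,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[PWESMatrix, list[SpatialCluster]]:
    """PWES computation, clustering, and per-cluster significance."""
    pwes = compute_pwes(scores, structure_residues, structure, t=t)
    clusters = cluster_pwes(pwes, n_clusters)
    rng = np.random.default_rng(seed)
    for c in clusters:
        c.p_value = cluster_significance(c, pwes, n_perm=n_perm, seed=rng)
    return pwes, clusters
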