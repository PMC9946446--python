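"""Per-residue score smoothing and 1D hotspot (linear cluster) calling.

Per-residue resistance scores are estimated by LOESS regression of
sgRNA scores on amino-acid position with a 100-residue sliding window
(``frac = 100/L``) and no robustness iterations, then quadratic spline
interpolation fills residues not directly targeted.  Significance comes
from a shuffle null: cut-site positions stay fixed while scores are
permuted, the smoothed track is recomputed per permutation, and each
residue gets a one-sided empirical p-value, BH-adjusted across the
track.  Linear clusters are maximal contiguous runs of residues with
adjusted p <= alpha.

Because LOESS with ``it=0`` followed by spline interpolation is linear
in the score vector for fixed positions, the permutation null is
evaluated through a precomputed smoother matrix (one matrix multiply
per batch of permutations) rather than by refitting; the two paths are
identical up to floating-point roundoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

WINDOW_AA = 100.0


@dataclass(frozen=True)
class LinearCluster:
    """A maximal contiguous run of significantly enriched residues (1-based, inclusive)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("cluster start > end")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


def _loess_frac(L: int) -> float:
    frac = WINDOW_AA / L
    if frac >= 1.0:
        warnings.warn(
            f"protein length {L} < {WINDOW_AA:.0f}-residue window; span clamped to 1.0",
            stacklevel=3,
        )
        frac = 1.0
    return frac


def fit_residue_scores(
    positions: np.ndarray, scores: np.ndarray, L: int
) -> np.ndarray:
    """LOESS-smooth sgRNA scores onto a per-residue track of length L.

    Locally weighted linear regression (tricube weights, span 100/L,
    zero robustness iterations) is evaluated at the targeted positions;
    a quadratic spline through those fitted values supplies every
    integer residue between the first and last targeted position.
    Residues outside the targeted span are NaN.

    sgRNAs assigned to two flanking residues should appear once per
    assigned residue in ``positions``/``scores``.
    """
    positions = np.asarray(positions, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if positions.shape != scores.shape:
        raise ValueError("positions and scores differ in length")
    if np.unique(positions).size < 3:
        raise ValueError("need >= 3 distinct targeted positions")
    if L < positions.max():
        raise ValueError("protein length L smaller than max targeted position")
    frac = _loess_frac(L)
    fitted = lowess(scores, positions, frac=frac, it=0, return_sorted=True)
    xs, idx = np.unique(fitted[:, 0], return_index=True)
    ys = fitted[idx, 1]
    kind = "quadratic" if xs.size >= 3 else "linear"
    spline = interp1d(xs, ys, kind=kind, assume_sorted=True)
    track = np.full(L, np.nan)
    lo = int(np.ceil(xs[0]))
    hi = int(np.floor(xs[-1]))
    grid = np.arange(lo, hi + 1)
    track[grid - 1] = spline(grid)
    return track


def smoother_matrix(positions: np.ndarray, L: int) -> np.ndarray:
    """The L x n linear operator mapping sgRNA scores to the smoothed track.

    Column j is the track produced by a unit score at data point j; any
    score vector y then maps to ``A @ y``.  Valid because the LOESS fit
    (it=0) and the interpolating spline are both linear in y.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.size
    A = np.empty((L, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        A[:, j] = fit_residue_scores(positions, e, L)
    return A


def permutation_null(
    positions: np.ndarray,
    scores: np.ndarray,
    L: int,
    n_perm: int,
    seed: int | np.random.Generator = 0,
    operator: np.ndarray | None = None,
) -> np.ndarray:
    """Null tracks from shuffling scores over the fixed position multiset.

    Returns an (n_perm, L) array of smoothed tracks, one per permutation
    of the score vector.  ``operator`` may carry a precomputed
    :func:`smoother_matrix` to share across calls.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    scores = np.asarray(scores, dtype=float)
    A = operator if operator is not None else smoother_matrix(positions, L)
    perms = np.empty((scores.size, n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(scores)
    return (A @ perms).T


def empirical_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """One-sided (enrichment) add-one empirical p per residue.

    p = (1 + #{null >= observed}) / (1 + n_perm); NaN where the track is
    undefined.  Ties between null and observed count against the
    observed value (conservative).
    """
    n_perm = null.shape[0]
    with np.errstate(invalid="ignore"):
        exceed = (null >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[np.isnan(observed)] = np.nan
    return p


def call_linear_clusters(
    observed: np.ndarray,
    null: np.ndarray,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[LinearCluster]]:
    """Empirical p-values, BH adjustment, and contiguous cluster calls.

    Returns the per-residue track table (residue, score, p, p_adj) and
    the list of maximal contiguous intervals with adjusted p <= alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if null.shape[0] < 100:
        warnings.warn("fewer than 100 permutations: p-value resolution is coarse")
    p = empirical_pvalues(observed, null)
    p_adj = np.full_like(p, np.nan)
    defined = ~np.isnan(p)
    if defined.any():
        p_adj[defined] = multipletests(p[defined], method="fdr_bh")[1]
    track = pd.DataFrame(
        {
            "residue": np.arange(1, observed.size + 1),
            "score": observed,
            "p": p,
            "p_adj": p_adj,
        }
    )
    sig = defined & (p_adj <= alpha)
    clusters: list[LinearCluster] = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i + 1
        elif not flag and start is not None:
            clusters.append(LinearCluster(start, i))
            start = None
    if start is not None:
        clusters.append(LinearCluster(start, observed.size))
    return track, clusters


def linear_scan(
    positions: np.ndarray,
    scores: np.ndarray,
    L: int,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[LinearCluster]]:
    """Full 1D scan: smooth, permute, adjust, call clusters."""
    A = smoother_matrix(positions, L)
    observed = A @ np.asarray(scores, dtype=float)
    null = permutation_null(positions, scores, L, n_perm, seed=seed, operator=A)
    return call_linear_clusters(observed, null, alpha=alpha)
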