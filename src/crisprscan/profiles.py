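"""Mutational-profile features and sgRNA partitioning.

Each genotyped sgRNA is summarized by a feature vector built from its
filtered allele table in vehicle and drug conditions:

* absolute frequencies of wild-type and in-frame alleles, and the
  relative (percent-of-edited) in-frame frequency, in drug;
* log2 fold-changes of wild-type / in-frame / loss-of-function
  absolute frequencies, drug vs vehicle;
* log-odds log2((f_IF + f_LOF)/f_WT) (absolute frequencies) and
  log2(f_rel(IF)/f_rel(LOF)) (relative frequencies) per condition, and
  their drug - vehicle (optionally drug - predicted) ratios;
* Pearson correlation of allele frequencies across conditions;
* symmetric Kullback-Leibler divergence D(P||Q) + D(Q||P) with a
  0.01 percentage-point pseudocount;
* Gini coefficients of the drug allele distribution over all alleles
  (absolute frequencies) and edited alleles (relative frequencies).

sgRNAs are partitioned by per-feature rank quantile transformation,
PCA (<= 10 components), and k-means (k = 2, many initializations)
repeated many times with the modal partition retained; the cluster
with the higher mean in-frame log2 fold-change is labeled
``drug-divergent``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import QuantileTransformer

from .genotypes import WILD_TYPE

KL_PSEUDOCOUNT_PCT = 0.01

FEATURES = [
    "score",
    "wt_abs_drug",
    "if_abs_drug",
    "if_rel_drug",
    "log2fc_wt",
    "log2fc_if",
    "log2fc_lof",
    "logodds_edited_wt_drug",
    "logodds_if_lof_drug",
    "oddsratio_edited_wt",
    "oddsratio_if_lof",
    "pearson_r",
    "symmetric_kl",
    "gini_all",
    "gini_edited",
]


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------


def log_odds(
    wt_abs: float, if_abs: float, lof_abs: float, pseudo: float | None = None
) -> tuple[float, float]:
    """(log2 odds edited/WT, log2 odds IF/LOF) from absolute class shares.

    Edited/WT uses absolute frequencies; IF/LOF reduces to the ratio of
    absolute frequencies because the edited-relative normalization
    cancels.  Zero numerators/denominators are replaced by ``pseudo``
    when given, else raise.
    """

    def _guard(v: float) -> float:
        if v > 0:
            return v
        if pseudo is None:
            raise ValueError("zero class frequency without pseudo-handling")
        return pseudo

    edited = if_abs + lof_abs
    lo_edited = np.log2(_guard(edited) / _guard(wt_abs))
    lo_iflof = np.log2(_guard(if_abs) / _guard(lof_abs))
    return float(lo_edited), float(lo_iflof)


def compute_odds_metrics(
    summary: pd.DataFrame, pseudo: float | None = None
) -> pd.DataFrame:
    """Log-odds per condition plus drug - vehicle odds ratios.

    ``summary`` is the per-condition class table from
    :func:`crisprscan.genotypes.summarize_classes` (rows vehicle/drug,
    columns wt_abs/if_abs/lof_abs).
    """
    rows = {}
    for cond in summary.index:
        lo_e, lo_i = log_odds(
            summary.loc[cond, "wt_abs"],
            summary.loc[cond, "if_abs"],
            summary.loc[cond, "lof_abs"],
            pseudo=pseudo,
        )
        rows[cond] = {"logodds_edited_wt": lo_e, "logodds_if_lof": lo_i}
    out = pd.DataFrame(rows).T
    if {"vehicle", "drug"} <= set(out.index):
        out.loc["ratio"] = out.loc["drug"] - out.loc["vehicle"]
    return out


def symmetric_kl(
    p: np.ndarray, q: np.ndarray, pseudocount: float = KL_PSEUDOCOUNT_PCT
) -> float:
    """Symmetric KL divergence between two allele-frequency vectors (%).

    A pseudocount (default 0.01 percentage points) is added to every
    allele in both distributions before the log-ratio sums; natural
    log; no renormalization (matching the percentage-scale recipe).
    """
    p = np.asarray(p, dtype=float) + pseudocount
    q = np.asarray(q, dtype=float) + pseudocount
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def gini(frequencies: np.ndarray) -> float:
    """Classical Gini coefficient of an allele-frequency distribution.

    Computed as the mean absolute difference over twice the mean,
    G = sum_ij |f_i - f_j| / (2 n^2 fbar): 0 for equal frequencies,
    (n-1)/n when one allele carries everything.  Equivalent to
    2*AUC - 1 for the Lorenz-curve area read against the diagonal.
    """
    f = np.sort(np.asarray(frequencies, dtype=float))
    n = f.size
    if n == 0 or f.sum() == 0:
        return 0.0
    if (f < 0).any():
        raise ValueError("negative frequencies")
    # identity: sum_ij |f_i - f_j| = 2 * sum_i (2i - n + 1) f_(i), i 0-based
    i = np.arange(n)
    mad = 2.0 * np.sum((2 * i - n + 1) * f)
    return float(mad / (2.0 * n * n * f.mean()))


def compute_divergence_stats(table: pd.DataFrame) -> dict[str, float]:
    """Pearson r, symmetric KL, and the Gini pair from a filtered allele table.

    The allele universe is the union of retained alleles across both
    conditions (absent alleles at 0%).  Pearson and KL compare absolute
    frequencies across conditions; ``gini_all`` uses all alleles'
    absolute drug frequencies, ``gini_edited`` the edited alleles'
    relative drug frequencies.
    """
    p = table["freq_drug"].to_numpy(dtype=float)
    q = table["freq_vehicle"].to_numpy(dtype=float)
    if p.size >= 2 and np.std(p) > 0 and np.std(q) > 0:
        pearson = float(stats.pearsonr(p, q)[0])
    else:
        pearson = np.nan
    kl = symmetric_kl(p, q)
    edited = table["classification"] != WILD_TYPE
    ed = p[edited.to_numpy()]
    gini_edited = gini(ed / ed.sum() * 100.0) if ed.sum() > 0 else np.nan
    return {
        "pearson_r": pearson,
        "symmetric_kl": kl,
        "gini_all": gini(p),
        "gini_edited": gini_edited,
    }


# ---------------------------------------------------------------------------
# per-sgRNA profile assembly
# ---------------------------------------------------------------------------


def mutational_profile(
    table: pd.DataFrame,
    summary: pd.DataFrame,
    score: float = np.nan,
) -> dict[str, float]:
    """One sgRNA's full feature dict from its filtered allele table.

    ``table`` and ``summary`` come from the genotypes module
    (:func:`filter_and_normalize`, :func:`summarize_classes`).  Zero
    frequencies entering ratios are floored at half the smallest
    representable frequency (one read over the condition total).
    """
    totals = table.attrs.get("total_reads", {})
    floors = {
        cond: 100.0 / totals.get(cond, 1e6) / 2.0 for cond in ("vehicle", "drug")
    }

    def _f(cond: str, key: str) -> float:
        v = summary.loc[cond, key]
        return float(v) if v > 0 else floors[cond]

    feats: dict[str, float] = {"score": score}
    feats["wt_abs_drug"] = float(summary.loc["drug", "wt_abs"])
    feats["if_abs_drug"] = float(summary.loc["drug", "if_abs"])
    feats["if_rel_drug"] = float(summary.loc["drug", "if_rel"])
    for key, col in (("wt", "wt_abs"), ("if", "if_abs"), ("lof", "lof_abs")):
        feats[f"log2fc_{key}"] = float(
            np.log2(_f("drug", col) / _f("vehicle", col))
        )
    for cond in ("vehicle", "drug"):
        lo_e, lo_i = log_odds(
            _f(cond, "wt_abs"),
            _f(cond, "if_abs"),
            _f(cond, "lof_abs"),
            pseudo=floors[cond],
        )
        feats[f"logodds_edited_wt_{cond}"] = lo_e
        feats[f"logodds_if_lof_{cond}"] = lo_i
    feats["oddsratio_edited_wt"] = (
        feats["logodds_edited_wt_drug"] - feats["logodds_edited_wt_vehicle"]
    )
    feats["oddsratio_if_lof"] = (
        feats["logodds_if_lof_drug"] - feats["logodds_if_lof_vehicle"]
    )
    feats.update(compute_divergence_stats(table))
    return feats


def assemble_feature_matrix(
    profiles: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Rectangular sgRNA x feature matrix with median imputation.

    Rows whose features are all missing are dropped with a warning;
    remaining missing values are imputed to the feature median.
    """
    features = features or [f for f in FEATURES if f in profiles.columns]
    X = profiles[features].astype(float).copy()
    all_missing = X.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} sgRNAs with no usable features"
        )
        X = X.loc[~all_missing]
    n_imputed = int(X.isna().to_numpy().sum())
    if n_imputed:
        warnings.warn(f"median-imputing {n_imputed} missing feature values")
        X = X.fillna(X.median())
    return X


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------


@dataclass
class ProfilePartition:
    """Modal two-way k-means partition of sgRNA mutational profiles."""

    labels: pd.Series  # 'drug-divergent' | 'other' per sgRNA
    pca_scores: pd.DataFrame
    stability: float  # fraction of repeats agreeing with the modal partition
    explained_variance_ratio: np.ndarray


def _canonical(labels: np.ndarray) -> tuple[int, ...]:
    """Partition signature invariant to label swapping."""
    flip = labels[0] == 1
    return tuple(int(l ^ 1 if flip else l) for l in labels)


def cluster_profiles(
    matrix: pd.DataFrame,
    seed: int = 0,
    n_components: int = 10,
    n_init: int = 1000,
    repeats: int = 1000,
    divergence_feature: str = "log2fc_if",
) -> ProfilePartition:
    """Quantile transform -> PCA -> repeated k-means (k=2) modal partition.

    Each feature is independently rank-transformed to a uniform target,
    PCA reduces to <= ``n_components``, and k-means with ``n_init``
    initializations runs ``repeats`` times; the most common partition
    (up to label swap) is kept, with the agreeing fraction reported as
    ``stability``.  The cluster with the higher mean of
    ``divergence_feature`` (on the raw matrix) is ``drug-divergent``.
    """
    if len(matrix) < 3:
        raise ValueError("need >= 3 sgRNAs to partition")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate feature matrix (zero variance everywhere)")
    rng = np.random.default_rng(seed)
    qt = QuantileTransformer(
        n_quantiles=min(len(matrix), 1000),
        output_distribution="uniform",
        random_state=int(rng.integers(2**31 - 1)),
    )
    Xq = qt.fit_transform(X)
    k = min(n_components, len(matrix), matrix.shape[1])
    pca = PCA(n_components=k, random_state=int(rng.integers(2**31 - 1)))
    Xp = pca.fit_transform(Xq)

    outcomes: Counter[tuple[int, ...]] = Counter()
    for _ in range(repeats):
        km = KMeans(
            n_clusters=2,
            n_init=n_init,
            random_state=int(rng.integers(2**31 - 1)),
        )
        outcomes[_canonical(km.fit_predict(Xp))] += 1
    modal, count = outcomes.most_common(1)[0]
    labels01 = np.array(modal)

    if divergence_feature in matrix.columns:
        mean0 = matrix.loc[labels01 == 0, divergence_feature].mean()
        mean1 = matrix.loc[labels01 == 1, divergence_feature].mean()
        divergent = 0 if mean0 >= mean1 else 1
    else:
        divergent = 0
    names = np.where(labels01 == divergent, "drug-divergent", "other")
    return ProfilePartition(
        labels=pd.Series(names, index=matrix.index, name="cluster"),
        pca_scores=pd.DataFrame(
            Xp,
            index=matrix.index,
            columns=[f"PC{i + 1}" for i in range(Xp.shape[1])],
        ),
        stability=count / repeats,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
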