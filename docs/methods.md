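# Methods notes

This document records the models, parameter choices, and numerical
decisions behind `crisprscan`, and what the synthetic-data generators
do and do not establish.

## Screen quantification

The normalization chain is RPM → +1 pseudocount → log2 → subtract the
plasmid sample → average replicates per condition → drug − vehicle →
subtract the negative-control mean. Two choices deserve note:

* **The plasmid sample receives the identical RPM/pseudocount/log2
  transform** as the selection samples. Any other convention makes
  scores depend on plasmid sequencing depth; with this one, uniformly
  rescaling any one sample's counts leaves every score unchanged
  (tested exactly).
* **Hit threshold** uses the strict inequality
  x > mean + 2·SD over negative controls (sample SD, ddof = 1); after
  centering the control mean is identically 0. A score exactly at the
  boundary is not a hit.
* sgRNAs with zero plasmid reads are excluded: they carry NaN scores
  and can never be hits. Reads shorter than prefix + 20 nt are counted
  as unassigned, not errors.
* Cut sites are stored as CDS *bond* indices (cut between nucleotides
  k and k+1, blunt cut 3 nt 5′ of the PAM). A cut inside a codon maps
  to that single residue; a cut on a codon boundary maps to both
  flanking residues, with the even-numbered one used for 3D analysis.
  A cut at the final codon boundary maps to the last residue alone
  (residue L+1 does not exist).

## 1D hotspot scan

LOESS uses tricube-weighted local linear regression with span
`frac = 100/L` and zero robustness iterations (`statsmodels.lowess`),
evaluated at targeted positions; a quadratic interpolating spline
(`scipy.interpolate.interp1d(kind="quadratic")`) fills untargeted
residues. Residues outside the span of targeted positions get no
score, no p-value, and cannot seed clusters. Proteins shorter than the
100-residue window clamp the span to 1.0 with a warning.

**Permutation null as a linear operator.** For fixed positions,
LOESS with `it = 0` followed by spline interpolation is linear in the
score vector. The implementation therefore materializes the L×n
smoother matrix (columns = unit-score responses through the exact
statsmodels/scipy code path) and evaluates all permutations with one
matrix multiply. A test verifies agreement with direct per-permutation
refits to 1e-10. This makes 10,000-permutation nulls cheap without
approximating anything.

Empirical p-values use the add-one estimator `(1+b)/(1+n)` (never
exactly zero), one-sided for enrichment; ties between null and
observed count against significance. BH adjustment runs across all
defined residues of one protein track. sgRNAs assigned to two flanking
residues contribute one data point at each. Dual-residue handling,
one-sided direction, and the estimator are deliberate choices where
the procedure's description leaves room; each is configurable or
documented here.

## 3D hotspot scan (PWES)

* Pair sums x_ij = x_i + x_j over unordered pairs; x̄ and s_x are the
  mean and **population** SD (these are normalization constants, not
  inferential estimates). All-equal scores degenerate to pw ≡ 0 with a
  warning rather than an error.
* PWES = pw · exp(−d²/(2·t²)) with t = 16 Å; the matrix diagonal is 0
  (self-pairs excluded everywhere). Adding a constant to all scores
  leaves pw, hence PWES, exactly unchanged.
* Residue centroids average all atom records of a residue (highest-
  occupancy altloc; waters/heteroatoms excluded); a Cα-only mode is
  available. Parsing goes through Bio.PDB.
* Clustering is Ward linkage on Euclidean distances between PWES row
  vectors (`scipy.cluster.hierarchy`); the linkage/metric are exposed,
  and the number of clusters is a required user parameter. Clusters
  are numbered by descending mean member resistance score.
* Cluster significance fixes scores to sgRNAs and permutes targeted
  positions (without replacement) across the residues targeted by
  resolved sgRNAs; the statistic is the summed intra-cluster |PWES|.
  |pw| is shuffle-invariant, so only the distance kernel is
  recomputed per permutation. Singleton clusters report statistic 0
  and p = 1.
* sgRNAs whose structure residue is unresolved are dropped from the
  3D module only, with the dropped ids reported; they remain in all
  1D analyses.

## Genotype classification

Classification precedence: unedited → wild-type; any edit touching
the 2 intronic nucleotides flanking an exon, an insertion at those
junction bonds, or a deletion spanning an intron–exon junction →
splice-site; net CDS indel ≢ 0 (mod 3) → frameshift; otherwise the
allele's spliced CDS region is realigned, translated and compared:
premature stop → nonsense; identical protein → wild-type (silent);
else in-frame with a protein-variant name. Frameshift, splice-site
and nonsense are exactly the loss-of-function set. Edits entirely
outside the CDS that spare splice sites are wild-type at the protein
level (the analysis is protein-centric; regulatory effects are out of
scope).

**Codon-unit Needleman–Wunsch.** Gaps open and extend only in whole
codons aligned to codon boundaries. An aligned codon pair scores its
nucleotide-identity count (0–3); each gapped codon costs −4. The
penalty is chosen so one codon gap (−4) beats two poorly matching
substitutions (≤ +2 combined when mostly mismatched) but loses to
well-matching substitutions; it is exposed in the API and validated
against exhaustive enumeration of all codon-gap placements for
sequences up to 6 codons. Ties are broken toward the most 3′ gap
placement (gap-preferring traceback from the 3′ corner).

**Variant naming** diffs the translated proteins by maximizing the
shared N-terminal flank first, so deletions in repeat runs take their
most C-terminal equivalent representation (`K4del` in `MKKKD → MKKD`);
a left-aligned mode exists. Equal-length differences become
substitution lists (`K592S/E593K`), length-changing replacements
become delins (`F545_D548delinsL`). Names are anchored to absolute
residue numbers via the gene model's CDS offset and round-trip through
`parse_variant_name`. Because names come from the protein diff, they
are independent of NW gap tie-breaking.

Zero denominators in fold-changes and odds are floored at half the
smallest representable frequency for that condition (one read over the
condition's total), keeping every ratio finite while preserving order
of magnitude.

## Profile features and partitioning

* Log-odds: edited/WT from absolute shares, IF/LOF from
  edited-relative shares (algebraically the ratio of absolute IF and
  LOF shares); odds ratios are drug − vehicle (and drug − predicted
  when a predicted table is supplied).
* Symmetric KL adds a 0.01 percentage-point pseudocount to every
  allele of both distributions, uses natural log, and does not
  renormalize — the literal percentage-scale recipe. The base only
  rescales the feature and is irrelevant after the rank-based quantile
  transform.
* Gini is the classical coefficient, mean absolute difference over
  twice the mean — equivalent to 2·AUC − 1 for the Lorenz-curve
  reading — oriented so uniform → 0 and a single dominant allele →
  (n−1)/n. Computed for all alleles (absolute frequencies) and edited
  alleles (relative frequencies).
* Pearson pairs alleles by identity of the edited sequence across
  conditions, absent alleles entering at 0%; with fewer than two
  alleles or zero variance it is missing (median-imputed later, with
  a warning).
* Partitioning: per-feature rank quantile transform to uniform →
  PCA (≤ 10 components) → k-means (k = 2). K-means runs `repeats`
  times with `n_init` initializations each; the modal partition (up
  to label swap) is kept and its agreement fraction reported as a
  stability diagnostic. The cluster with the higher mean raw in-frame
  log2 fold-change is labeled drug-divergent. The modal protocol makes
  the outcome insensitive to the seed (tested across 20 seeds on
  separated data).

## Synthetic data: what it does and does not establish

The generators state a world and keep it fixed:

* **Screen**: cut sites uniform over the CDS; true scores = N(0, σ)
  background plus δ inside planted windows; negative controls from the
  background; negative-binomial counts (dispersion 0.05) around
  lognormal per-sgRNA abundances, with drug-sample means scaled by
  2^score so the normalization chain is unbiased for the true score.
  Defaults are desk-scale (tests use L ≈ 200–400 with 100–200 sgRNAs;
  the full-scale default mirrors an ~1616-residue target with 830+77
  sgRNAs and 3+3 replicates).
* **Structure**: a jittered helical backbone (rise 1.5 Å/residue) in
  which a planted residue set, dispersed in sequence, is pulled within
  < 10 Å of a common center. This gives the 3D analysis a true
  spatially-compact/sequence-dispersed hotspot but does not reproduce
  real protein packing, domains, or contact statistics.
* **Alleles**: outcome catalogues around the cut site mix 1-bp
  insertions, geometric-tailed deletions, and substitutions (silent
  ones included); drug frequencies reweight the prior by exp(fitness)
  per class — GOF boosts in-frame and penalizes WT/LOF, KO penalizes
  all edits. The predicted table is the prior without selection,
  standing in for a repair-outcome predictor. Sequence-context-
  accurate repair spectra and PCR/sequencing error are deliberately
  not modeled.

A green recovery test therefore establishes that the statistics
recover the planted structure under their own assumptions (correct
nulls, calibrated p-values, sufficient power at the stated effect
sizes) — not that the pipeline is robust to real-data pathologies such
as guide-specific cutting efficiency, off-target effects, jackpotting
beyond NB dispersion, or mis-specified gene models.

One stated expectation was corrected analytically: with a one-sided
2-SD hit rule, per-sgRNA power at δ = 3σ is Φ(1) ≈ 0.84, not ≥ 0.9;
the generator test asserts the analytic value. Window-level detection
through the LOESS scan does reach ≥ 95% of runs at the same effect
size and is tested at that threshold.

## Known limitations

* The genotype module consumes aligned allele tables; raw-read
  alignment and its quality filters are upstream and out of scope.
* Multi-exon gene models assume the amplicon covers each edit; edits
  at amplicon borders inside a trimmed partial codon fall back to an
  unnamed in-frame call rather than guessing a frame.
* The PWES module handles a single chain; multi-chain complexes and
  mmCIF-specific extensions are not supported.
* k for the 3D clustering is a user parameter: the choice that
  yields a particular published cluster count is data-dependent and
  not derivable from first principles.
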