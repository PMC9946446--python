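"""Seeded synthetic screens, structures, and allele tables.

Every generator is a pure function of (spec, seed) and emits the exact
dialects consumed by the analysis modules, plus the ground truth needed
for recovery tests:

* :func:`simulate_screen` — a pooled tiling screen: sgRNAs with cut
  sites uniform over a CDS, true resistance scores drawn from a normal
  background plus planted hotspot windows, negative-binomial counts in
  plasmid/vehicle/drug samples shaped so the normalization chain
  recovers the true scores in expectation.
* :func:`simulate_structure` — PDB text for a synthetic backbone where
  a planted, sequence-dispersed residue set is made mutually proximal
  (< 10 Angstrom), emulating a folded hotspot.
* :func:`simulate_allele_tables` — CRISPResso-dialect allele tables for
  vehicle and drug under a gain-of-function (in-frame alleles positively
  selected) or knockout (edited alleles deselected) regime, exercising
  every classifier branch (silent, nonsense, splice-site, frameshift,
  in-frame deletions/insertions, substitutions).

Default sizes mirror a desk-scale version of a DNMT1-style screen:
L = 1616 residues, 830 targeting + 77 control sgRNAs, 3 + 3 replicates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genotypes import GeneModel
from .screen_quant import DEFAULT_PREFIX, SgRNALibrary, SgRNARecord, map_sgrna_to_residues

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimSpec:
    """Stated world for the pooled-screen generator."""

    protein_length: int = 1616
    n_sgrnas: int = 830
    n_controls: int = 77
    background_sd: float = 1.0
    hotspots: list[tuple[int, int, float]] = field(default_factory=list)
    # (start_residue, end_residue, effect delta) triples
    reads_per_sgrna: float = 500.0
    nb_dispersion: float = 0.05
    replicates: int = 3

    def __post_init__(self) -> None:
        L = self.protein_length
        for s, e, d in self.hotspots:
            if not (1 <= s <= e <= L):
                raise ValueError(f"hotspot window ({s},{e}) outside [1,{L}]")
            if d <= 0:
                raise ValueError("hotspot effect must be positive")
        if self.background_sd <= 0:
            raise ValueError("background SD must be positive")


@dataclass
class SimulatedScreen:
    library: SgRNALibrary
    counts: pd.DataFrame
    design: dict[str, str]
    true_scores: pd.Series
    hotspots: list[tuple[int, int, float]]


def simulate_screen(spec: ScreenSimSpec, seed: int = 0) -> SimulatedScreen:
    """Generate a pooled screen with known per-sgRNA true scores.

    True score = N(0, sd) background, plus delta for sgRNAs whose
    structure residue falls in a planted window; negative controls draw
    from the background only.  Counts are negative binomial around
    plasmid abundances, with the drug-sample mean multiplied by
    2**score so the RPM/log2 normalization chain is unbiased for the
    true score in expectation.
    """
    rng = np.random.default_rng(seed)
    L = spec.protein_length
    cds_len = 3 * L
    cuts = np.sort(rng.integers(1, cds_len, size=spec.n_sgrnas))

    records = []
    protos: set[str] = set()
    for i, cut in enumerate(cuts):
        while True:
            proto = _random_dna(rng, 20)
            if proto not in protos:
                protos.add(proto)
                break
        residues, struct = map_sgrna_to_residues(int(cut), cds_len)
        records.append(
            SgRNARecord(
                id=f"sg{i:04d}",
                protospacer=proto,
                gene="GENE",
                cut_site_cds=int(cut),
                residue_assignment=residues,
                structure_residue=struct,
            )
        )
    for i in range(spec.n_controls):
        while True:
            proto = _random_dna(rng, 20)
            if proto not in protos:
                protos.add(proto)
                break
        records.append(
            SgRNARecord(
                id=f"ctrl{i:03d}", protospacer=proto, gene="", is_negative_control=True
            )
        )
    library = SgRNALibrary(records)

    n_total = len(records)
    true = rng.normal(0.0, spec.background_sd, size=n_total)
    for s, e, delta in spec.hotspots:
        inwin = [
            k
            for k, rec in enumerate(records)
            if rec.structure_residue is not None and s <= rec.structure_residue <= e
        ]
        true[inwin] += delta
    true_scores = pd.Series(true, index=library.ids, name="true_score")

    abundance = rng.lognormal(mean=0.0, sigma=0.25, size=n_total)
    abundance /= abundance.mean()

    def _nb(mean: np.ndarray) -> np.ndarray:
        r = 1.0 / spec.nb_dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    depth = spec.reads_per_sgrna
    counts: dict[str, np.ndarray] = {"plasmid": _nb(abundance * depth)}
    design = {"plasmid": "plasmid"}
    for rep in range(1, spec.replicates + 1):
        counts[f"vehicle_{rep}"] = _nb(abundance * depth)
        design[f"vehicle_{rep}"] = "vehicle"
        counts[f"drug_{rep}"] = _nb(abundance * depth * np.exp2(true))
        design[f"drug_{rep}"] = "drug"
    count_df = pd.DataFrame(counts, index=library.ids)
    return SimulatedScreen(
        library=library,
        counts=count_df,
        design=design,
        true_scores=true_scores,
        hotspots=list(spec.hotspots),
    )


def screen_reads_fastq(
    screen: SimulatedScreen,
    sample: str,
    seed: int = 0,
    max_reads: int | None = None,
    prefix: str = DEFAULT_PREFIX,
) -> str:
    """Render one sample's counts as FASTQ text (cassette reads)."""
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    protos = {r.id: r.protospacer for r in screen.library}
    n_written = 0
    for sgid, count in screen.counts[sample].items():
        for _ in range(int(count)):
            if max_reads is not None and n_written >= max_reads:
                break
            pad = _random_dna(rng, 5)
            tail = _random_dna(rng, 10)
            seq = pad + prefix + protos[sgid] + tail
            lines += [f"@read{n_written}", seq, "+", "I" * len(seq)]
            n_written += 1
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# structure simulation
# ---------------------------------------------------------------------------


@dataclass
class StructureSimSpec:
    """Stated world for the synthetic-structure generator."""

    n_residues: int = 1000
    planted_residues: tuple[int, ...] = ()
    planted_radius: float = 4.0  # max distance from hotspot center (Angstrom)
    rise_per_residue: float = 1.5
    turn_radius: float = 10.0
    turn_per_residue: float = 0.6  # radians
    jitter_sd: float = 0.3

    def __post_init__(self) -> None:
        for r in self.planted_residues:
            if not 1 <= r <= self.n_residues:
                raise ValueError(f"planted residue {r} outside [1,{self.n_residues}]")


def simulate_structure(spec: StructureSimSpec, seed: int = 0) -> tuple[str, dict[int, np.ndarray]]:
    """PDB text for a helical backbone with a planted compact residue set.

    Non-planted residue i sits on a helix (radius ``turn_radius``, rise
    ``rise_per_residue``) plus Gaussian jitter, so sequence-distant
    residues are spatially distant; planted residues are pulled to
    within ``planted_radius`` of a common off-backbone center, making
    them mutually proximal regardless of sequence position.  Each
    residue is written as four pseudo-atoms around its center so that
    all-atom centroids recover the intended coordinates.

    Returns (pdb_text, {residue_number: intended centroid}).
    """
    rng = np.random.default_rng(seed)
    centers: dict[int, np.ndarray] = {}
    for i in range(1, spec.n_residues + 1):
        theta = spec.turn_per_residue * i
        base = np.array(
            [
                spec.turn_radius * np.cos(theta),
                spec.turn_radius * np.sin(theta),
                spec.rise_per_residue * i,
            ]
        )
        centers[i] = base + rng.normal(0.0, spec.jitter_sd, size=3)
    if spec.planted_residues:
        hotspot_center = np.array(
            [3.0 * spec.turn_radius, 0.0, spec.rise_per_residue * spec.n_residues / 2]
        )
        for r in spec.planted_residues:
            offset = rng.normal(0.0, 1.0, size=3)
            offset *= rng.uniform(0, spec.planted_radius / 2) / max(
                np.linalg.norm(offset), 1e-9
            )
            centers[r] = hotspot_center + offset

    # four pseudo-atoms in a tetrahedron of zero mean around each center
    tet = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) * 0.6
    buf = io.StringIO()
    serial = 1
    atom_names = ["N", "CA", "C", "O"]
    for i in range(1, spec.n_residues + 1):
        for name, off in zip(atom_names, tet):
            x, y, z = centers[i] + off
            buf.write(
                f"ATOM  {serial:5d} {name:^4s} ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{name[0]:>2s}\n"
            )
            serial += 1
    buf.write("END\n")
    return buf.getvalue(), centers


# ---------------------------------------------------------------------------
# allele-table simulation
# ---------------------------------------------------------------------------


def make_toy_gene(
    rng: np.random.Generator,
    exon1_len: int = 60,
    intron_len: int = 30,
    exon2_len: int = 60,
    flank: int = 15,
) -> GeneModel:
    """A two-exon toy gene whose CDS starts at exon 1 and has no internal stop."""
    while True:
        e1 = _random_dna(rng, exon1_len)
        e2 = _random_dna(rng, exon2_len)
        cds = e1 + e2
        prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
        if "*" not in prot:
            break
    intron = "GT" + _random_dna(rng, intron_len - 4) + "AG"
    left = _random_dna(rng, flank)
    right = _random_dna(rng, flank)
    amplicon = left + e1 + intron + e2 + right
    s1 = flank + 1
    exons = [
        (s1, s1 + exon1_len - 1),
        (s1 + exon1_len + intron_len, s1 + exon1_len + intron_len + exon2_len - 1),
    ]
    return GeneModel(amplicon=amplicon, exons=exons, cds_offset=0, name="toygene")


@dataclass
class AlleleSimSpec:
    """Stated world for the per-sgRNA editing-outcome generator."""

    regime: str = "GOF"  # 'GOF' or 'KO'
    cut_exonic_offset: int = 30  # cut position within exon 1 (1-based, exonic)
    wt_fraction: float = 0.30
    insertion_fraction: float = 0.35  # of edited outcomes: 1-bp insertions
    substitution_fraction: float = 0.10
    deletion_geom_p: float = 0.18  # geometric tail for deletion sizes
    n_outcome_types: int = 40
    selection_strength: float = 2.0  # fitness bonus/penalty on exp scale
    read_depth: int = 10_000

    def __post_init__(self) -> None:
        if self.regime not in {"GOF", "KO"}:
            raise ValueError("regime must be 'GOF' or 'KO'")


@dataclass
class SimulatedAlleles:
    vehicle: pd.DataFrame  # CRISPResso-dialect table
    drug: pd.DataFrame
    predicted: pd.DataFrame  # same dialect, prior without selection
    gene: GeneModel
    regime: str


def _apply_edit(
    ref: str, kind: str, pos: int, size: int, rng: np.random.Generator
) -> tuple[str, str]:
    """Return (aligned_read, aligned_reference) rows for one edit on ``ref``."""
    if kind == "del":
        read = ref[: pos - 1] + "-" * size + ref[pos - 1 + size :]
        return read, ref
    if kind == "ins":
        ins = _random_dna(rng, size)
        read = ref[:pos] + ins + ref[pos:]
        aref = ref[:pos] + "-" * size + ref[pos:]
        return read, aref
    if kind == "sub":
        out = list(ref)
        for k in range(size):
            old = out[pos - 1 + k]
            out[pos - 1 + k] = rng.choice([b for b in "ACGT" if b != old])
        return "".join(out), ref
    raise ValueError(kind)


def simulate_allele_tables(
    spec: AlleleSimSpec, seed: int = 0, gene: GeneModel | None = None
) -> SimulatedAlleles:
    """Vehicle/drug/predicted allele tables under a selection regime.

    Editing outcomes around the cut site follow a mixture prior (1-bp
    insertions, geometric-tailed deletions, substitutions including
    silent ones); the vehicle and predicted tables sample the prior
    directly, while drug frequencies are reweighted by exp(fitness):
    GOF boosts in-frame alleles and penalizes wild-type and LOF, KO
    penalizes all edited alleles equally (in-frame behaving like LOF).
    """
    from . import genotypes  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    if gene is None:
        gene = make_toy_gene(rng)
    ref = gene.amplicon
    exon1 = gene.exons[0]
    cut = exon1[0] + spec.cut_exonic_offset - 1  # amplicon coordinate

    # build outcome catalogue around the cut site
    outcomes: list[tuple[str, str]] = []  # (aligned_read, aligned_ref)
    seen: set[str] = set()

    def _add(read: str, aref: str) -> None:
        key = read
        if key not in seen:
            seen.add(key)
            outcomes.append((read, aref))

    _add(ref, ref)  # wild-type
    while len(outcomes) < spec.n_outcome_types:
        u = rng.uniform()
        if u < spec.insertion_fraction:
            _add(*_apply_edit(ref, "ins", cut, 1, rng))
        elif u < spec.insertion_fraction + spec.substitution_fraction:
            size = int(rng.integers(1, 4))
            start = cut - int(rng.integers(0, 6))
            _add(*_apply_edit(ref, "sub", max(start, 1), size, rng))
        else:
            size = 1 + int(rng.geometric(spec.deletion_geom_p))
            start = cut - int(rng.integers(0, size + 1))
            if start < 1:
                start = 1
            if start - 1 + size > len(ref):
                size = len(ref) - start + 1
            _add(*_apply_edit(ref, "del", start, size, rng))

    reads_rows, ref_rows = zip(*outcomes)
    classes = [
        genotypes.classify_allele(a, r, gene)[0] for a, r in outcomes
    ]

    # prior over outcomes: wild-type mass + broken-stick over edits
    weights = rng.dirichlet(np.ones(len(outcomes) - 1) * 0.8) * (
        1.0 - spec.wt_fraction
    )
    prior = np.concatenate([[spec.wt_fraction], weights])

    s = spec.selection_strength
    if spec.regime == "GOF":
        fitness = {
            genotypes.WILD_TYPE: -s / 2,
            genotypes.IN_FRAME: s,
            genotypes.FRAMESHIFT: -s,
            genotypes.SPLICE_SITE: -s,
            genotypes.NONSENSE: -s,
        }
    else:  # KO: every edit is deleterious, wild-type outgrows
        fitness = {
            genotypes.WILD_TYPE: s / 2,
            genotypes.IN_FRAME: -s,
            genotypes.FRAMESHIFT: -s,
            genotypes.SPLICE_SITE: -s,
            genotypes.NONSENSE: -s,
        }
    drug_w = prior * np.exp([fitness[c] for c in classes])
    drug_p = drug_w / drug_w.sum()

    def _table(p: np.ndarray) -> pd.DataFrame:
        counts = rng.multinomial(spec.read_depth, p)
        rows = []
        for (read, aref), c, cnt in zip(outcomes, classes, counts):
            if cnt == 0:
                continue
            rows.append(
                {
                    "Aligned_Sequence": read,
                    "Reference_Sequence": aref,
                    "Unedited": read == aref,
                    "n_deleted": read.count("-"),
                    "n_inserted": aref.count("-"),
                    "n_mutated": sum(
                        1
                        for x, y in zip(read, aref)
                        if x != y and x != "-" and y != "-"
                    ),
                    "#Reads": int(cnt),
                    "%Reads": cnt / spec.read_depth * 100.0,
                }
            )
        return pd.DataFrame(rows)

    return SimulatedAlleles(
        vehicle=_table(prior),
        drug=_table(drug_p),
        predicted=_table(prior),
        gene=gene,
        regime=spec.regime,
    )
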