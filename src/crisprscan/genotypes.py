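"""Genotype-level variant classification from per-sgRNA allele tables.

Aligned allele tables (CRISPResso2 ``Alleles_frequency_table`` dialect:
aligned read, gapped reference, read counts and frequencies) are
post-processed into protein-level classes:

* ``wild-type``    — no edits, edits outside the CDS, or silent edits;
* ``in-frame``     — net CDS indel divisible by 3, translation differs
                     from reference without a premature stop;
* ``frameshift``   — net CDS indel not divisible by 3;
* ``splice-site``  — any edit hitting the 2 intronic nt flanking an
                     exon, or an indel spanning an intron-exon junction;
* ``nonsense``     — in-frame by indel size but translating to a
                     premature stop.

Frameshift, splice-site, and nonsense are jointly ``loss-of-function``.
In-frame variants are realigned to the reference CDS with a codon-based
global (Needleman-Wunsch) aligner whose gaps open only in whole-codon
units, translated, and named in protein notation (M694_D701del, K592L,
K592S/E593K, M1077_N1081delinsNRFY, ...).  Deletions in repeats are
normalized to their most C-terminal equivalent placement by default.

Frequency handling follows the screen's validation protocol: variants
kept when >= 0.1% frequent in either condition, retained frequencies
renormalized to 100% per condition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

WILD_TYPE = "wild-type"
IN_FRAME = "in-frame"
FRAMESHIFT = "frameshift"
SPLICE_SITE = "splice-site"
NONSENSE = "nonsense"
LOF_CLASSES = frozenset({FRAMESHIFT, SPLICE_SITE, NONSENSE})
CLASSES = (WILD_TYPE, IN_FRAME, FRAMESHIFT, SPLICE_SITE, NONSENSE)

DEFAULT_GAP_PENALTY = -4.0
MIN_FREQ_PCT = 0.1


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Reference amplicon with exon structure and CDS frame anchor.

    ``exons`` are 1-based inclusive intervals on the amplicon, ordered
    and non-overlapping.  ``cds_offset`` counts the CDS nucleotides that
    precede the first exonic base of the amplicon (0 when the amplicon
    starts at the CDS start); it anchors both the reading frame and the
    absolute residue numbering used in variant names.
    """

    amplicon: str
    exons: list[tuple[int, int]]
    cds_offset: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.amplicon = self.amplicon.upper()
        prev_end = 0
        for s, e in self.exons:
            if not (1 <= s <= e <= len(self.amplicon)):
                raise ValueError(f"exon ({s},{e}) outside amplicon")
            if s <= prev_end:
                raise ValueError("exons overlap or are unordered")
            prev_end = e
        if self.cds_offset < 0:
            raise ValueError("cds_offset must be >= 0")
        self._exonic = np.zeros(len(self.amplicon) + 1, dtype=bool)
        for s, e in self.exons:
            self._exonic[s : e + 1] = True

    # -- coordinate predicates ------------------------------------------------

    def is_exonic(self, pos: int) -> bool:
        """1-based amplicon position lies inside an exon."""
        return bool(self._exonic[pos]) if 1 <= pos <= len(self.amplicon) else False

    @property
    def splice_positions(self) -> frozenset[int]:
        """Intronic positions in the 2-nt windows flanking each exon."""
        pos: set[int] = set()
        for s, e in self.exons:
            for p in (s - 2, s - 1, e + 1, e + 2):
                if 1 <= p <= len(self.amplicon) and not self.is_exonic(p):
                    pos.add(p)
        return frozenset(pos)

    @property
    def splice_bonds(self) -> frozenset[int]:
        """Bond indices r (between r and r+1) whose disruption by insertion breaks splicing."""
        bonds: set[int] = set()
        for s, e in self.exons:
            if e + 1 <= len(self.amplicon) and not self.is_exonic(e + 1):
                bonds.update({e, e + 1})  # donor side
            if s - 1 >= 1 and not self.is_exonic(s - 1):
                bonds.update({s - 2, s - 1})  # acceptor side
        return frozenset(b for b in bonds if 1 <= b < len(self.amplicon))

    # -- CDS region -----------------------------------------------------------

    @property
    def exonic_reference(self) -> str:
        return "".join(self.amplicon[s - 1 : e] for s, e in self.exons)

    @property
    def frame_lead(self) -> int:
        """Bases of the leading partial codon in the amplicon's exonic sequence."""
        return (3 - self.cds_offset % 3) % 3

    def reference_codon_region(self) -> tuple[str, int]:
        """Reference exonic sequence trimmed to whole codons + first residue number."""
        seq = self.exonic_reference
        lead = self.frame_lead
        trimmed = seq[lead:]
        trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
        first_residue = (self.cds_offset + lead) // 3 + 1
        return trimmed, first_residue

    def reference_protein(self) -> str:
        region, _ = self.reference_codon_region()
        return str(Seq(region).translate())


# ---------------------------------------------------------------------------
# alignment-column parsing
# ---------------------------------------------------------------------------


@dataclass
class _Edits:
    deletions: list[int] = field(default_factory=list)  # ref positions
    insertions: list[tuple[int, str]] = field(default_factory=list)  # (bond r, base)
    substitutions: list[int] = field(default_factory=list)  # ref positions
    deletion_runs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_edited(self) -> bool:
        return bool(self.deletions or self.insertions or self.substitutions)


def _parse_edits(aligned: str, reference: str) -> _Edits:
    if len(aligned) != len(reference):
        raise ValueError("aligned and reference rows differ in length")
    edits = _Edits()
    r = 0
    run_start = None
    for a, b in zip(aligned.upper(), reference.upper()):
        if b == "-" and a == "-":
            raise ValueError("column with gap in both rows")
        if b == "-":
            edits.insertions.append((r, a))
            continue
        r += 1
        if a == "-":
            edits.deletions.append(r)
            run_start = r if run_start is None else run_start
            continue
        if run_start is not None:
            edits.deletion_runs.append((run_start, r - 1))
            run_start = None
        if a != b and a != "N":
            edits.substitutions.append(r)
    if run_start is not None:
        edits.deletion_runs.append((run_start, r))
    return edits


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _touches_splice(edits: _Edits, gene: GeneModel) -> bool:
    splice = gene.splice_positions
    if splice.intersection(edits.deletions) or splice.intersection(
        edits.substitutions
    ):
        return True
    bonds = gene.splice_bonds
    if any(r in bonds for r, _ in edits.insertions):
        return True
    # indel spanning an intron-exon junction
    for s, e in edits.deletion_runs:
        kinds = {gene.is_exonic(p) for p in range(s, e + 1)}
        if len(kinds) == 2:
            return True
    return False


def _net_cds_indel(edits: _Edits, gene: GeneModel) -> int:
    deleted = sum(1 for p in edits.deletions if gene.is_exonic(p))
    inserted = sum(
        1
        for r, _ in edits.insertions
        if gene.is_exonic(r) and gene.is_exonic(r + 1)
    )
    return inserted - deleted


def _edits_in_cds(edits: _Edits, gene: GeneModel) -> bool:
    if any(gene.is_exonic(p) for p in edits.deletions + edits.substitutions):
        return True
    return any(
        gene.is_exonic(r) and gene.is_exonic(r + 1) for r, _ in edits.insertions
    )


def _variant_codon_region(aligned: str, reference: str, gene: GeneModel) -> str:
    """The allele's spliced CDS-region sequence, trimmed to reference frame.

    Walks the pairwise alignment, keeping read bases at exonic reference
    columns and insertions internal to exons, while discarding the
    leading/trailing partial-codon reference columns so the result is
    comparable codon-by-codon with :meth:`GeneModel.reference_codon_region`.
    """
    ref_region, _ = gene.reference_codon_region()
    lead = gene.frame_lead
    keep_from = lead + 1  # 1-based index into exonic reference
    keep_to = lead + len(ref_region)
    out: list[str] = []
    r = 0  # amplicon reference position
    x = 0  # exonic reference position
    for a, b in zip(aligned.upper(), reference.upper()):
        if b == "-":
            if (
                gene.is_exonic(r)
                and gene.is_exonic(r + 1)
                and keep_from <= x + 1 <= keep_to + 1
                and x >= keep_from - 1
            ):
                out.append(a)
            continue
        r += 1
        if not gene.is_exonic(r):
            continue
        x += 1
        if a != "-" and keep_from <= x <= keep_to:
            out.append(a)
    return "".join(out)


def classify_allele(
    aligned: str, reference: str, gene: GeneModel, gap_penalty: float = DEFAULT_GAP_PENALTY
) -> tuple[str, str | None]:
    """Classify one aligned allele; returns (classification, protein_variant).

    Precedence: unedited -> wild-type; splice disruption -> splice-site;
    net CDS indel not a multiple of 3 -> frameshift; otherwise the
    variant CDS region is realigned codon-wise, translated and compared:
    premature stop -> nonsense, identical protein -> wild-type (silent),
    else in-frame with a protein variant name.  Edits entirely outside
    the CDS that spare splice sites are wild-type at the protein level.
    """
    edits = _parse_edits(aligned, reference)
    if not edits.is_edited:
        return WILD_TYPE, None
    if _touches_splice(edits, gene):
        return SPLICE_SITE, None
    net = _net_cds_indel(edits, gene)
    if net % 3 != 0:
        return FRAMESHIFT, None
    if not _edits_in_cds(edits, gene):
        return WILD_TYPE, None

    ref_region, first_residue = gene.reference_codon_region()
    var_region = _variant_codon_region(aligned, reference, gene)
    if len(var_region) % 3 != 0:
        # an in-frame indel split by the partial-codon trim; treat as in-frame,
        # unnamed, rather than guessing a frame
        return IN_FRAME, None
    alignment, _ = realign_codon_nw(var_region, ref_region, gap_penalty)
    return translate_and_name(alignment, first_residue)


def is_loss_of_function(classification: str) -> bool:
    return classification in LOF_CLASSES


# ---------------------------------------------------------------------------
# codon-based Needleman-Wunsch
# ---------------------------------------------------------------------------


def _codons(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def codon_match_score(codon_a: str, codon_b: str) -> int:
    """Number of identical nucleotides between two aligned codons (0-3)."""
    return sum(a == b for a, b in zip(codon_a, codon_b))


def realign_codon_nw(
    variant_cds: str,
    reference_cds: str,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> tuple[list[tuple[str | None, str | None]], float]:
    """Global codon-unit Needleman-Wunsch alignment of two in-frame CDSs.

    Gaps open and extend only in whole-codon steps aligned to codon
    boundaries; an aligned codon pair scores its nucleotide identity
    count (0-3) and each gapped codon costs ``gap_penalty``.  Ties are
    broken deterministically in favour of the most 3' gap placement.

    Returns the aligned (reference_codon, variant_codon) column list
    (None marks a gap) and the optimal score.
    """
    ref = _codons(reference_cds.upper())
    var = _codons(variant_cds.upper())
    n, m = len(ref), len(var)
    F = np.empty((n + 1, m + 1))
    F[0, :] = np.arange(m + 1) * gap_penalty
    F[:, 0] = np.arange(n + 1) * gap_penalty
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            F[i, j] = max(
                F[i - 1, j - 1] + codon_match_score(ref[i - 1], var[j - 1]),
                F[i - 1, j] + gap_penalty,
                F[i, j - 1] + gap_penalty,
            )
    # traceback runs 3'->5'; preferring gap moves over the diagonal at
    # ties therefore emits gaps as close to the 3' end as possible
    cols: list[tuple[str | None, str | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and F[i, j] == F[i - 1, j] + gap_penalty:
            cols.append((ref[i - 1], None))
            i -= 1
        elif j > 0 and F[i, j] == F[i, j - 1] + gap_penalty:
            cols.append((None, var[j - 1]))
            j -= 1
        else:
            cols.append((ref[i - 1], var[j - 1]))
            i -= 1
            j -= 1
    cols.reverse()
    return cols, float(F[n, m])


def translate_and_name(
    alignment: Sequence[tuple[str | None, str | None]],
    first_residue: int = 1,
) -> tuple[str, str | None]:
    """Translate a codon alignment and name the protein-level change.

    Consumes :func:`realign_codon_nw` output.  A premature stop in the
    variant (before the reference's terminal stop, if any) yields
    ``nonsense``; a protein identical to the reference collapses to
    ``wild-type`` (silent); anything else is ``in-frame`` with a
    protein-variant name anchored at ``first_residue``.
    """
    ref_region = "".join(c for c, _ in alignment if c is not None)
    var_region = "".join(c for _, c in alignment if c is not None)
    ref_prot = str(Seq(ref_region).translate())
    if "*" in ref_prot[:-1]:
        raise ValueError("internal stop codon in reference CDS region")
    var_prot = str(Seq(var_region).translate()) if var_region else ""
    ref_core = ref_prot[:-1] if ref_prot.endswith("*") else ref_prot
    var_core = var_prot[:-1] if var_prot.endswith("*") else var_prot
    if "*" in var_core:
        return NONSENSE, None
    if var_prot == ref_prot:
        return WILD_TYPE, None
    name = name_protein_variant(ref_core, var_core, first_residue)
    if name is None:
        return WILD_TYPE, None
    return IN_FRAME, name


# ---------------------------------------------------------------------------
# protein variant naming
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinVariant:
    """A parsed protein-level variant name."""

    kind: str  # del | ins | delins | sub | multi-sub
    start: int
    end: int
    ref: str = ""
    alt: str = ""

    @property
    def name(self) -> str:
        if self.kind == "del":
            if self.start == self.end:
                return f"{self.ref}{self.start}del"
            return f"{self.ref[0]}{self.start}_{self.ref[-1]}{self.end}del"
        if self.kind == "ins":
            return f"{self.ref[0]}{self.start}_{self.ref[1]}{self.end}ins{self.alt}"
        if self.kind == "delins":
            if self.start == self.end:
                return f"{self.ref}{self.start}delins{self.alt}"
            return f"{self.ref[0]}{self.start}_{self.ref[-1]}{self.end}delins{self.alt}"
        # sub / multi-sub
        subs = [
            f"{r}{self.start + k}{a}"
            for k, (r, a) in enumerate(zip(self.ref, self.alt))
            if r != a
        ]
        return "/".join(subs)


_DEL_RE = re.compile(r"^([A-Z*])(\d+)(?:_([A-Z*])(\d+))?del$")
_INS_RE = re.compile(r"^([A-Z*])(\d+)_([A-Z*])(\d+)ins([A-Z*]+)$")
_DELINS_RE = re.compile(r"^([A-Z*])(\d+)(?:_([A-Z*])(\d+))?delins([A-Z*]+)$")
_SUB_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


def parse_variant_name(name: str, reference_protein: str | None = None) -> ProteinVariant:
    """Inverse of :meth:`ProteinVariant.name` (reference needed only for
    multi-residue del/delins interiors)."""
    if "/" in name:
        parts = [parse_variant_name(p) for p in name.split("/")]
        start = parts[0].start
        end = parts[-1].start
        if reference_protein is None:
            ref = "".join(p.ref for p in parts)
            alt = "".join(p.alt for p in parts)
            if end - start + 1 != len(parts):  # gaps of unchanged residues
                raise ValueError(
                    f"multi-sub {name!r} with unchanged interior needs reference_protein"
                )
        else:
            ref = reference_protein[start - 1 : end]
            alt = list(ref)
            for p in parts:
                alt[p.start - start] = p.alt
            alt = "".join(alt)
        return ProteinVariant("multi-sub", start, end, ref, alt)
    m = _DELINS_RE.match(name)
    if m:
        a1, p1, a2, p2, alt = m.groups()
        start, end = int(p1), int(p2) if p2 else int(p1)
        ref = (
            reference_protein[start - 1 : end]
            if reference_protein
            else a1 + ("?" * (end - start - 1) + (a2 or "") if end > start else "")
        )
        return ProteinVariant("delins", start, end, ref, alt)
    m = _DEL_RE.match(name)
    if m:
        a1, p1, a2, p2 = m.groups()
        start, end = int(p1), int(p2) if p2 else int(p1)
        ref = (
            reference_protein[start - 1 : end]
            if reference_protein
            else a1 + ("?" * (end - start - 1) + (a2 or "") if end > start else "")
        )
        return ProteinVariant("del", start, end, ref, "")
    m = _INS_RE.match(name)
    if m:
        a1, p1, a2, p2, alt = m.groups()
        return ProteinVariant("ins", int(p1), int(p2), a1 + a2, alt)
    m = _SUB_RE.match(name)
    if m:
        r, p, a = m.groups()
        return ProteinVariant("sub", int(p), int(p), r, a)
    raise ValueError(f"unparseable protein variant name {name!r}")


def name_protein_variant(
    ref_protein: str,
    var_protein: str,
    first_residue: int = 1,
    right_align: bool = True,
) -> str | None:
    """Name the difference between reference and variant proteins.

    The edit is localized by maximizing the shared flank; with
    ``right_align`` (default) the common prefix is maximized first, so
    deletions in repeat regions take their most C-terminal equivalent
    placement.  Returns None for identical proteins.
    """
    if ref_protein == var_protein:
        return None
    if right_align:
        p = _common_prefix(ref_protein, var_protein)
        s = _common_suffix(ref_protein[p:], var_protein[p:])
    else:
        s = _common_suffix(ref_protein, var_protein)
        p = _common_prefix(ref_protein[: len(ref_protein) - s], var_protein[: len(var_protein) - s])
    ref_mid = ref_protein[p : len(ref_protein) - s]
    var_mid = var_protein[p : len(var_protein) - s]
    start = first_residue + p
    end = first_residue + p + len(ref_mid) - 1
    if not var_mid:  # pure deletion
        return ProteinVariant("del", start, end, ref_mid, "").name
    if not ref_mid:  # pure insertion, named by flanking residues
        left = first_residue + p - 1
        flank = ref_protein[p - 1 : p + 1] if p >= 1 else "?" + ref_protein[p]
        return ProteinVariant("ins", left, left + 1, flank, var_mid).name
    if len(ref_mid) == len(var_mid):
        kind = "sub" if len(ref_mid) == 1 else "multi-sub"
        return ProteinVariant(kind, start, end, ref_mid, var_mid).name
    return ProteinVariant("delins", start, end, ref_mid, var_mid).name


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _common_suffix(a: str, b: str) -> int:
    return _common_prefix(a[::-1], b[::-1])


# ---------------------------------------------------------------------------
# allele tables
# ---------------------------------------------------------------------------

CRISPRESSO_COLUMNS = [
    "Aligned_Sequence",
    "Reference_Sequence",
    "Unedited",
    "n_deleted",
    "n_inserted",
    "n_mutated",
    "#Reads",
    "%Reads",
]


def read_allele_table(path: str | Path) -> pd.DataFrame:
    """Read a CRISPResso2-dialect allele frequency table (TSV)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CRISPRESSO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"allele table missing columns: {missing}")
    return df


def classify_allele_table(
    table: pd.DataFrame, gene: GeneModel
) -> pd.DataFrame:
    """Classify each row of a CRISPResso-dialect table.

    Adds ``classification``, ``protein_variant`` and ``lof`` columns and
    an ``allele`` key: the gap-free read sequence for edited alleles,
    ``"WT"`` for everything collapsing to wild-type (unedited, silent,
    non-coding edits).
    """
    out = table.copy()
    cls, names, keys = [], [], []
    for row in table.itertuples(index=False):
        c, name = classify_allele(row.Aligned_Sequence, row.Reference_Sequence, gene)
        cls.append(c)
        names.append(name)
        keys.append(
            "WT" if c == WILD_TYPE else row.Aligned_Sequence.replace("-", "")
        )
    out["classification"] = cls
    out["protein_variant"] = names
    out["lof"] = [c in LOF_CLASSES for c in cls]
    out["allele"] = keys
    return out


def merge_conditions(
    vehicle: pd.DataFrame, drug: pd.DataFrame, gene: GeneModel
) -> pd.DataFrame:
    """Classify both condition tables and merge on the allele key.

    Alleles absent from one condition enter at 0 reads / 0%.  Rows with
    the same allele key (notably all wild-type-collapsed rows) are
    pooled.  The result carries per-condition read counts and raw
    (pre-filter) percent frequencies; total read counts are stored in
    ``DataFrame.attrs['total_reads']``.
    """
    merged: dict[str, pd.DataFrame] = {}
    totals: dict[str, float] = {}
    for cond, df in (("vehicle", vehicle), ("drug", drug)):
        c = classify_allele_table(df, gene)
        grouped = (
            c.groupby("allele", sort=False)
            .agg(
                reads=("#Reads", "sum"),
                classification=("classification", "first"),
                protein_variant=("protein_variant", "first"),
            )
            .reset_index()
        )
        totals[cond] = float(grouped["reads"].sum())
        grouped[f"reads_{cond}"] = grouped["reads"]
        grouped[f"freq_{cond}"] = grouped["reads"] / totals[cond] * 100.0
        merged[cond] = grouped.drop(columns=["reads"])
    out = pd.merge(
        merged["vehicle"],
        merged["drug"],
        on="allele",
        how="outer",
        suffixes=("_v", "_d"),
    )
    out["classification"] = out["classification_v"].fillna(out["classification_d"])
    out["protein_variant"] = out["protein_variant_v"].where(
        out["protein_variant_v"].notna(), out["protein_variant_d"]
    )
    out = out.drop(
        columns=[
            "classification_v",
            "classification_d",
            "protein_variant_v",
            "protein_variant_d",
        ]
    )
    for cond in ("vehicle", "drug"):
        out[f"reads_{cond}"] = out[f"reads_{cond}"].fillna(0).astype(int)
        out[f"freq_{cond}"] = out[f"freq_{cond}"].fillna(0.0)
    out["lof"] = out["classification"].isin(LOF_CLASSES)
    out.attrs["total_reads"] = totals
    return out


def filter_and_normalize(
    table: pd.DataFrame, min_freq: float = MIN_FREQ_PCT
) -> pd.DataFrame:
    """Keep variants >= ``min_freq`` % in either condition; renormalize to 100%.

    ``min_freq`` is in percent of total reads, matching the reported
    0.1% retention threshold.
    """
    keep = (table["freq_vehicle"] >= min_freq) | (table["freq_drug"] >= min_freq)
    out = table.loc[keep].copy()
    if out.empty:
        raise ValueError("no variants pass the frequency filter")
    for cond in ("vehicle", "drug"):
        total = out[f"freq_{cond}"].sum()
        if total > 0:
            out[f"freq_{cond}"] = out[f"freq_{cond}"] / total * 100.0
    out.attrs = dict(table.attrs)
    return out


def enriched_inframe_variants(
    table: pd.DataFrame,
    min_drug_freq: float = 1.0,
    min_log2fc: float = 2.0,
) -> pd.DataFrame:
    """In-frame variants >= 1% in drug with log2(drug/vehicle) >= 2.

    Zero vehicle frequencies are replaced by half the smallest
    representable frequency for that condition (one read over the
    condition's total) before the fold-change.
    """
    inframe = table[table["classification"] == IN_FRAME].copy()
    totals = table.attrs.get("total_reads", {})
    floors = {c: 100.0 / totals.get(c, 1e6) / 2.0 for c in ("vehicle", "drug")}
    denom = inframe["freq_vehicle"].where(inframe["freq_vehicle"] > 0, floors["vehicle"])
    numer = inframe["freq_drug"].where(inframe["freq_drug"] > 0, floors["drug"])
    inframe["log2fc"] = np.log2(numer / denom)
    hit = (inframe["freq_drug"] >= min_drug_freq) & (inframe["log2fc"] >= min_log2fc)
    return inframe.loc[hit].sort_values("freq_drug", ascending=False)


def summarize_classes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition absolute class shares and edited-relative IF/LOF shares.

    Absolute shares (percent of total reads) sum to 100; relative shares
    are percent of edited (non-wild-type) reads and are NaN when nothing
    is edited.
    """
    rows = {}
    for cond in ("vehicle", "drug"):
        f = table[f"freq_{cond}"]
        wt = f[table["classification"] == WILD_TYPE].sum()
        inf = f[table["classification"] == IN_FRAME].sum()
        lof = f[table["lof"]].sum()
        edited = inf + lof
        rows[cond] = {
            "wt_abs": wt,
            "if_abs": inf,
            "lof_abs": lof,
            "if_rel": inf / edited * 100.0 if edited > 0 else np.nan,
            "lof_rel": lof / edited * 100.0 if edited > 0 else np.nan,
        }
    return pd.DataFrame(rows).T.rename_axis("condition")
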