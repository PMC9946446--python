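"""Pooled-screen quantification: read counting, resistance scores, hits.

The screen measures, per sgRNA, the change in abundance under drug
selection relative to vehicle, normalized to the plasmid library and
centered on negative-control sgRNAs.  The score chain per sample is

    reads -> reads-per-million -> +1 pseudocount -> log2
          -> subtract plasmid (same transform)
          -> average replicates per condition

and the resistance score of sgRNA i is

    x_i = <drug> - <vehicle> - mean_over_negative_controls(...),

so the negative-control mean is exactly 0 after centering.  An sgRNA is
an enrichment hit when x_i strictly exceeds 2 standard deviations of
the centered negative-control scores.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_PREFIX = "CGAAACACCG"
PROTOSPACER_LEN = 20
_DNA = set("ACGT")


# ---------------------------------------------------------------------------
# library records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SgRNARecord:
    """One library sgRNA and its coordinate assignments.

    ``cut_site_cds`` is the bond index of the blunt Cas9 cut in CDS
    nucleotide coordinates: a value of k means the cut falls between CDS
    nucleotides k and k+1 (Cas9 cuts 3 nt 5' of the PAM, i.e. between
    protospacer positions 17 and 18).  ``residue_assignment`` holds one
    residue when the cut is inside a codon and the two flanking residues
    when it sits exactly on a codon boundary; ``structure_residue`` is
    the single assigned residue, or the even-numbered of the two.
    """

    id: str
    protospacer: str
    gene: str = ""
    cut_site_cds: int | None = None
    residue_assignment: tuple[int, ...] = ()
    structure_residue: int | None = None
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"protospacer of {self.id!r} has length {len(self.protospacer)}, "
                f"expected {PROTOSPACER_LEN}"
            )
        if not set(self.protospacer) <= _DNA:
            raise ValueError(f"protospacer of {self.id!r} has non-ACGT characters")


@dataclass
class SgRNALibrary:
    """An ordered sgRNA library with unique ids and protospacers."""

    records: list[SgRNARecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty sgRNA library")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sgRNA ids in library")
        protos = [r.protospacer for r in self.records]
        if len(set(protos)) != len(protos):
            dupes = sorted({p for p in protos if protos.count(p) > 1})
            raise ValueError(f"duplicate protospacers in library: {dupes[:3]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def negative_control_ids(self) -> list[str]:
        return [r.id for r in self.records if r.is_negative_control]

    @classmethod
    def from_table(cls, path: str | Path, sep: str | None = None) -> "SgRNALibrary":
        """Load a library CSV/TSV with columns id, protospacer, gene, cut_site, is_control."""
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep)
        records = []
        for row in df.itertuples(index=False):
            cut = getattr(row, "cut_site", None)
            cut = None if cut is None or pd.isna(cut) else int(cut)
            if cut is not None:
                residues, struct = map_sgrna_to_residues(cut)
            else:
                residues, struct = (), None
            records.append(
                SgRNARecord(
                    id=str(row.id),
                    protospacer=str(row.protospacer),
                    gene=str(getattr(row, "gene", "")),
                    cut_site_cds=cut,
                    residue_assignment=residues,
                    structure_residue=struct,
                    is_negative_control=bool(getattr(row, "is_control", False)),
                )
            )
        return cls(records)

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "protospacer": [r.protospacer for r in self.records],
                "gene": [r.gene for r in self.records],
                "cut_site": [r.cut_site_cds for r in self.records],
                "is_control": [int(r.is_negative_control) for r in self.records],
            }
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# residue assignment
# ---------------------------------------------------------------------------


def map_sgrna_to_residues(
    cut_site_cds: int, cds_length: int | None = None
) -> tuple[tuple[int, ...], int]:
    """Map a CDS cut bond to its amino-acid assignment.

    The cut after CDS nucleotide k lands inside codon ceil(k/3) when
    k mod 3 != 0, giving a single-residue assignment; when k mod 3 == 0
    the cut sits on the boundary between codons k/3 and k/3+1 and both
    flanking residues are assigned.  The structure residue (used for 3D
    analysis) is the single residue, or the even-numbered of the two.

    Returns ``(residues, structure_residue)``.
    """
    if cut_site_cds < 1:
        raise ValueError(f"cut site bond {cut_site_cds} outside CDS")
    if cds_length is not None and cut_site_cds > cds_length:
        raise ValueError(
            f"cut site bond {cut_site_cds} outside CDS of length {cds_length}"
        )
    if cut_site_cds % 3:
        residue = cut_site_cds // 3 + 1
        return (residue,), residue
    left = cut_site_cds // 3
    if cds_length is not None and cut_site_cds == cds_length:
        # boundary after the final codon: residue left+1 does not exist
        return (left,), left
    residues = (left, left + 1)
    structure = left if left % 2 == 0 else left + 1
    return residues, structure


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------


def _iter_fastq_sequences(path: str | Path) -> Iterable[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for i, line in enumerate(handle):
            if i % 4 == 1:
                yield line.strip().upper()


def count_reads(
    reads: str | Path | Iterable[str],
    library: SgRNALibrary,
    prefix: str = DEFAULT_PREFIX,
) -> tuple[pd.Series, int]:
    """Count reads per sgRNA by exact protospacer match after a fixed prefix.

    The 20-nt sequence immediately downstream of the first occurrence of
    ``prefix`` in the read is looked up in the library with no mismatch
    allowance; each read contributes to at most one sgRNA.  Reads without
    the prefix, reads too short to yield 20 nt after it, and non-matching
    20-mers are tallied as unassigned.

    Parameters
    ----------
    reads
        A FASTQ path (plain or .gz) or an iterable of read sequences.
    library
        The sgRNA library; protospacers must be unique.
    prefix
        Vector-derived constant sequence preceding the protospacer.

    Returns
    -------
    counts, unassigned
        ``counts`` is a Series indexed by sgRNA id (every library member
        present, zeros included); ``unassigned`` the number of
        unassignable reads.
    """
    lookup = {r.protospacer: r.id for r in library}
    counts = {r.id: 0 for r in library}
    unassigned = 0
    seqs = (
        _iter_fastq_sequences(reads)
        if isinstance(reads, (str, Path))
        else (s.upper() for s in reads)
    )
    plen = len(prefix)
    for seq in seqs:
        pos = seq.find(prefix)
        if pos < 0:
            unassigned += 1
            continue
        proto = seq[pos + plen : pos + plen + PROTOSPACER_LEN]
        sgid = lookup.get(proto) if len(proto) == PROTOSPACER_LEN else None
        if sgid is None:
            unassigned += 1
        else:
            counts[sgid] += 1
    return pd.Series(counts, name="count"), unassigned


# ---------------------------------------------------------------------------
# resistance scores
# ---------------------------------------------------------------------------


def _normalize_log2(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample reads-per-million, +1 pseudocount, log2."""
    rpm = counts / counts.sum(axis=0) * 1e6
    return np.log2(rpm + 1.0)


def compute_resistance_scores(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    negative_controls: Sequence[str],
    plasmid_sample: str | None = None,
) -> pd.DataFrame:
    """Compute negative-control-centered resistance scores.

    Parameters
    ----------
    counts
        sgRNA x sample integer count table (all library sgRNAs present).
    design
        Map sample name -> condition, with conditions ``plasmid``,
        ``vehicle`` and ``drug``.  Exactly one plasmid sample.
    negative_controls
        Ids of negative-control sgRNAs (>= 2 required for centering).
    plasmid_sample
        Override the plasmid sample name (else taken from ``design``).

    Returns
    -------
    DataFrame indexed by sgRNA id with columns ``vehicle``, ``drug``
    (library-normalized condition means), ``score`` (the centered
    resistance score x_i), ``excluded`` (zero plasmid reads) and ``hit``.
    Excluded sgRNAs carry NaN scores and are never hits.
    """
    conditions: dict[str, list[str]] = {}
    for sample, cond in design.items():
        conditions.setdefault(cond, []).append(sample)
    if plasmid_sample is None:
        plasmid = conditions.get("plasmid", [])
        if len(plasmid) != 1:
            raise ValueError("design must name exactly one plasmid sample")
        plasmid_sample = plasmid[0]
    for cond in ("vehicle", "drug"):
        if not conditions.get(cond):
            raise ValueError(f"no replicates for condition {cond!r}")
    missing = [s for s in design if s not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from count table: {missing}")
    if (counts.values < 0).any():
        raise ValueError("negative read counts")

    excluded = counts[plasmid_sample] == 0
    log2 = _normalize_log2(counts)
    libnorm = log2.sub(log2[plasmid_sample], axis=0)

    out = pd.DataFrame(index=counts.index)
    for cond in ("vehicle", "drug"):
        out[cond] = libnorm[conditions[cond]].mean(axis=1)
    out["score"] = out["drug"] - out["vehicle"]
    out.loc[excluded, ["vehicle", "drug", "score"]] = np.nan
    out["excluded"] = excluded

    controls = [c for c in negative_controls if c in out.index and not excluded[c]]
    if len(controls) < 2:
        raise ValueError("need >= 2 non-excluded negative controls for centering")
    out["score"] -= out.loc[controls, "score"].mean()
    out["hit"] = call_hits(out["score"], controls)
    out.attrs["negative_controls"] = list(controls)
    return out


def call_hits(scores: pd.Series, negative_controls: Sequence[str]) -> pd.Series:
    """Flag sgRNAs whose score strictly exceeds mean + 2 SD of controls.

    With centered scores the control mean is 0, so the threshold equals
    twice the control standard deviation (sample SD, ddof=1).
    """
    ctrl = scores.loc[list(negative_controls)].dropna()
    if len(ctrl) < 2:
        raise ValueError("hit calling needs >= 2 negative-control scores")
    threshold = ctrl.mean() + 2.0 * ctrl.std(ddof=1)
    hits = scores > threshold
    hits[scores.isna()] = False
    return hits
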