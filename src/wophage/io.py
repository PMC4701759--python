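"""Readers, writers and core record types for the prophage-proteome pipeline.

Everything downstream consumes the types defined here: :class:`ProteinRecord`
for database entries, :class:`PeptideEvidence` / :class:`EvidenceTable` for
MS peptide evidence, plus plain-TSV annotation tables.  Protein masses are
average (not monoisotopic) masses in kilodaltons, matching how proteome
reports print integer kDa values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Functional classes used throughout: phage structural modules (head,
#: baseplate, tail), DNA recombination / replication / modification,
#: virulence & host-interaction, unknown, and a catch-all for proteins
#: outside any prophage region.
FUNCTIONAL_CLASSES = ("HEAD", "BP", "TAIL", "REC", "REP", "MOD", "VIR", "UK", "NONPHAGE")

#: Default peptide-confidence threshold: only >= 95%-confidence peptides count.
CONFIDENCE_THRESHOLD = 0.95

# Average residue (monomer-in-chain) masses in Da.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153
# X (any residue) priced at the unweighted mean of the twenty standard residues.
MEAN_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)

AMINO_ALPHABET = frozenset(AVERAGE_RESIDUE_MASS) | {"X"}


def compute_mass_kda(sequence: str) -> float:
    """Average molecular mass of a protein sequence, in kilodaltons.

    Sum of average residue masses plus one water, divided by 1000.  ``X``
    counts as the mean residue mass.  Raises ``ValueError`` for an empty
    sequence or an illegal character (naming its 1-based position).
    """
    if not sequence:
        raise ValueError("cannot compute mass of an empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(sequence, start=1):
        if aa == "X":
            total += MEAN_RESIDUE_MASS
        else:
            try:
                total += AVERAGE_RESIDUE_MASS[aa]
            except KeyError:
                raise ValueError(
                    f"illegal amino-acid character {aa!r} at position {pos}"
                ) from None
    return total / 1000.0


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up (report convention)."""
    return int(math.floor(x + 0.5))


@dataclass
class ProteinRecord:
    """One database protein: locus tag, sequence and annotation.

    ``mass_kda`` is recomputed from the sequence when not supplied; a supplied
    mass must agree with the sequence-derived one within 1%.
    """

    locus_tag: str
    sequence: str
    genome: str = ""
    homolog_group: str = ""
    functional_class: str = "UK"
    mass_kda: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.locus_tag}: empty sequence")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"{self.locus_tag}: unknown functional class {self.functional_class!r}"
            )
        computed = compute_mass_kda(self.sequence)
        if self.mass_kda is None:
            self.mass_kda = computed
        elif not math.isclose(self.mass_kda, computed, rel_tol=0.01):
            raise ValueError(
                f"{self.locus_tag}: declared mass {self.mass_kda:.3f} kDa differs "
                f"from sequence-derived {computed:.3f} kDa by more than 1%"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideEvidence:
    """One observed peptide in one MS data set.

    ``matched_proteins`` is filled by the matching stage; ``confidence`` below
    the 0.95 threshold keeps the row in the table but excludes it from
    counting.
    """

    peptide: str
    dataset_id: str
    matched_proteins: set[str] = field(default_factory=set)
    confidence: float = 0.99

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide string")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def passes_confidence(self) -> bool:
        return self.confidence >= CONFIDENCE_THRESHOLD


@dataclass
class EvidenceTable:
    """Peptide evidence rows plus the ordered list of MS data-set labels."""

    rows: list[PeptideEvidence]
    dataset_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.dataset_ids)) != len(self.dataset_ids):
            raise ValueError("dataset_ids must be unique")
        known = set(self.dataset_ids)
        for row in self.rows:
            if row.dataset_id not in known:
                raise ValueError(f"unknown dataset label {row.dataset_id!r}")

    def counting_rows(self) -> list[PeptideEvidence]:
        """Rows passing the 95%-confidence threshold (the ones that count)."""
        return [r for r in self.rows if r.passes_confidence]

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# FASTA


def _parse_header(description: str) -> dict[str, str]:
    """Parse ``locus key=value ...`` FASTA description into a field dict."""
    tokens = description.split()
    if not tokens:
        raise ValueError("empty FASTA header")
    fields = {"locus_tag": tokens[0]}
    for tok in tokens[1:]:
        if "=" not in tok:
            raise ValueError(
                f"malformed FASTA header near {tok!r} in record {tokens[0]!r}: "
                "expected key=value annotations"
            )
        key, value = tok.split("=", 1)
        fields[key] = value
    return fields


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects, in file order.

    Header convention: ``>LOCUS genome=... class=... group=...`` where the
    key=value annotations are optional.  Masses are computed from sequence.
    An empty file yields an empty list.
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = _parse_header(rec.description)
        records.append(
            ProteinRecord(
                locus_tag=fields["locus_tag"],
                sequence=str(rec.seq).upper(),
                genome=fields.get("genome", ""),
                homolog_group=fields.get("group", ""),
                functional_class=fields.get("class", "UK"),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records in the same header dialect :func:`read_fasta` reads."""
    seqrecords = []
    for r in records:
        parts = [r.locus_tag]
        if r.genome:
            parts.append(f"genome={r.genome}")
        if r.functional_class != "UK":
            parts.append(f"class={r.functional_class}")
        if r.homolog_group:
            parts.append(f"group={r.homolog_group}")
        seqrecords.append(
            SeqRecord(Seq(r.sequence), id=r.locus_tag,
                      description=" ".join(parts[1:]))
        )
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# Evidence TSV

EVIDENCE_COLUMNS = ["peptide", "dataset", "proteins", "confidence"]


def read_evidence(path: str | Path, dataset_ids: Sequence[str] | None = None) -> EvidenceTable:
    """Read a peptide-evidence TSV (peptide, dataset, proteins, confidence).

    ``proteins`` is a semicolon-joined locus-tag list (may be empty before
    matching).  When ``dataset_ids`` is given, any row with a label outside it
    is an error; otherwise labels are taken in order of first appearance.
    Low-confidence rows are retained (flagged by ``passes_confidence``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "dataset": str,
                                            "proteins": str})
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"evidence table missing column(s): {', '.join(missing)}")
    rows = []
    seen: list[str] = []
    for rec in df.itertuples(index=False):
        ds = str(rec.dataset)
        if dataset_ids is not None and ds not in dataset_ids:
            raise ValueError(f"unknown dataset label {ds!r}")
        if ds not in seen:
            seen.append(ds)
        prot = "" if pd.isna(rec.proteins) else str(rec.proteins)
        matched = {p for p in prot.split(";") if p}
        rows.append(PeptideEvidence(str(rec.peptide), ds, matched,
                                    float(rec.confidence)))
    labels = list(dataset_ids) if dataset_ids is not None else seen
    return EvidenceTable(rows=rows, dataset_ids=labels)


def write_evidence(table: EvidenceTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "peptide": [r.peptide for r in table.rows],
            "dataset": [r.dataset_id for r in table.rows],
            "proteins": [";".join(sorted(r.matched_proteins)) for r in table.rows],
            "confidence": [r.confidence for r in table.rows],
        },
        columns=EVIDENCE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation TSV

ANNOTATION_COLUMNS = ["locus_tag", "class", "region", "group", "kda"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a per-protein annotation TSV (locus_tag, class, region, group, kda)."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_tag": str}, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing column(s): {', '.join(missing)}")
    bad = set(df["class"]) - set(FUNCTIONAL_CLASSES)
    if bad:
        raise ValueError(f"unknown functional class(es): {sorted(bad)}")
    return df[ANNOTATION_COLUMNS]


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)
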