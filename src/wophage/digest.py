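"""In-silico tryptic digestion, peptide-to-protein matching and detection filters.

The matching model is deliberately simple and transparent: a peptide is
credited to every database protein that contains it as an exact substring
(peptides hitting more than one protein are flagged *shared*, mirroring the
mosaic multi-homolog matches seen when several *Wolbachia* genomes are
searched at once).  Counting operates on distinct peptide sequences per
(protein, data set) cell — classic spectral counting of unique peptides.
"""

from __future__ import annotations

import bisect
import copy
from dataclasses import dataclass, field

import pandas as pd
from pyteomics import parser as _pparser

from .io import EvidenceTable, PeptideEvidence, ProteinRecord, round_half_up

#: cleave C-terminal to K/R unless followed by P
TRYPSIN_RULE = r"[KR](?!P)"


def tryptic_digest(sequence: str, min_len: int = 1, max_missed: int = 0) -> list[tuple[str, int]]:
    """Tryptic peptides of ``sequence`` with 1-based start positions.

    Cleaves C-terminal to K/R except before P.  Peptides shorter than
    ``min_len`` are dropped; up to ``max_missed`` internal missed cleavages
    are allowed.  Result is sorted by (start, length).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not sequence:
        return []
    out = [
        (pep, start + 1)
        for start, pep in _pparser.icleave(
            sequence, TRYPSIN_RULE, missed_cleavages=max_missed, min_length=min_len
        )
    ]
    out.sort(key=lambda t: (t[1], len(t[0])))
    return out


def peptide_set(sequence: str, min_len: int = 6, max_missed: int = 1) -> set[str]:
    """Distinct theoretical tryptic peptides (default: length >= 6, <= 1 missed)."""
    return {pep for pep, _ in tryptic_digest(sequence, min_len, max_missed)}


# ---------------------------------------------------------------------------


@dataclass
class HomologGroup:
    """Set of homologous locus tags (possibly across genomes) plus a representative."""

    group_id: str
    members: set[str]
    representative: str

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(
                f"group {self.group_id}: representative {self.representative!r} "
                "not among members"
            )


class DetectionMatrix:
    """Per (protein, data set) unique-peptide evidence.

    Cells hold the *set* of distinct matched peptide strings; counts are cell
    sizes, totals are unions over data sets, and coverage is the merged span
    of every occurrence of every matched peptide divided by protein length.
    """

    def __init__(self, proteins: list[str], dataset_ids: list[str],
                 sequences: dict[str, str] | None = None):
        self.proteins = list(proteins)
        self.dataset_ids = list(dataset_ids)
        self.sequences = dict(sequences or {})
        self.cells: dict[str, dict[str, set[str]]] = {
            p: {d: set() for d in self.dataset_ids} for p in self.proteins
        }
        self.shared_peptides: set[str] = set()
        self.unmatched: list[PeptideEvidence] = []

    # -- counting ----------------------------------------------------------
    def add(self, locus: str, dataset: str, peptide: str) -> None:
        self.cells[locus][dataset].add(peptide)

    def unique_peptide_count(self, locus: str, dataset: str) -> int:
        return len(self.cells[locus][dataset])

    def union_peptides(self, locus: str) -> set[str]:
        cells = self.cells[locus]
        out: set[str] = set()
        for d in self.dataset_ids:
            out |= cells[d]
        return out

    def total_unique_peptides(self, locus: str) -> int:
        return len(self.union_peptides(locus))

    def counts_per_dataset(self, locus: str) -> list[int]:
        return [self.unique_peptide_count(locus, d) for d in self.dataset_ids]

    def total_matched_peptides(self) -> int:
        """Distinct (protein, peptide) pairings over the whole matrix."""
        return sum(self.total_unique_peptides(p) for p in self.proteins)

    def coverage_pct(self, locus: str) -> float:
        seq = self.sequences.get(locus)
        if seq is None:
            raise KeyError(f"no sequence stored for {locus}")
        peps = self.union_peptides(locus)
        if not peps:
            return 0.0
        return coverage_from_peptides(seq, peps)

    # -- export ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: one ``n/cov`` column per data set plus totals.

        Per-data-set cells use the compact ``peptides/coverage`` notation
        (e.g. ``2/5`` = 2 peptides covering 5% of the protein).
        """
        rows = []
        for p in self.proteins:
            row: dict[str, object] = {"locus_tag": p}
            for d in self.dataset_ids:
                n = self.unique_peptide_count(p, d)
                cov = (
                    coverage_from_peptides(self.sequences[p], self.cells[p][d])
                    if n and p in self.sequences else 0.0
                )
                row[d] = render_cell(n, cov)
            row["total_peptides"] = self.total_unique_peptides(p)
            row["coverage_pct"] = (
                round_half_up(self.coverage_pct(p)) if p in self.sequences else ""
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def copy(self) -> "DetectionMatrix":
        new = DetectionMatrix(self.proteins, self.dataset_ids, self.sequences)
        new.cells = copy.deepcopy(self.cells)
        new.shared_peptides = set(self.shared_peptides)
        new.unmatched = list(self.unmatched)
        return new


def render_cell(n_peptides: int, coverage_pct: float) -> str:
    """Compact ``n/cov`` notation: 2 peptides at 5% coverage renders as ``2/5``."""
    return f"{n_peptides}/{round_half_up(coverage_pct)}"


# ---------------------------------------------------------------------------
# coverage


def _occurrences(sequence: str, peptide: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) occurrence intervals, half-open 0-based."""
    spans = []
    start = sequence.find(peptide)
    while start != -1:
        spans.append((start, start + len(peptide)))
        start = sequence.find(peptide, start + 1)
    return spans


def coverage_from_peptides(sequence: str, peptides: set[str] | list[str]) -> float:
    """Percent of residues covered by the union of all peptide occurrences.

    Every occurrence of every peptide contributes; intervals are merged.
    A peptide absent from the sequence is an error.
    """
    spans: list[tuple[int, int]] = []
    for pep in peptides:
        occ = _occurrences(sequence, pep)
        if not occ:
            raise ValueError(f"peptide {pep!r} is not a substring of the protein")
        spans.extend(occ)
    if not spans:
        return 0.0
    spans.sort()
    covered = 0
    cur_lo, cur_hi = spans[0]
    for lo, hi in spans[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return 100.0 * covered / len(sequence)


def compute_coverage(protein: ProteinRecord, matched_peptides: set[str]) -> float:
    """Coverage of ``protein`` by ``matched_peptides`` (see module docstring)."""
    if not matched_peptides:
        return 0.0
    return coverage_from_peptides(protein.sequence, matched_peptides)


# ---------------------------------------------------------------------------
# matching


class _SubstringIndex:
    """Locate which database proteins contain a peptide, via one concatenated
    string with ``#`` separators (C-speed ``str.find`` instead of a per-protein
    Python loop)."""

    def __init__(self, db: list[ProteinRecord]):
        self.loci = [r.locus_tag for r in db]
        offsets = []
        pos = 0
        chunks = []
        for r in db:
            offsets.append(pos)
            chunks.append(r.sequence)
            pos += len(r.sequence) + 1
        self.offsets = offsets
        self.blob = "#".join(chunks)

    def containing(self, peptide: str) -> set[str]:
        hits: set[str] = set()
        start = self.blob.find(peptide)
        while start != -1:
            idx = bisect.bisect_right(self.offsets, start) - 1
            hits.add(self.loci[idx])
            start = self.blob.find(peptide, start + 1)
        return hits


def map_peptides(evidence: EvidenceTable, db: list[ProteinRecord]) -> DetectionMatrix:
    """Match evidence peptides onto a protein database by exact substring.

    Only rows at >= 95% confidence are counted.  A peptide contained in more
    than one protein is credited to every containing protein and flagged
    shared; a peptide contained in none goes to ``matrix.unmatched`` (the
    input pool for :func:`refined_search`).  Each row's ``matched_proteins``
    is updated in place.
    """
    matrix = DetectionMatrix(
        [r.locus_tag for r in db], list(evidence.dataset_ids),
        {r.locus_tag: r.sequence for r in db},
    )
    index = _SubstringIndex(db)
    cache: dict[str, set[str]] = {}
    for row in evidence.counting_rows():
        hits = cache.get(row.peptide)
        if hits is None:
            hits = index.containing(row.peptide)
            cache[row.peptide] = hits
        row.matched_proteins = set(hits)
        if not hits:
            matrix.unmatched.append(row)
            continue
        if len(hits) > 1:
            matrix.shared_peptides.add(row.peptide)
        for locus in hits:
            matrix.add(locus, row.dataset_id, row.peptide)
    return matrix


DETECTION_MODES = ("stringent", "relaxed")


def apply_detection_filter(matrix: DetectionMatrix, mode: str,
                           stringent_min: int = 2) -> set[str]:
    """Protein inclusion filter.

    ``stringent``: keep a protein iff some single data set contributed at
    least ``stringent_min`` (default 2) unique peptides.  ``relaxed``: keep
    iff at least one unique peptide was seen anywhere (admits single-peptide
    detections).
    """
    if mode not in DETECTION_MODES:
        raise ValueError(f"unknown detection mode {mode!r}; expected one of {DETECTION_MODES}")
    kept: set[str] = set()
    for p in matrix.proteins:
        if mode == "stringent":
            if any(matrix.unique_peptide_count(p, d) >= stringent_min
                   for d in matrix.dataset_ids):
                kept.add(p)
        else:
            if matrix.total_unique_peptides(p) >= 1:
                kept.add(p)
    return kept


# ---------------------------------------------------------------------------
# refined search


def refined_search(matrix: DetectionMatrix, new_db: list[ProteinRecord]
                   ) -> tuple[DetectionMatrix, pd.DataFrame]:
    """Re-scan the unmatched peptide pool against newly added proteins.

    Emulates augmenting the original search database with newly sequenced
    genes and re-searching: previously matched counts never decrease, and the
    returned report lists each newly matched (locus, dataset, peptide).
    """
    out = matrix.copy()
    for rec in new_db:
        if rec.locus_tag not in out.cells:
            out.proteins.append(rec.locus_tag)
            out.cells[rec.locus_tag] = {d: set() for d in out.dataset_ids}
        out.sequences[rec.locus_tag] = rec.sequence
    index = _SubstringIndex(new_db)
    report_rows = []
    still_unmatched = []
    for row in out.unmatched:
        hits = index.containing(row.peptide)
        if not hits:
            still_unmatched.append(row)
            continue
        row.matched_proteins |= hits
        if len(hits) > 1:
            out.shared_peptides.add(row.peptide)
        for locus in sorted(hits):
            out.add(locus, row.dataset_id, row.peptide)
            report_rows.append(
                {"locus_tag": locus, "dataset": row.dataset_id, "peptide": row.peptide}
            )
    out.unmatched = still_unmatched
    report = pd.DataFrame(report_rows, columns=["locus_tag", "dataset", "peptide"])
    return out, report


def n_new_peptides(report: pd.DataFrame) -> int:
    """Distinct peptide sequences newly matched by a refined search."""
    return report["peptide"].nunique() if len(report) else 0


# ---------------------------------------------------------------------------
# homolog-group aggregation


def aggregate_by_group(matrix: DetectionMatrix, groups: list[HomologGroup]
                       ) -> DetectionMatrix:
    """Collapse the matrix onto homolog groups (union of member peptide sets).

    Groups must be disjoint; proteins not covered by any group become
    singleton groups of themselves.  The aggregated matrix carries the
    representative's sequence, so coverage there refers to the representative
    (peptides from other members that do not occur in it are skipped when
    computing coverage).
    """
    owner: dict[str, HomologGroup] = {}
    for g in groups:
        for m in g.members:
            if m in owner:
                raise ValueError(f"protein {m} belongs to two groups "
                                 f"({owner[m].group_id} and {g.group_id})")
            owner[m] = g
    all_groups = list(groups)
    for p in matrix.proteins:
        if p not in owner:
            g = HomologGroup(p, {p}, p)
            owner[p] = g
            all_groups.append(g)

    out = DetectionMatrix([g.group_id for g in all_groups], matrix.dataset_ids)
    for g in all_groups:
        if g.representative in matrix.sequences:
            out.sequences[g.group_id] = matrix.sequences[g.representative]
        for d in matrix.dataset_ids:
            merged: set[str] = set()
            for m in g.members:
                if m in matrix.cells:
                    merged |= matrix.cells[m][d]
            out.cells[g.group_id][d] = merged
    out.shared_peptides = set(matrix.shared_peptides)
    return out


def group_coverage_pct(matrix: DetectionMatrix, group_id: str) -> float:
    """Coverage of the group's representative by the member-union peptides
    that actually occur in it."""
    seq = matrix.sequences[group_id]
    peps = {p for p in matrix.union_peptides(group_id) if p in seq}
    if not peps:
        return 0.0
    return coverage_from_peptides(seq, peps)
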