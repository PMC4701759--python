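"""Pairwise identity, gene-array layout and direct-repeat detection.

Percent identity follows the BLAST convention: matches divided by alignment
length *including* internal gap columns.  Default scoring mirrors the
classic BLASTn (+2/-3, gap open 5 extend 2) and BLASTp (BLOSUM62, open 11
extend 1) parameter sets; identities of diverged pairs may differ from NCBI
output by a point or two because alignment extent depends on the scoring
details.  Dynamic programming is delegated to Bio.Align.PairwiseAligner;
tests pin it against exhaustive alignment enumeration on short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

MODES = ("global", "local")


@dataclass(frozen=True)
class Scoring:
    """Match/mismatch or substitution-matrix scoring with affine gap costs.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST convention).
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    matrix: str | None = None  # e.g. "BLOSUM62"; overrides match/mismatch


#: BLASTn-like nucleotide defaults.
NUCLEOTIDE_SCORING = Scoring(match=2.0, mismatch=-3.0, gap_open=5.0, gap_extend=2.0)
#: BLASTp-like protein defaults.
PROTEIN_SCORING = Scoring(gap_open=11.0, gap_extend=1.0, matrix="BLOSUM62")


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    identities: int
    alignment_length: int
    mode: str
    scoring: Scoring
    score: float = 0.0

    @property
    def identity_pct(self) -> float:
        # a local alignment can be empty when no segment scores positively
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.identities / self.alignment_length

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings differ in length")
        if self.alignment_length != len(self.aligned_a):
            raise ValueError("alignment_length inconsistent with gapped strings")


def _make_aligner(mode: str, scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if scoring.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    # biopython scores a length-k gap as open + (k-1)*extend with its own
    # open_gap_score; fold the BLAST convention (open + k*extend) into that.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    if mode == "global":
        # end gaps are free only in local mode; keep them priced globally
        pass
    return aligner


def _identities(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x == y and x != "-")


def align_identity(a: str, b: str, mode: str = "global",
                   scoring: Scoring | None = None) -> AlignmentResult:
    """Optimal pairwise alignment and its percent identity.

    ``mode`` is ``global`` (end-to-end) or ``local`` (best-scoring segment).
    Identity is counted over all alignment columns, internal gaps included.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if scoring is None:
        scoring = PROTEIN_SCORING if _looks_protein(a + b) else NUCLEOTIDE_SCORING
    aligner = _make_aligner(mode, scoring)
    try:
        aln = aligner.align(a, b)[0]
    except IndexError:
        # local mode with no positive-scoring segment: empty alignment
        return AlignmentResult(aligned_a="", aligned_b="", identities=0,
                               alignment_length=0, mode=mode, scoring=scoring,
                               score=0.0)
    ga, gb = str(aln[0]), str(aln[1])
    return AlignmentResult(
        aligned_a=ga, aligned_b=gb,
        identities=_identities(ga, gb),
        alignment_length=len(ga),
        mode=mode, scoring=scoring, score=float(aln.score),
    )


_NUC = set("ACGTUN")


def _looks_protein(seq: str) -> bool:
    return any(c not in _NUC for c in seq.upper())


def concat_identity(gene_pairs: list[tuple[str, str]], mode: str = "global",
                    scoring: Scoring | None = None) -> AlignmentResult:
    """Align the in-order concatenations of each side of a syntenic gene list."""
    if not gene_pairs:
        raise ValueError("need at least one gene pair")
    a = "".join(p[0] for p in gene_pairs)
    b = "".join(p[1] for p in gene_pairs)
    return align_identity(a, b, mode=mode, scoring=scoring)


# ---------------------------------------------------------------------------
# gene arrays


@dataclass
class Orf:
    """One open reading frame on a contiguous sequence (1-based inclusive)."""

    locus_tag: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"{self.locus_tag}: bad coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_tag}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneArray:
    """Ordered ORFs on one contiguous nucleotide sequence."""

    orfs: list[Orf]
    sequence: str = ""

    def __post_init__(self) -> None:
        starts = [o.start for o in self.orfs]
        if starts != sorted(starts):
            raise ValueError("ORFs must be sorted by start coordinate")
        if self.sequence:
            for o in self.orfs:
                if o.end > len(self.sequence):
                    raise ValueError(f"{o.locus_tag} extends past the sequence end")

    def orf_sequence(self, locus_tag: str) -> str:
        """ORF nucleotide sequence, reverse-complemented for minus-strand genes."""
        o = next(x for x in self.orfs if x.locus_tag == locus_tag)
        sub = self.sequence[o.start - 1:o.end]
        return str(Seq(sub).reverse_complement()) if o.strand == "-" else sub


def intergenic_layout(array: GeneArray) -> pd.DataFrame:
    """Gaps between consecutive ORFs in genomic coordinates (strand-agnostic).

    ``gap_bp = next.start - prev.end - 1``: zero means directly adjacent,
    negative means overlapping ORFs.
    """
    rows = []
    for prev, nxt in zip(array.orfs, array.orfs[1:]):
        rows.append({
            "upstream_locus": prev.locus_tag,
            "downstream_locus": nxt.locus_tag,
            "gap_bp": nxt.start - prev.end - 1,
        })
    return pd.DataFrame(rows, columns=["upstream_locus", "downstream_locus", "gap_bp"])


# ---------------------------------------------------------------------------
# direct repeats


@dataclass(frozen=True)
class RepeatPair:
    """Two same-strand occurrences of a subsequence (1-based positions)."""

    pos1: int
    pos2: int
    length: int
    mismatches: int = 0


def find_direct_repeats(sequence: str, min_len: int, max_mismatch: int = 0
                        ) -> list[RepeatPair]:
    """Maximal non-overlapping same-strand repeat pairs.

    A pair (i, j, L) qualifies when the two length-L windows at i and j have
    at most ``max_mismatch`` mismatches, do not overlap (j - i >= L), and are
    maximal: no single-position extension left or right stays within the
    mismatch budget, the sequence, and the non-overlap constraint.  Windows
    contained in a longer reported window on the same diagonal are
    suppressed.  Positions are 1-based; result sorted by (pos1, pos2).
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    n = len(sequence)
    out: list[RepeatPair] = []
    for d in range(min_len, n - min_len + 1):  # d = j - i; non-overlap needs L <= d
        prev_end = -1  # containment suppression per diagonal
        for i in range(0, n - d - min_len + 1):
            j = i + d
            max_l = min(d, n - j)
            if max_l < min_len:
                break
            # greedy maximal extension from i within the mismatch budget
            mm = 0
            L = 0
            while L < max_l:
                if sequence[i + L] != sequence[j + L]:
                    if mm == max_mismatch:
                        break
                    mm += 1
                L += 1
            if L < min_len:
                continue
            if i + L <= prev_end:
                continue  # contained in the previous window on this diagonal
            left_ext = (
                i > 0 and L + 1 <= d
                and (mm + (1 if sequence[i - 1] != sequence[j - 1] else 0))
                <= max_mismatch
            )
            if left_ext:
                continue  # not maximal; the left-extended window is reported instead
            out.append(RepeatPair(i + 1, j + 1, L, mm))
            prev_end = i + L
    out.sort(key=lambda r: (r.pos1, r.pos2))
    return out


def repeats_frame(repeats: list[RepeatPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"pos1": r.pos1, "pos2": r.pos2, "length": r.length,
          "mismatches": r.mismatches} for r in repeats],
        columns=["pos1", "pos2", "length", "mismatches"],
    )


def alignment_frame(results: dict[str, AlignmentResult]) -> pd.DataFrame:
    """Alignment report rows (pair label -> result) in TSV-ready form."""
    rows = []
    for label, r in results.items():
        rows.append({"pair": label, "mode": r.mode, "identities": r.identities,
                     "alignment_length": r.alignment_length,
                     "identity_pct": round(r.identity_pct, 1)})
    return pd.DataFrame(rows, columns=["pair", "mode", "identities",
                                       "alignment_length", "identity_pct"])
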