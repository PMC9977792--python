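"""DDE/DDD catalytic-triad detection and aligned-domain statistics.

The spacing class names the number of residues strictly between the second
aspartate and the final catalytic residue, e.g. D..D<34>E -> "DD34E".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Align import substitution_matrices

from .errors import ValidationError

#: spacing classes observed across the family: the common 34 plus rarer
#: 37/38/39 variants and the 40 of the large yeast element.
DEFAULT_SPACING_SET = frozenset({34, 37, 38, 39, 40})
DEFAULT_LAST_RESIDUES = frozenset({"D", "E"})
DEFAULT_D1_D2_RANGE = (50, 250)
GLYCINE_WINDOW = 30  # +/- residues around each anchor scored for conserved G


@dataclass(frozen=True)
class DdeTriad:
    """Catalytic residue positions (1-based) with the spacing-class string."""

    d1_pos: int
    d2_pos: int
    last_pos: int
    last_residue: str
    evidence_score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.d1_pos < self.d2_pos < self.last_pos):
            raise ValidationError(
                f"triad positions must be ordered: {self.d1_pos}, {self.d2_pos}, {self.last_pos}"
            )
        if self.last_residue not in {"D", "E"}:
            raise ValidationError(f"last residue must be D or E, got {self.last_residue!r}")

    @property
    def spacing(self) -> int:
        return self.last_pos - self.d2_pos - 1

    @property
    def spacing_class(self) -> str:
        return f"DD{self.spacing}{self.last_residue}"


@dataclass(frozen=True)
class DomainSpan:
    """1-based inclusive residue span of a protein domain."""

    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if self.start_aa < 1 or self.end_aa < self.start_aa:
            raise ValidationError(f"bad span {self.start_aa}-{self.end_aa}")

    @property
    def length_aa(self) -> int:
        return self.end_aa - self.start_aa + 1


@dataclass(frozen=True)
class PairwiseDomainStats:
    n_cols: int
    n_identical: int
    n_positive: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_identical <= self.n_positive <= self.n_cols):
            raise ValidationError(
                f"inconsistent counts: {self.n_identical} identical, "
                f"{self.n_positive} positive, {self.n_cols} columns"
            )

    @property
    def identity_pct(self) -> float:
        return round(100.0 * self.n_identical / self.n_cols, 2)

    @property
    def positives_pct(self) -> float:
        return round(100.0 * self.n_positive / self.n_cols, 1)


def spacing_class(d1: int, d2: int, last: int, last_residue: str) -> str:
    """Class string for a triad, e.g. (892, 1056, 1097, 'E') -> 'DD40E'.

    Only the d2->last spacing names the class; d1 must merely precede d2.
    """
    if not (d1 < d2 < last):
        raise ValidationError(f"positions must satisfy d1 < d2 < last: {d1}, {d2}, {last}")
    if last_residue not in {"D", "E"}:
        raise ValidationError(f"last residue must be D or E, got {last_residue!r}")
    return f"DD{last - d2 - 1}{last_residue}"


def domain_length(span: DomainSpan) -> int:
    return span.length_aa


def insert_span(region_start: int, region_end: int) -> int:
    """Inclusive length of a residue region, e.g. (945, 994) -> 50."""
    if region_start > region_end:
        raise ValidationError(f"start {region_start} > end {region_end}")
    return region_end - region_start + 1


def _glycine_evidence(protein: str, positions: tuple[int, int, int], window: int = GLYCINE_WINDOW) -> float:
    """Count glycines in the union of +/-window residue neighborhoods of the anchors."""
    covered: set[int] = set()
    n = len(protein)
    for p in positions:
        covered.update(range(max(1, p - window), min(n, p + window) + 1))
    return float(sum(1 for i in covered if protein[i - 1] == "G"))


def find_dde_triads(
    protein: str,
    spacing_set: frozenset[int] | set[int] = DEFAULT_SPACING_SET,
    last_residues: frozenset[str] | set[str] = DEFAULT_LAST_RESIDUES,
    d1_d2_range: tuple[int, int] = DEFAULT_D1_D2_RANGE,
) -> list[DdeTriad]:
    """All (D, D, D/E) triads with the requested geometry.

    Returns triads with last_pos - d2 - 1 in spacing_set and d2 - d1 - 1
    within d1_d2_range, scored by glycine context (conserved-G evidence) and
    sorted by score descending, then total span ascending, then d1 ascending.
    """
    if not spacing_set:
        raise ValidationError("spacing_set must be non-empty")
    protein = protein.upper()
    d_positions = [i + 1 for i, aa in enumerate(protein) if aa == "D"]
    last_positions = [i + 1 for i, aa in enumerate(protein) if aa in last_residues]
    lo, hi = d1_d2_range
    spacing_set = set(spacing_set)
    triads = []
    for d2 in d_positions:
        lasts = [d2 + s + 1 for s in spacing_set]
        for last in lasts:
            if last > len(protein) or protein[last - 1] not in last_residues:
                continue
            for d1 in d_positions:
                gap = d2 - d1 - 1
                if gap < lo:
                    break  # d_positions ascending: later d1 only shrink the gap
                if gap > hi:
                    continue
                score = _glycine_evidence(protein, (d1, d2, last))
                triads.append(DdeTriad(d1, d2, last, protein[last - 1], score))
    triads.sort(key=lambda t: (-t.evidence_score, t.last_pos - t.d1_pos, t.d1_pos, t.d2_pos))
    return triads


def load_matrix(name: str = "BLOSUM62"):
    """Load a substitution matrix by name or from an NCBI-format file path."""
    p = Path(name)
    if p.exists():
        return substitution_matrices.read(str(p))
    return substitution_matrices.load(name)


def pairwise_domain_stats(
    aligned_a: str, aligned_b: str, substitution_matrix: str = "BLOSUM62"
) -> PairwiseDomainStats:
    """Identity and positive-substitution counts over an aligned pair.

    Columns where both rows carry a residue (no gap) are counted; a column is
    positive when its substitution score is > 0, identities included.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValidationError(
            f"aligned lengths differ: {len(aligned_a)} vs {len(aligned_b)}"
        )
    matrix = load_matrix(substitution_matrix)
    gaps = {"-", ".", "*"}
    n_cols = n_id = n_pos = 0
    for a, b in zip(aligned_a.upper(), aligned_b.upper()):
        if a in gaps or b in gaps:
            continue
        n_cols += 1
        if a == b:
            n_id += 1
        if matrix[a, b] > 0:
            n_pos += 1
    return PairwiseDomainStats(n_cols=n_cols, n_identical=n_id, n_positive=n_pos)
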