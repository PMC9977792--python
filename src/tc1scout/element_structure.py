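"""Element evidence rules: TIR pairs, excision-site/TSD checks, five-part
layout assembly, and boundary inference from homolog presence/absence groups.

An element is called on three pieces of evidence: (1) terminal inverted
repeats at both ends, (2) excision-site symmetry with the target-site
duplication on each flank, and (3) a transposase ORF between the TIRs.
Elements whose TIRs have decayed beyond recognition are represented with
zero-length TIR segments so the segment-sum invariant holds universally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .core_io import GenomeSequence, Interval, revcomp
from .errors import (
    AmbiguousBoundaryError,
    InsufficientFlankError,
    LayoutError,
    ValidationError,
)

DEFAULT_TIR_MIN_LEN = 10
DEFAULT_TIR_MAX_LEN = 250
DEFAULT_TSD = "TA"


@dataclass(frozen=True)
class TirPair:
    """Matched terminal inverted repeats; identity compares the 5' TIR with
    the reverse complement of the 3' TIR."""

    tir5: Interval
    tir3: Interval
    identity: float

    def __post_init__(self) -> None:
        if self.tir5.end >= self.tir3.start:
            raise ValidationError("5' TIR must lie strictly upstream of 3' TIR")
        if self.tir5.length() != self.tir3.length():
            raise ValidationError("TIR lengths differ")
        if not 0.0 <= self.identity <= 1.0:
            raise ValidationError(f"identity {self.identity} outside [0,1]")

    @property
    def length(self) -> int:
        return self.tir5.length()


@dataclass(frozen=True)
class ElementLayout:
    """Five-segment anatomy (5'TIR, 5'UTR, ORF, 3'UTR, 3'TIR) + excision evidence.

    Unknown TIRs are zero-length segments, never absent fields, so
    tir5 + utr5 + orf + utr3 + tir3 always equals the element length.
    """

    element: Interval
    tir5_len: int
    utr5_len: int
    orf_len: int
    utr3_len: int
    tir3_len: int
    excision_ok: bool = False
    flank5_4mer: str = ""
    flank3_4mer: str = ""

    def __post_init__(self) -> None:
        lens = (self.tir5_len, self.utr5_len, self.orf_len, self.utr3_len, self.tir3_len)
        if any(x < 0 for x in lens):
            raise ValidationError(f"negative segment length in {lens}")
        if sum(lens) != self.element.length():
            raise ValidationError(
                f"segments sum to {sum(lens)} but element length is {self.element.length()}"
            )

    @classmethod
    def from_segment_lengths(
        cls, tir5: int, utr5: int, orf: int, utr3: int, tir3: int, seq_id: str = "ref"
    ) -> "ElementLayout":
        total = tir5 + utr5 + orf + utr3 + tir3
        return cls(Interval(seq_id, 1, total), tir5, utr5, orf, utr3, tir3)

    @property
    def segment_lengths(self) -> tuple[int, int, int, int, int]:
        return (self.tir5_len, self.utr5_len, self.orf_len, self.utr3_len, self.tir3_len)


@dataclass(frozen=True)
class BoundaryCall:
    """Inserted-segment interval supported by homolog presence/absence counts."""

    interval: Interval
    support_with: int
    support_without: int

    @property
    def confident(self) -> bool:
        return self.support_with >= 1 and self.support_without >= 1


def layout_total_length(layout: ElementLayout) -> int:
    """Sum of the five segment lengths (equals the element interval length)."""
    return sum(layout.segment_lengths)


def detect_tirs(
    element_region: str,
    min_len: int = DEFAULT_TIR_MIN_LEN,
    max_len: int = DEFAULT_TIR_MAX_LEN,
    min_identity: float = 1.0,
    seq_id: str = "region",
) -> TirPair | None:
    """Longest terminal inverted repeat of the region, or None.

    Scans prefix lengths from max_len down to min_len and returns the first
    (longest) length L at which identity(prefix, revcomp(suffix)) >=
    min_identity. Windows containing N are excluded: 'identical TIRs' is an
    exact claim that N cannot support.
    """
    region = element_region.upper()
    n = len(region)
    if min_len > max_len:
        raise ValidationError(f"min_len {min_len} > max_len {max_len}")
    top = min(max_len, n // 2)
    for L in range(top, min_len - 1, -1):
        prefix = region[:L]
        suffix = region[n - L :]
        if "N" in prefix or "N" in suffix:
            continue
        rc = revcomp(suffix)
        matches = sum(1 for a, b in zip(prefix, rc) if a == b)
        identity = matches / L
        if identity >= min_identity:
            return TirPair(
                tir5=Interval(seq_id, 1, L),
                tir3=Interval(seq_id, n - L + 1, n),
                identity=identity,
            )
    return None


def check_excision_sites(
    genome: GenomeSequence, element: Interval, tsd: str = DEFAULT_TSD
) -> tuple[bool, str, str]:
    """Boundary 4-mer check: 2 bp of flank + 2 bp of element terminus.

    The 5' 4-mer spans the left boundary (flank|element) and the 3' 4-mer the
    right boundary (element|flank). The call passes when the two 4-mers are
    reverse complements and both flank 2-mers equal the TSD, mirroring the
    'TACA|' / '|TGTA' and 'TA|TA' printed site patterns.
    """
    if element.start < 3 or element.end > genome.length - 2:
        raise InsufficientFlankError(
            f"element {element.start}-{element.end} needs >= 2 bp of flank on each side"
        )
    s = genome.seq
    left2 = s[element.start - 3 : element.start - 1]
    first2 = s[element.start - 1 : element.start + 1]
    last2 = s[element.end - 2 : element.end]
    right2 = s[element.end : element.end + 2]
    flank5 = left2 + first2
    flank3 = last2 + right2
    ok = flank5 == revcomp(flank3) and left2 == tsd and right2 == tsd
    return ok, flank5, flank3


def annotate_layout(
    genome: GenomeSequence,
    element: Interval,
    tir: TirPair | None,
    orf: "Interval",
    tsd: str = DEFAULT_TSD,
) -> ElementLayout:
    """Assemble the five-part layout; UTR lengths fall out by subtraction.

    `orf` is the ORF interval in genome coordinates; it must sit strictly
    between the TIRs. Elements at the sequence edge get excision_ok=False.
    """
    tir5_len = tir.length if tir is not None else 0
    tir3_len = tir5_len
    if not element.contains(orf):
        raise LayoutError("ORF not contained in element")
    utr5_len = orf.start - element.start - tir5_len
    utr3_len = element.end - orf.end - tir3_len
    if utr5_len < 0 or utr3_len < 0:
        raise LayoutError("ORF overlaps a TIR")
    try:
        ok, f5, f3 = check_excision_sites(genome, element, tsd)
    except InsufficientFlankError:
        ok, f5, f3 = False, "", ""
    return ElementLayout(
        element=element,
        tir5_len=tir5_len,
        utr5_len=utr5_len,
        orf_len=orf.length(),
        utr3_len=utr3_len,
        tir3_len=tir3_len,
        excision_ok=ok,
        flank5_4mer=f5,
        flank3_4mer=f3,
    )


def has_internal_tirs(
    element_region: str,
    tir_len: int,
    min_len: int = DEFAULT_TIR_MIN_LEN,
    min_identity: float = 1.0,
) -> bool:
    """Scan the interior (terminal TIRs excluded) for another inverted-repeat
    pair; used to rule out composite-element structure."""
    interior = element_region[tir_len:-tir_len] if tir_len else element_region
    if len(interior) < 2 * min_len:
        return False
    hit = detect_tirs(interior, min_len=min_len, max_len=len(interior) // 2, min_identity=min_identity)
    return hit is not None


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def _deletion_runs(ref_row: str, other_row: str) -> list[tuple[int, int]]:
    """Gap runs in other_row as (start, end) 1-based inclusive on ref coordinates."""
    runs = []
    ref_pos = 0
    run_start = None
    for a, b in zip(ref_row, other_row):
        if a != "-":
            ref_pos += 1
            if b == "-":
                if run_start is None:
                    run_start = ref_pos
            else:
                if run_start is not None:
                    runs.append((run_start, ref_pos - 1))
                    run_start = None
        # insertion columns (a == '-') do not advance ref and cannot open a
        # deletion run on ref coordinates
    if run_start is not None:
        runs.append((run_start, ref_pos))
    return runs


def infer_insertion_interval(
    with_group: Sequence[str],
    without_group: Sequence[str],
    tolerance: int = 2,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    seq_id: str = "with_rep",
) -> BoundaryCall:
    """Locate the segment present in every with-group region and absent from
    every without-group region.

    One with-group representative is globally aligned against each
    without-group region; the longest deletion gap on each alignment must
    agree across the group within +/- tolerance bp, otherwise
    AmbiguousBoundaryError is raised. Coordinates are on the representative.
    """
    if not with_group or not without_group:
        raise ValidationError("both homolog groups must be non-empty")
    rep = with_group[0].upper()
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    candidates = []
    for wo in without_group:
        aln = aligner.align(rep, wo.upper())[0]
        runs = _deletion_runs(aln[0], aln[1])
        if not runs:
            raise AmbiguousBoundaryError(
                "a without-group region shows no deletion relative to the representative"
            )
        candidates.append(max(runs, key=lambda r: r[1] - r[0]))
    ref_start, ref_end = candidates[0]
    for s, e in candidates[1:]:
        if abs(s - ref_start) > tolerance or abs(e - ref_end) > tolerance:
            raise AmbiguousBoundaryError(
                f"without-group regions disagree on the segment: "
                f"{(ref_start, ref_end)} vs {(s, e)} beyond +/-{tolerance} bp"
            )
    seg_len = ref_end - ref_start + 1
    support_with = 0
    for w in with_group:
        if w is rep or w.upper() == rep:
            support_with += 1
            continue
        aln = aligner.align(rep, w.upper())[0]
        runs = _deletion_runs(aln[0], aln[1])
        overlap_gap = any(
            min(e, ref_end) - max(s, ref_start) + 1 > tolerance for s, e in runs
        )
        if not overlap_gap:
            support_with += 1
    return BoundaryCall(
        interval=Interval(seq_id, ref_start, ref_end),
        support_with=support_with,
        support_without=len(without_group),
    )
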