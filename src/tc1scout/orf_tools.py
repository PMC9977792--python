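"""ORF scanning, translation, and frameshift repair by minimal insertion removal.

Repair models the recovery of a coding sequence broken by short insertions:
it searches for the removal set with the fewest segments (each segment is
one putative insertion event), then minimal total length, then leftmost,
whose excision restores one uninterrupted ORF from the first fragment's
start codon to the last fragment's stop codon. The search is an exact
dynamic program over (position, codon phase, partial codon) states, with
deletion jumps bounded by max_insert_len, so desk-scale inputs get provably
optimal answers rather than heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .core_io import Interval, revcomp
from .errors import TranslationError, ValidationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG"})
DEFAULT_MAX_INSERT_LEN = 50


@dataclass(frozen=True)
class OrfCall:
    """A maximal open reading frame; length_nt includes the stop codon,
    the protein does not."""

    interval: Interval
    frame: int
    start_codon: str
    protein: str

    def __post_init__(self) -> None:
        if self.length_nt % 3 != 0:
            raise ValidationError(f"ORF length {self.length_nt} not a multiple of 3")
        if len(self.protein) != self.length_nt // 3 - 1:
            raise ValidationError(
                f"protein length {len(self.protein)} != {self.length_nt}/3 - 1"
            )
        if "*" in self.protein:
            raise ValidationError("protein contains an internal stop")

    @property
    def length_nt(self) -> int:
        return self.interval.length()

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class RepairResult:
    """Insertion segments removed to restore a single ORF.

    removed_segments entries are (position, length, sequence) with position
    1-based in the input region; the segment occupied
    region[position .. position+length-1].
    """

    removed_segments: tuple[tuple[int, int, str], ...]
    repaired_region: str
    repaired_orf: OrfCall

    @property
    def total_removed(self) -> int:
        return sum(length for _, length, _ in self.removed_segments)


def translate(orf_nt: str) -> str:
    """Translate a complete ORF (standard code); input must end in a stop
    codon and contain no internal stop."""
    s = orf_nt.upper()
    if len(s) % 3 != 0:
        raise TranslationError(f"length {len(s)} not a multiple of 3")
    if len(s) < 6:
        raise TranslationError("ORF must contain at least a start and a stop codon")
    if s[-3:] not in STOP_CODONS:
        raise TranslationError(f"ORF does not end in a stop codon ({s[-3:]})")
    protein = str(Seq(s).translate(table=1))
    if "*" in protein[:-1]:
        raise TranslationError("internal stop codon")
    return protein[:-1]


def _scan_strand(
    seq: str, min_aa: int, start_codons: frozenset[str], strand: str, seq_id: str
) -> list[OrfCall]:
    n = len(seq)
    calls = []
    for frame in range(3):
        region_start = frame  # first candidate position after the previous stop
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                # leftmost start codon in [region_start, i) gives the maximal ORF
                j = region_start
                while j < i:
                    if seq[j : j + 3] in start_codons:
                        aa_len = (i + 3 - j) // 3 - 1
                        if aa_len >= min_aa:
                            nt = seq[j : i + 3]
                            if strand == "+":
                                iv = Interval(seq_id, j + 1, i + 3, "+")
                            else:
                                iv = Interval(seq_id, n - (i + 3) + 1, n - j, "-")
                            calls.append(
                                OrfCall(
                                    interval=iv,
                                    frame=frame,
                                    start_codon=seq[j : j + 3],
                                    protein=translate(nt),
                                )
                            )
                        break
                    j += 3
                region_start = i + 3
            i += 3
    return calls


def find_orfs(
    seq: str,
    min_aa: int = 50,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    seq_id: str = "seq",
) -> list[OrfCall]:
    """All maximal ORFs on both strands, longest first (ties by coordinate).

    An ORF runs from the leftmost in-frame start codon after the previous
    stop to the next stop codon (stop included in the nucleotide length).
    """
    if min_aa < 1:
        raise ValidationError("min_aa must be >= 1")
    starts = frozenset(c.upper() for c in start_codons)
    s = seq.upper()
    calls = _scan_strand(s, min_aa, starts, "+", seq_id)
    calls += _scan_strand(revcomp(s), min_aa, starts, "-", seq_id)
    calls.sort(key=lambda c: (-c.length_nt, c.interval.start, c.interval.strand))
    return calls


# ---------------------------------------------------------------------------
# frameshift repair
# ---------------------------------------------------------------------------

_KEEP_FIRST = 3  # start codon is never deleted
_KEEP_LAST = 3  # final stop codon is never deleted


def _dp_repair(sub: str, max_insert_len: int) -> tuple[tuple[int, int], ...] | None:
    """Minimal removal set turning sub into one clean ORF (start..stop).

    Returns ((offset, length), ...) with 0-based offsets into sub, or None.
    Cost order: fewest segments, then smallest total removed, then leftmost
    (position, length) tuple lexicographically. Segment count leads because
    each removed segment models one insertion event; ordering by raw length
    first would let the search keep most of a long insertion by excising
    only its stop codons.
    """
    n = len(sub)
    if n < 6 or sub[-3:] not in STOP_CODONS:
        return None
    # state: (phase, partial_codon) -> (cost_tuple, done_flag)
    # done_flag marks that the final stop codon has been completed.
    Infinity = None
    states: list[dict[tuple[int, str, bool], tuple] | None] = [None] * (n + 1)
    states[0] = {(0, "", False): (0, 0, ())}

    def offer(bucket: dict, key: tuple, cost: tuple) -> None:
        old = bucket.get(key)
        if old is None or cost < old:
            bucket[key] = cost

    for i in range(n):
        bucket = states[i]
        if not bucket:
            continue
        base = sub[i]
        for (phase, partial, done), cost in bucket.items():
            if done:
                continue  # nothing may follow the final stop
            # keep base
            if phase == 2:
                codon = partial + base
                if codon in STOP_CODONS:
                    if i == n - 1:  # the terminal stop
                        if states[i + 1] is None:
                            states[i + 1] = {}
                        offer(states[i + 1], (0, "", True), cost)
                    # premature stop: kept path dies here
                else:
                    if states[i + 1] is None:
                        states[i + 1] = {}
                    offer(states[i + 1], (0, "", False), cost)
            else:
                if states[i + 1] is None:
                    states[i + 1] = {}
                offer(states[i + 1], (phase + 1, partial + base, False), cost)
            # start a deletion (never inside the fixed start/stop codons)
            if i >= _KEEP_FIRST:
                nseg, total, segs = cost
                max_l = min(max_insert_len, n - _KEEP_LAST - i)
                for L in range(1, max_l + 1):
                    j = i + L
                    if states[j] is None:
                        states[j] = {}
                    offer(
                        states[j],
                        (phase, partial, False),
                        (nseg + 1, total + L, segs + ((i, L),)),
                    )
    final = states[n]
    if not final:
        return None
    best = final.get((0, "", True))
    if best is None:
        return None
    return best[2]


def _merge_segments(segs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for off, length in sorted(segs):
        if merged and merged[-1][0] + merged[-1][1] == off:
            merged[-1] = (merged[-1][0], merged[-1][1] + length)
        else:
            merged.append((off, length))
    return merged


def _protein_identity(a: str, b: str) -> float:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    same = sum(1 for x, y in zip(aln[0], aln[1]) if x == y and x != "-")
    return same / max(len(a), len(b))


def repair_frameshifts(
    region: str,
    max_insert_len: int = DEFAULT_MAX_INSERT_LEN,
    reference_protein: str | None = None,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    min_identity: float = 0.8,
    max_anchor_tries: int = 6,
) -> RepairResult | None:
    """Repair a frameshift-broken coding region by removing short insertions.

    Anchors on candidate start codons (leftmost first) and stop codons
    (rightmost first) and runs the exact DP between them; the first anchored
    span admitting a repair wins, so an already-intact ORF yields an empty
    removal set. Returns None (repair-failure signal, not an exception) when
    no removal within max_insert_len restores an ORF, or when the restored
    protein falls below min_identity against reference_protein.
    """
    if max_insert_len < 1:
        raise ValidationError("max_insert_len must be >= 1")
    r = region.upper()
    starts = frozenset(c.upper() for c in start_codons)
    start_pos = [i for i in range(len(r) - 5) if r[i : i + 3] in starts]
    stop_end = [i + 3 for i in range(len(r) - 2) if r[i : i + 3] in STOP_CODONS]
    for s in start_pos[:max_anchor_tries]:
        for e in reversed(stop_end):
            if e - s < 6:
                continue
            segs = _dp_repair(r[s:e], max_insert_len)
            if segs is None:
                continue
            merged = _merge_segments([(s + off, length) for off, length in segs])
            removed = tuple(
                (off + 1, length, r[off : off + length]) for off, length in merged
            )
            repaired = []
            pos = 0
            for off, length in merged:
                repaired.append(r[pos:off])
                pos = off + length
            repaired.append(r[pos:])
            repaired_region = "".join(repaired)
            orf_nt = repaired_region[s : e - sum(L for _, L in merged)]
            protein = translate(orf_nt)
            if reference_protein is not None and _protein_identity(protein, reference_protein) < min_identity:
                continue
            orf = OrfCall(
                interval=Interval("repaired", s + 1, s + len(orf_nt), "+"),
                frame=s % 3,
                start_codon=r[s : s + 3],
                protein=protein,
            )
            return RepairResult(
                removed_segments=removed,
                repaired_region=repaired_region,
                repaired_orf=orf,
            )
    return None
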