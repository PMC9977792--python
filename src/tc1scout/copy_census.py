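"""Genome-wide placement of a reference element.

Seed-and-extend census: exact k-mer seeds on both strands are clustered into
loci, each locus is verified by local alignment against the reference, and a
hit is a full-length copy when its reference coverage is strictly greater
than 0.90 (the "more than 90%" counting rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .core_io import GenomeSequence, Interval, revcomp
from .errors import ValidationError

FULL_LENGTH_THRESHOLD = 0.90  # strict: coverage must exceed this
DEFAULT_MIN_IDENTITY = 0.8  # family norm allows ~20% divergence at the DNA level
DEFAULT_SEED_K = 14
CHAIN_GAP_FRACTION = 0.20
GAP_EDGE_EXCLUSION = 1  # SNP columns within this many bp of a gap are ignored


@dataclass(frozen=True)
class CopyHit:
    interval: Interval
    coverage: float
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0 or not 0.0 <= self.identity <= 1.0:
            raise ValidationError("coverage/identity must lie in [0,1]")

    @property
    def full_length(self) -> bool:
        return self.coverage > FULL_LENGTH_THRESHOLD


@dataclass(frozen=True)
class CopyDiff:
    """Divergence between two copies from one global alignment.

    Indel positions are 1-based on copy A; type 'del' means copy B lacks the
    bases, 'ins' means copy B carries extra bases.
    """

    n_snps: int
    indels: tuple[tuple[int, int, str], ...]
    aa_consequence: str | None = None


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _global_aligner() -> Align.PairwiseAligner:
    a = _local_aligner()
    a.mode = "global"
    return a


def _seed_positions(genome: str, ref: str, k: int) -> list[tuple[int, str]]:
    """(genome position, strand) of exact k-mer matches to ref or its revcomp."""
    fwd = {ref[i : i + k] for i in range(0, len(ref) - k + 1)}
    rc_ref = revcomp(ref)
    rev = {rc_ref[i : i + k] for i in range(0, len(rc_ref) - k + 1)}
    hits = []
    for i in range(0, len(genome) - k + 1):
        kmer = genome[i : i + k]
        if kmer in fwd:
            hits.append((i, "+"))
        elif kmer in rev:
            hits.append((i, "-"))
    return hits


def _cluster(hits: list[tuple[int, str]], ref_len: int, k: int) -> list[tuple[int, int, str]]:
    """Chain seeds on the same strand within the gap tolerance into loci."""
    max_gap = int(CHAIN_GAP_FRACTION * ref_len) + k
    loci = []
    for strand in "+-":
        pos = sorted(p for p, s in hits if s == strand)
        if not pos:
            continue
        start = prev = pos[0]
        for p in pos[1:]:
            if p - prev > max_gap:
                loci.append((start, prev + k, strand))
                start = p
            prev = p
        loci.append((start, prev + k, strand))
    loci.sort()
    return loci


def find_copies(
    genome: GenomeSequence,
    reference_element: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = 0.10,
    seed_k: int = DEFAULT_SEED_K,
) -> list[CopyHit]:
    """Seed-and-extend hits of the reference across the genome, both strands.

    coverage = aligned reference span / reference length; identity is
    computed over aligned columns. Hits below min_identity or min_coverage
    are dropped; overlapping hits keep the higher-coverage one. Sorted by
    coordinate.
    """
    ref = reference_element.upper()
    if len(ref) < 50:
        raise ValidationError(f"reference must be >= 50 bp, got {len(ref)}")
    hits = _seed_positions(genome.seq, ref, seed_k)
    loci = _cluster(hits, len(ref), seed_k)
    aligner = _local_aligner()
    margin = int(0.15 * len(ref)) + 50
    out: list[CopyHit] = []
    for lo, hi, strand in loci:
        w_start = max(0, lo - margin)
        w_end = min(genome.length, hi + margin)
        window = genome.seq[w_start:w_end]
        target = ref if strand == "+" else revcomp(ref)
        aln = aligner.align(window, target)[0]
        blocks_g, blocks_r = aln.aligned
        if len(blocks_r) == 0:
            continue
        ref_span = int(blocks_r[-1][1] - blocks_r[0][0])
        coverage = ref_span / len(ref)
        row_g, row_r = aln[0], aln[1]
        cols = sum(1 for a, b in zip(row_g, row_r) if a != "-" and b != "-")
        matches = sum(1 for a, b in zip(row_g, row_r) if a == b and a != "-")
        identity = matches / cols if cols else 0.0
        if coverage < min_coverage or identity < min_identity:
            continue
        g_start = w_start + int(blocks_g[0][0]) + 1
        g_end = w_start + int(blocks_g[-1][1])
        out.append(
            CopyHit(Interval(genome.id, g_start, g_end, strand), coverage, identity)
        )
    out.sort(key=lambda h: (h.interval.start, -h.coverage))
    deduped: list[CopyHit] = []
    for h in out:
        if deduped and deduped[-1].interval.overlaps(h.interval):
            if h.coverage > deduped[-1].coverage:
                deduped[-1] = h
            continue
        deduped.append(h)
    return deduped


def find_solo_tirs(
    genome: GenomeSequence,
    tir_seq: str,
    min_identity: float = 0.9,
    exclude: list[Interval] | None = None,
) -> list[Interval]:
    """Strand-symmetric windowed matches to the TIR outside element copies.

    Every window whose identity to the TIR (or its reverse complement)
    reaches min_identity is a hit; overlapping windows are merged to the
    best-scoring one, and hits inside `exclude` intervals are dropped.
    """
    tir = tir_seq.upper()
    L = len(tir)
    if L < 10:
        raise ValidationError(f"TIR must be >= 10 bp, got {L}")
    g = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    n = genome.length - L + 1
    if n <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(g, L)
    scores = {}
    for strand, pattern in (("+", tir), ("-", revcomp(tir))):
        p = np.frombuffer(pattern.encode(), dtype=np.uint8)
        ident = (windows == p).sum(axis=1) / L
        for i in np.nonzero(ident >= min_identity)[0]:
            key = int(i)
            cand = (float(ident[key]), strand)
            if key not in scores or cand > scores[key]:
                scores[key] = cand
    hits: list[Interval] = []
    for i in sorted(scores):
        iv = Interval(genome.id, i + 1, i + L, scores[i][1])
        if hits and hits[-1].overlaps(iv):
            continue
        hits.append(iv)
    if exclude:
        hits = [h for h in hits if not any(e.overlaps(h) for e in exclude)]
    return hits


def _indels_and_snps(row_a: str, row_b: str) -> tuple[int, list[tuple[int, int, str]]]:
    gap_cols = [i for i, (a, b) in enumerate(zip(row_a, row_b)) if a == "-" or b == "-"]
    near_gap = set()
    for i in gap_cols:
        near_gap.update(range(i - GAP_EDGE_EXCLUSION, i + GAP_EDGE_EXCLUSION + 1))
    n_snps = 0
    indels: list[tuple[int, int, str]] = []
    a_pos = 0
    run_type = None
    run_len = 0
    run_pos = 0
    for i, (a, b) in enumerate(zip(row_a, row_b)):
        if a != "-":
            a_pos += 1
        kind = "del" if b == "-" else ("ins" if a == "-" else None)
        if kind != run_type:
            if run_type is not None:
                indels.append((run_pos, run_len, run_type))
            run_type, run_len = kind, 0
            run_pos = a_pos if kind == "del" else a_pos + (0 if a == "-" else 1)
        if kind is not None:
            run_len += 1
        elif a != b and i not in near_gap:
            n_snps += 1
    if run_type is not None:
        indels.append((run_pos, run_len, run_type))
    return n_snps, indels


def compare_copies(
    copy_a: str,
    copy_b: str,
    orf_interval: Interval | None = None,
) -> CopyDiff:
    """SNP/indel report from one global alignment of the two copies.

    A k-bp gap run counts as one indel of length k; SNP counting skips
    columns adjacent (within 1 bp) to gaps to avoid edge-wander artifacts.
    When orf_interval (on copy A) is given and copy B carries an in-frame
    deletion inside it, the deleted residues are named.
    """
    if not copy_a or not copy_b:
        raise ValidationError("both copies must be non-empty")
    aln = _global_aligner().align(copy_a.upper(), copy_b.upper())[0]
    n_snps, indels = _indels_and_snps(aln[0], aln[1])
    aa = None
    if orf_interval is not None:
        aa = _aa_consequence(copy_a.upper(), aln, orf_interval, indels)
    return CopyDiff(n_snps=n_snps, indels=tuple(indels), aa_consequence=aa)


def _aa_consequence(
    copy_a: str, aln, orf_interval: Interval, indels: list[tuple[int, int, str]]
) -> str | None:
    in_orf = [
        (p, L, t)
        for p, L, t in indels
        if t == "del" and orf_interval.start <= p <= orf_interval.end and L % 3 == 0
    ]
    if len(in_orf) != 1 or any(t == "ins" for _, _, t in indels):
        return None
    try:
        prot_a = str(Seq(copy_a[orf_interval.start - 1 : orf_interval.end]).translate())
        # project the ORF interval onto copy B through the alignment
        row_a, row_b = aln[0], aln[1]
        a_pos = 0
        b_chars = []
        for a, b in zip(row_a, row_b):
            if a != "-":
                a_pos += 1
                if orf_interval.start <= a_pos <= orf_interval.end and b != "-":
                    b_chars.append(b)
        orf_b = "".join(b_chars)
        if len(orf_b) % 3 != 0:
            return None
        prot_b = str(Seq(orf_b).translate())
    except Exception:
        return None
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    p = aligner.align(prot_a, prot_b)[0]
    lost = [a for a, b in zip(p[0], p[1]) if b == "-" and a != "-"]
    if not lost:
        return None
    return f"deletion of {len(lost)} aa ({''.join(lost)})"
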