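"""End-to-end discovery workflow: ORF scan -> triad filter -> TIR/excision
validation -> layout -> reports.

A reported element must satisfy all three evidence predicates: a terminal
inverted repeat pair, excision-site/TSD symmetry on both flanks, and a
triad-bearing ORF between the TIRs. Candidates that carry a TIR pair and a
transposase-like ORF but fail the excision check land in the failed-evidence
section instead of being dropped silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .core_io import (
    ElementAnnotation,
    GenomeSequence,
    Interval,
    read_fasta,
    write_gff,
)
from .dde_motif import DEFAULT_SPACING_SET, find_dde_triads
from .element_structure import (
    ElementLayout,
    annotate_layout,
    check_excision_sites,
    detect_tirs,
    has_internal_tirs,
)
from .errors import InsufficientFlankError, ValidationError
from .orf_tools import OrfCall, find_orfs

SO_TERMS = (
    "terminal_inverted_repeat",
    "five_prime_UTR",
    "CDS",
    "three_prime_UTR",
    "terminal_inverted_repeat",
)


@dataclass(frozen=True)
class PipelineConfig:
    start_codons: tuple[str, ...] = ("ATG",)
    min_orf_aa: int = 100
    spacing_set: tuple[int, ...] = tuple(sorted(DEFAULT_SPACING_SET))
    tir_min_len: int = 10
    tir_max_len: int = 250
    tir_min_identity: float = 1.0
    tsd: str = "TA"
    census_min_identity: float = 0.8
    max_flank: int = 2500
    max_candidate_orfs: int = 20
    rng_seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("start_codons", "spacing_set"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ElementReport:
    seq_id: str
    layout: ElementLayout
    orf: OrfCall
    tir_len: int
    tir_identity: float
    triad_class: str
    triad_positions: tuple[int, int, int]
    internal_tirs: bool

    def tsv_row(self) -> str:
        iv = self.layout.element
        return "\t".join(
            str(x)
            for x in [
                self.seq_id, iv.start, iv.end, iv.length(), self.tir_len,
                f"{self.tir_identity:.3f}", self.layout.utr5_len, self.layout.orf_len,
                self.layout.utr3_len, int(self.layout.excision_ok),
                self.layout.flank5_4mer, self.layout.flank3_4mer,
                self.triad_class,
                "/".join(map(str, self.triad_positions)),
                int(self.internal_tirs),
            ]
        )


@dataclass
class FailedCandidate:
    seq_id: str
    element: Interval
    reason: str

    def tsv_row(self) -> str:
        return "\t".join(
            [self.seq_id, str(self.element.start), str(self.element.end), self.reason]
        )


REPORT_HEADER = (
    "seq_id\tstart\tend\tlength\ttir_len\ttir_identity\tutr5_len\torf_len\t"
    "utr3_len\texcision_ok\tflank5_4mer\tflank3_4mer\ttriad_class\t"
    "triad_positions\tinternal_tirs"
)


def _candidate_bounds(
    genome: GenomeSequence, orf: OrfCall, config: PipelineConfig
) -> list[tuple[int, int]]:
    """Candidate (element start, element end) pairs, 1-based inclusive.

    Seeds on the first tir_min_len bases after a TSD in the left flank and
    looks for the seed's reverse complement ahead of a TSD in the right
    flank; a TSD-free fallback scan is used only when the anchored scan
    yields nothing (it feeds the failed-evidence report).
    """
    s = genome.seq
    k = config.tir_min_len
    tsd = config.tsd
    left_lo = max(0, orf.interval.start - 1 - config.max_flank)
    left_hi = orf.interval.start - 1  # 0-based exclusive
    right_lo = orf.interval.end  # 0-based inclusive
    right_hi = min(genome.length, orf.interval.end + config.max_flank)
    right_window = s[right_lo:right_hi]

    def right_matches(seed_rc: str, require_tsd: bool) -> list[int]:
        ends = []
        p = right_window.find(seed_rc)
        while p != -1:
            end0 = right_lo + p + k  # 0-based exclusive element end
            if not require_tsd or s[end0 : end0 + 2] == tsd:
                ends.append(end0)
            p = right_window.find(seed_rc, p + 1)
        return ends

    pairs = []
    for ls in range(left_lo, left_hi - k + 1):
        if s[ls - 2 : ls] != tsd or ls < 2:
            continue
        seed = s[ls : ls + k]
        if "N" in seed:
            continue
        from .core_io import revcomp

        for end0 in right_matches(revcomp(seed), require_tsd=True):
            pairs.append((ls + 1, end0))
    if pairs:
        return pairs
    # fallback: no TSD anchoring (candidates will fail the excision predicate)
    from .core_io import revcomp

    for ls in range(left_lo, left_hi - k + 1):
        seed = s[ls : ls + k]
        if "N" in seed:
            continue
        for end0 in right_matches(revcomp(seed), require_tsd=False):
            pairs.append((ls + 1, end0))
    return pairs


def discover_elements(
    genome: GenomeSequence, config: PipelineConfig
) -> tuple[list[ElementReport], list[FailedCandidate]]:
    """Run the three-point evidence scan on one sequence."""
    reports: list[ElementReport] = []
    failed: list[FailedCandidate] = []
    seen: set[tuple[int, int]] = set()
    orfs = find_orfs(
        genome.seq, min_aa=config.min_orf_aa, start_codons=config.start_codons, seq_id=genome.id
    )
    for orf in orfs[: config.max_candidate_orfs]:
        triads = find_dde_triads(orf.protein, spacing_set=set(config.spacing_set))
        if not triads:
            continue
        triad = triads[0]
        best = None
        best_fail = None
        for e_start, e_end in _candidate_bounds(genome, orf, config):
            key = (e_start, e_end)
            if key in seen:
                continue
            region = genome.seq[e_start - 1 : e_end]
            tir = detect_tirs(
                region,
                min_len=config.tir_min_len,
                max_len=config.tir_max_len,
                min_identity=config.tir_min_identity,
                seq_id=genome.id,
            )
            if tir is None:
                continue
            element = Interval(genome.id, e_start, e_end)
            try:
                ok, _, _ = check_excision_sites(genome, element, config.tsd)
            except InsufficientFlankError:
                ok = False
            if ok:
                cand = (tir.length, element.length(), element, tir)
                if best is None or cand[:2] > best[:2]:
                    best = cand
            else:
                cand = (tir.length, element.length(), element, tir)
                if best_fail is None or cand[:2] > best_fail[:2]:
                    best_fail = cand
        if best is not None:
            _, _, element, tir = best
            seen.add((element.start, element.end))
            layout = annotate_layout(genome, element, tir, orf.interval, config.tsd)
            region = genome.seq[element.start - 1 : element.end]
            reports.append(
                ElementReport(
                    seq_id=genome.id,
                    layout=layout,
                    orf=orf,
                    tir_len=tir.length,
                    tir_identity=tir.identity,
                    triad_class=triad.spacing_class,
                    triad_positions=(triad.d1_pos, triad.d2_pos, triad.last_pos),
                    internal_tirs=has_internal_tirs(region, tir.length, min_len=config.tir_min_len),
                )
            )
        elif best_fail is not None:
            _, _, element, _ = best_fail
            seen.add((element.start, element.end))
            failed.append(
                FailedCandidate(genome.id, element, "excision-site/TSD check failed")
            )
    # overlapping calls describe the same locus (e.g. a TA inside a TIR
    # yields a trimmed sub-element that also satisfies all three predicates);
    # keep the call with the longest TIR, then the longest element
    reports.sort(key=lambda r: (-r.tir_len, -r.layout.element.length()))
    deduped: list[ElementReport] = []
    for rep in reports:
        if any(rep.layout.element.overlaps(d.layout.element) for d in deduped):
            continue
        deduped.append(rep)
    deduped.sort(key=lambda r: (r.seq_id, r.layout.element.start))
    failed = [
        f
        for f in failed
        if not any(f.element.overlaps(d.layout.element) for d in deduped)
    ]
    failed.sort(key=lambda f: (-f.element.length(), f.element.start))
    failed_dedup: list[FailedCandidate] = []
    for f in failed:
        if any(f.element.overlaps(d.element) for d in failed_dedup):
            continue
        failed_dedup.append(f)
    failed_dedup.sort(key=lambda f: (f.seq_id, f.element.start))
    return deduped, failed_dedup


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_discover(genome_path: str | Path, config: PipelineConfig, out_dir: str | Path) -> dict:
    """Discover elements in every genome record and write GFF3/TSV/log/JSON.

    Outputs are deterministic for identical (inputs, config, seed).
    """
    genome_path = Path(genome_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = read_fasta(genome_path)
    all_reports: list[ElementReport] = []
    all_failed: list[FailedCandidate] = []
    for g in genomes:
        reports, failed = discover_elements(g, config)
        all_reports.extend(reports)
        all_failed.extend(failed)

    annotations = []
    for n, rep in enumerate(all_reports, start=1):
        iv = rep.layout.element
        segs = []
        pos = iv.start
        for term, length in zip(SO_TERMS, rep.layout.segment_lengths):
            if length > 0:
                segs.append((term, Interval(iv.seq_id, pos, pos + length - 1)))
            pos += length
        annotations.append(
            ElementAnnotation(
                element=iv,
                segments=segs,
                segment_lengths=list(rep.layout.segment_lengths),
                attributes={"ID": f"te{n:04d}", "triad_class": rep.triad_class},
            )
        )
    seq_lengths = {g.id: g.length for g in genomes}
    write_gff(annotations, out / "elements.gff3", seq_lengths=seq_lengths)

    tsv = [REPORT_HEADER] + [r.tsv_row() for r in all_reports]
    (out / "elements.tsv").write_text("\n".join(tsv) + "\n")
    ftsv = ["seq_id\tstart\tend\treason"] + [f.tsv_row() for f in all_failed]
    (out / "failed_evidence.tsv").write_text("\n".join(ftsv) + "\n")

    summary = {
        "tool": "tc1scout",
        "version": __version__,
        "genome": str(genome_path),
        "genome_sha256": _sha256(genome_path),
        "config": config.as_dict(),
        "n_elements": len(all_reports),
        "n_failed_candidates": len(all_failed),
        "elements": [
            {
                "seq_id": r.seq_id,
                "start": r.layout.element.start,
                "end": r.layout.element.end,
                "tir_len": r.tir_len,
                "triad_class": r.triad_class,
                "excision_ok": r.layout.excision_ok,
            }
            for r in all_reports
        ],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log_lines = [
        f"tc1scout {__version__}",
        f"input {genome_path} sha256 {summary['genome_sha256']}",
    ]
    log_lines += [f"config {k} = {v}" for k, v in sorted(config.as_dict().items())]
    log_lines.append(f"elements reported: {len(all_reports)}")
    log_lines.append(f"failed-evidence candidates: {len(all_failed)}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
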