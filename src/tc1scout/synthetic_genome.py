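"""Synthetic genomes with planted transposable elements and ground truth.

Every downstream stage is testable offline: the generator plants full-length
copies (with TA target-site duplication), diverged copies (substitutions +
short indels), truncated copies, solo TIRs, and frameshift-breaking
insertions, and returns truth records that downstream detectors must
recover.

Construction guarantees:
  * 5' and 3' TIRs are exact reverse complements.
  * The planted ORF has a valid start/stop, no internal stop, and carries
    the requested D..D..D/E triad; other positions avoid D/E so the planted
    triad is the unique candidate.
  * Full insertions duplicate the TA target site: flank pattern TA-element-TA.
  * Substitutions never touch the first/last 4 bp of either TIR (excision
    evidence stays intact) and never create an in-frame stop; edits are
    spaced >= 8 bp apart so alignment-based counting is unambiguous.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .core_io import GenomeSequence, Interval, revcomp
from .dde_motif import DdeTriad
from .element_structure import ElementLayout
from .errors import PlacementError, SpecError
from .orf_tools import STOP_CODONS, translate

_AA_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _AA_CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _AA_CODONS.setdefault(aa, []).append(codon)
        for aa in _AA_CODONS:
            _AA_CODONS[aa].sort()
    return _AA_CODONS


# residues used for random ORF body positions: D and E excluded so a planted
# triad has no decoys; M allowed (it is not evidence for anything).
_BODY_RESIDUES = "ACFGHIKLMNPQRSTVWY"
MIN_EDIT_SPACING = 8
TIR_PROTECT = 4  # bp at each TIR end never mutated


@dataclass(frozen=True)
class TriadSpec:
    """Planted catalytic triad: 1-based residue offsets into the protein."""

    d1_offset_aa: int
    d2_offset_aa: int
    last_residue: str = "E"
    d2_to_last_spacing_aa: int = 34

    @property
    def last_offset_aa(self) -> int:
        return self.d2_offset_aa + self.d2_to_last_spacing_aa + 1


@dataclass(frozen=True)
class ElementSpec:
    tir_len: int
    utr5_len: int
    orf_len: int
    utr3_len: int
    triad: TriadSpec | None = None
    tsd: str = "TA"

    def __post_init__(self) -> None:
        if self.orf_len % 3 != 0 or self.orf_len < 6:
            raise SpecError(f"orf_len must be a multiple of 3 and >= 6, got {self.orf_len}")
        if min(self.tir_len, self.utr5_len, self.utr3_len) < 0:
            raise SpecError("segment lengths must be non-negative")
        if self.triad is not None:
            n_aa = self.orf_len // 3 - 1
            t = self.triad
            if not (1 < t.d1_offset_aa < t.d2_offset_aa < t.last_offset_aa <= n_aa):
                raise SpecError(
                    f"triad offsets {t.d1_offset_aa}/{t.d2_offset_aa}/{t.last_offset_aa} "
                    f"collide with start/stop or exceed protein length {n_aa}"
                )
            if t.last_residue not in {"D", "E"}:
                raise SpecError("triad last residue must be D or E")
        if len(self.tsd) != 2:
            raise SpecError("tsd must be a dinucleotide")

    @property
    def total_length(self) -> int:
        return 2 * self.tir_len + self.utr5_len + self.orf_len + self.utr3_len


@dataclass(frozen=True)
class PlantPlan:
    n_full: int = 1
    n_partial: tuple[float, ...] = ()
    n_solo_tir: int = 0
    copy_divergence: tuple[int, tuple[int, ...]] | None = None
    frameshift_insertions: tuple[tuple[int, str], ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 < f < 1.0 for f in self.n_partial):
            raise SpecError("partial coverage fractions must lie in (0,1)")
        if self.n_full < 0 or self.n_solo_tir < 0:
            raise SpecError("counts must be non-negative")


@dataclass
class TruthRecord:
    """Ground truth for one planted feature, in final genome coordinates."""

    kind: str  # full | partial | solo_tir
    interval: Interval
    copy_index: int
    inserted_seq: str
    layout: ElementLayout | None = None
    n_substitutions: int = 0
    indel_lengths: tuple[int, ...] = ()
    frameshifted: bool = False
    retained_fraction: float = 1.0


def random_background(length: int, gc: float, rng_seed: int, seq_id: str = "synthetic") -> GenomeSequence:
    """i.i.d. background with P(G)+P(C)=gc; same seed, same sequence."""
    if length <= 0:
        raise SpecError(f"length must be positive, got {length}")
    if not 0.0 < gc < 1.0:
        raise SpecError(f"gc must lie strictly in (0,1), got {gc}")
    rng = random.Random(rng_seed)
    w = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    seq = "".join(rng.choices("GCAT", weights=w, k=length))
    return GenomeSequence(id=seq_id, seq=seq)


def _random_protein(rng: random.Random, n_aa: int, triad: TriadSpec | None) -> str:
    aas = ["M"] + [rng.choice(_BODY_RESIDUES) for _ in range(n_aa - 1)]
    if triad is not None:
        aas[triad.d1_offset_aa - 1] = "D"
        aas[triad.d2_offset_aa - 1] = "D"
        aas[triad.last_offset_aa - 1] = triad.last_residue
    return "".join(aas)


def _encode(rng: random.Random, protein: str) -> str:
    table = _codon_table()
    codons = ["ATG"]
    for aa in protein[1:]:
        codons.append(rng.choice(table[aa]))
    codons.append(rng.choice(sorted(STOP_CODONS)))
    return "".join(codons)


def build_element(spec: ElementSpec, rng_seed: int) -> tuple[str, ElementLayout, DdeTriad | None]:
    """One reference element: TIR5 + UTR5 + ORF + UTR3 + TIR3 (=revcomp TIR5).

    The returned layout is in element-local coordinates (excision fields are
    filled at planting time); the triad is the construction truth.
    """
    rng = random.Random(rng_seed)
    n_aa = spec.orf_len // 3 - 1
    protein = _random_protein(rng, n_aa, spec.triad)
    orf = _encode(rng, protein)
    assert len(orf) == spec.orf_len and translate(orf) == protein
    tir5 = "".join(rng.choice("ACGT") for _ in range(spec.tir_len))
    utr5 = "".join(rng.choice("ACGT") for _ in range(spec.utr5_len))
    utr3 = "".join(rng.choice("ACGT") for _ in range(spec.utr3_len))
    if spec.tir_len and spec.utr5_len and spec.utr3_len:
        # break inverted symmetry one base beyond the TIRs so the exact TIR
        # length is recovered, not overcalled
        while revcomp(utr3[-1]) == utr5[0]:
            utr3 = utr3[:-1] + rng.choice("ACGT")
    element = tir5 + utr5 + orf + utr3 + revcomp(tir5)
    layout = ElementLayout(
        element=Interval("element", 1, spec.total_length),
        tir5_len=spec.tir_len,
        utr5_len=spec.utr5_len,
        orf_len=spec.orf_len,
        utr3_len=spec.utr3_len,
        tir3_len=spec.tir_len,
    )
    triad = None
    if spec.triad is not None:
        t = spec.triad
        triad = DdeTriad(t.d1_offset_aa, t.d2_offset_aa, t.last_offset_aa, t.last_residue)
    return element, layout, triad


def _protected_positions(spec: ElementSpec) -> set[int]:
    """0-based element positions no edit may touch."""
    total = spec.total_length
    protect: set[int] = set()
    if spec.tir_len:
        protect.update(range(0, TIR_PROTECT))
        protect.update(range(spec.tir_len - TIR_PROTECT, spec.tir_len))
        protect.update(range(total - spec.tir_len, total - spec.tir_len + TIR_PROTECT))
        protect.update(range(total - TIR_PROTECT, total))
    orf_start = spec.tir_len + spec.utr5_len
    protect.update(range(orf_start, orf_start + 3))  # start codon
    protect.update(range(orf_start + spec.orf_len - 3, orf_start + spec.orf_len))  # stop
    return protect


def _pick_spaced(rng: random.Random, candidates: list[int], k: int, taken: list[int]) -> list[int]:
    picked: list[int] = []
    pool = candidates[:]
    rng.shuffle(pool)
    for p in pool:
        if len(picked) == k:
            break
        if all(abs(p - q) >= MIN_EDIT_SPACING for q in picked + taken):
            picked.append(p)
    if len(picked) < k:
        raise PlacementError(f"could not place {k} spaced edits (got {len(picked)})")
    return sorted(picked)


def diverge_copy(
    element: str, spec: ElementSpec, n_substitutions: int, indel_lengths: tuple[int, ...], rng: random.Random
) -> str:
    """Apply substitutions + deletions to a copy without breaking its ORF.

    Deletions with length % 3 == 0 are placed on ORF codon boundaries (so the
    protein loses whole residues); other lengths go into the 3' UTR (5' UTR
    as fallback) to keep the reading frame intact.
    """
    protect = _protected_positions(spec)
    orf_start = spec.tir_len + spec.utr5_len
    orf_end = orf_start + spec.orf_len  # exclusive
    taken: list[int] = []
    seq = list(element)

    # deletions first (recorded on original coordinates, applied at the end)
    deletions: list[tuple[int, int]] = []
    for L in indel_lengths:
        if L % 3 == 0 and spec.orf_len >= L + 12:
            cands = [
                p
                for p in range(orf_start + 3, orf_end - 3 - L, 3)
                if not any(q in protect for q in range(p, p + L))
            ]
        else:
            zones = []
            utr3_start = orf_end
            if spec.utr3_len > L + 2:
                zones.append((utr3_start, utr3_start + spec.utr3_len - L))
            if spec.utr5_len > L + 2:
                zones.append((spec.tir_len, spec.tir_len + spec.utr5_len - L))
            cands = [p for s, e in zones for p in range(s, e) if not any(q in protect for q in range(p, p + L))]
        placed = _pick_spaced(rng, cands, 1, taken)[0]
        deletions.append((placed, L))
        taken.extend(range(placed - MIN_EDIT_SPACING, placed + L + MIN_EDIT_SPACING))

    sub_cands = [p for p in range(len(element)) if p not in protect]
    subs = _pick_spaced(rng, sub_cands, n_substitutions, taken)
    for p in subs:
        old = seq[p]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for new in choices:
            seq[p] = new
            if orf_start <= p < orf_end:
                cstart = orf_start + ((p - orf_start) // 3) * 3
                if "".join(seq[cstart : cstart + 3]) in STOP_CODONS:
                    seq[p] = old
                    continue
            break
        else:
            seq[p] = old  # could not substitute safely; skip silently
    out = "".join(seq)
    for p, L in sorted(deletions, reverse=True):
        out = out[:p] + out[p + L :]
    return out


#: stop codons at offsets 0 (TAG), 4 (TAA) and 8 (TGA) — one in each frame
_STOP_TILE = "TAGATAAGTGAC"

#: codons whose first two bases prefix a stop (TAx/TGx, themselves non-stop)
_T_START_CODONS = frozenset({"TAT", "TAC", "TGT", "TGC", "TGG"})


def frameshift_insert(length: int) -> str:
    """A frameshift-causing insert that repair can only fix by removing it whole.

    The body tiles stop codons in all three reading frames (so no kept
    stretch of the insert can be read through in any frame) and the edges
    are engineered: the insert opens with a frame-0 stop (TAG) and closes
    with the end-aligned stop chain TAA+TGA, which also turns every 1- or
    2-base edge keep into a stop codon (T + the last two bases of any stop
    codon is again a stop, as is TA + its last base). Insert at an ORF codon
    boundary chosen by frameshift_sites() for the full uniqueness guarantee.
    """
    if length < 1:
        raise SpecError("insert length must be >= 1")
    body = (_STOP_TILE * (length // len(_STOP_TILE) + 1))[:length]
    if length >= 15:
        body = body[: length - 6] + "TAATGA"
    return body


def frameshift_sites(spec: ElementSpec, element: str) -> list[int]:
    """Codon-aligned insert positions (1-based, element coords) where repair
    of a frameshift_insert() is guaranteed to excise exactly the insert.

    The preceding codon must start TA/TG (its first bases fuse with kept
    insert edges into stop codons for off-by-a-few removals) and the
    following codon must end in A or G (same trick on the right edge).
    """
    orf_start = spec.tir_len + spec.utr5_len  # 0-based
    out = []
    for c in range(2, spec.orf_len // 3 - 2):
        prev = element[orf_start + 3 * (c - 1) : orf_start + 3 * c]
        nxt = element[orf_start + 3 * c : orf_start + 3 * (c + 1)]
        if prev in _T_START_CODONS and nxt[2] in "AG":
            out.append(orf_start + 3 * c + 1)
    return out


def apply_frameshifts(element: str, insertions: tuple[tuple[int, str], ...]) -> str:
    """Insert sequences at 1-based element positions (descending application)."""
    out = element
    for pos, ins in sorted(insertions, reverse=True):
        if not 1 <= pos <= len(element):
            raise PlacementError(f"frameshift position {pos} outside element")
        out = out[: pos - 1] + ins.upper() + out[pos - 1 :]
    return out


def _derived_seeds(plan: PlantPlan) -> tuple[int, int, random.Random]:
    rng = random.Random(plan.rng_seed)
    bg_seed = rng.randrange(2**31)
    el_seed = rng.randrange(2**31)
    return bg_seed, el_seed, rng


def reference_for_plan(spec: ElementSpec, plan: PlantPlan) -> tuple[str, ElementLayout, DdeTriad | None]:
    """The exact reference element that plant_elements plants for this plan."""
    _, el_seed, _ = _derived_seeds(plan)
    return build_element(spec, el_seed)


def plant_elements(
    background_len: int,
    spec: ElementSpec,
    plan: PlantPlan,
    gc: float = 0.42,
) -> tuple[GenomeSequence, list[TruthRecord]]:
    """Plant the plan into a random background at TA target sites.

    Full copies duplicate the TSD (tsd-element-tsd); divergence goes to the
    second full copy, frameshift insertions to the last. Partial copies and
    solo TIRs are inserted without TSD duplication. Deterministic under
    plan.rng_seed; reference_for_plan() reproduces the planted reference.
    """
    bg_seed, el_seed, rng = _derived_seeds(plan)
    background = random_background(background_len, gc, rng_seed=bg_seed)
    element, base_layout, triad = build_element(spec, rng_seed=el_seed)

    copies: list[tuple[str, str, dict]] = []  # (kind, sequence, meta)
    for i in range(plan.n_full):
        seq_i = element
        meta: dict = {"copy_index": i, "n_substitutions": 0, "indel_lengths": (), "frameshifted": False}
        if plan.copy_divergence is not None and i == 1:
            n_sub, indels = plan.copy_divergence
            seq_i = diverge_copy(seq_i, spec, n_sub, tuple(indels), rng)
            meta.update(n_substitutions=n_sub, indel_lengths=tuple(indels))
        if plan.frameshift_insertions and i == plan.n_full - 1:
            seq_i = apply_frameshifts(seq_i, plan.frameshift_insertions)
            meta["frameshifted"] = True
        copies.append(("full", seq_i, meta))
    for j, frac in enumerate(plan.n_partial):
        keep = max(1, int(round(frac * len(element))))
        if rng.random() < 0.5:
            part, meta_end = element[:keep], "3'-truncated"
        else:
            part, meta_end = element[-keep:], "5'-truncated"
        copies.append(
            ("partial", part, {"copy_index": plan.n_full + j, "retained_fraction": keep / len(element), "end": meta_end})
        )
    tir5 = element[: spec.tir_len]
    for k in range(plan.n_solo_tir):
        copies.append(("solo_tir", tir5, {"copy_index": plan.n_full + len(plan.n_partial) + k}))

    if not copies:
        return background, []

    # choose well-separated TA occurrences as insertion sites
    tsd = spec.tsd
    sites = []
    p = background.seq.find(tsd)
    while p != -1:
        sites.append(p)
        p = background.seq.find(tsd, p + 1)
    rng.shuffle(sites)
    min_gap = len(element) + 2 * MIN_EDIT_SPACING
    chosen: list[int] = []
    for s in sites:
        if len(chosen) == len(copies):
            break
        if 10 <= s <= background_len - 10 and all(abs(s - c) >= min_gap for c in chosen):
            chosen.append(s)
    if len(chosen) < len(copies):
        raise PlacementError(
            f"background of {background_len} bp has only {len(chosen)} usable "
            f"{tsd} sites for {len(copies)} placements"
        )
    order = sorted(range(len(chosen)), key=lambda i: chosen[i])

    out_parts: list[str] = []
    truth: list[TruthRecord] = []
    prev = 0
    for idx in order:
        site = chosen[idx]
        kind, seq_i, meta = copies[idx]
        out_parts.append(background.seq[prev : site + 2])  # through the left TA
        offset = sum(len(x) for x in out_parts)
        start = offset + 1  # 1-based start of inserted feature
        out_parts.append(seq_i)
        if kind == "full":
            out_parts.append(tsd)  # duplicated target site
        prev = site + 2
        iv = Interval(background.id, start, start + len(seq_i) - 1)
        rec = TruthRecord(
            kind=kind,
            interval=iv,
            copy_index=meta["copy_index"],
            inserted_seq=seq_i,
            n_substitutions=meta.get("n_substitutions", 0),
            indel_lengths=meta.get("indel_lengths", ()),
            frameshifted=meta.get("frameshifted", False),
            retained_fraction=meta.get("retained_fraction", 1.0),
        )
        if kind == "full" and not rec.frameshifted and not rec.indel_lengths:
            rec.layout = replace(
                base_layout, element=Interval(background.id, iv.start, iv.end)
            )
        truth.append(rec)
    out_parts.append(background.seq[prev:])
    genome = GenomeSequence(id=background.id, seq="".join(out_parts))
    truth.sort(key=lambda r: r.interval.start)
    return genome, truth


def reference_triad(spec: ElementSpec) -> DdeTriad | None:
    if spec.triad is None:
        return None
    t = spec.triad
    return DdeTriad(t.d1_offset_aa, t.d2_offset_aa, t.last_offset_aa, t.last_residue)
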