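"""Amino-acid composition vectors, proteome PCC ranking, and serine-rich
class labels (SR-/SAP-/PS-/SP-rich)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlphabetError, UndefinedCorrelationError, ValidationError

#: the 20 standard residues, alphabetical by one-letter code
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
#: ambiguous/rare codes excluded from numerator and denominator
EXCLUDED = frozenset("BZXUO*-.")

#: approximate background residue frequencies (UniProt/Swiss-Prot averages),
#: used as the default enrichment baseline for rich-class calls
BACKGROUND_FREQS = {
    "A": 0.0826, "C": 0.0136, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class CompositionVector:
    protein_id: str
    freqs: tuple[float, ...]
    n_residues: int

    def __post_init__(self) -> None:
        if len(self.freqs) != 20:
            raise ValidationError("composition vector must have 20 entries")
        if self.n_residues > 0 and abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValidationError(f"frequencies sum to {sum(self.freqs)}, not 1")

    def freq(self, aa: str) -> float:
        return self.freqs[_AA_INDEX[aa]]


@dataclass(frozen=True)
class PccHit:
    protein_id: str
    pcc: float


@dataclass(frozen=True)
class RichClassConfig:
    """Enrichment = frequency >= multiplier x background for that residue."""

    background: dict[str, float] = field(default_factory=lambda: dict(BACKGROUND_FREQS))
    multiplier: float = 1.5


def aa_composition(protein: str, protein_id: str = "query") -> CompositionVector:
    """Per-residue fractions over the 20 standard residues.

    Ambiguous codes (B, Z, X, U, O) and gap characters are excluded from
    both numerator and denominator; anything else unrecognized is an error.
    """
    counts = np.zeros(20)
    n = 0
    for aa in protein.upper():
        if aa in EXCLUDED:
            continue
        idx = _AA_INDEX.get(aa)
        if idx is None:
            raise AlphabetError(f"unknown residue {aa!r}")
        counts[idx] += 1
        n += 1
    if n == 0:
        raise ValidationError("no countable residues after exclusions")
    return CompositionVector(protein_id=protein_id, freqs=tuple(counts / n), n_residues=n)


def composition_pcc(a: CompositionVector, b: CompositionVector) -> float:
    """Pearson correlation of the two 20-vectors (population formula)."""
    x = np.asarray(a.freqs)
    y = np.asarray(b.freqs)
    if x.std() < 1e-12 or y.std() < 1e-12:
        raise UndefinedCorrelationError(
            f"zero-variance composition ({a.protein_id!r} vs {b.protein_id!r})"
        )
    return float(np.corrcoef(x, y)[0, 1])


def rank_against_proteome(
    query: CompositionVector, proteome: list[CompositionVector]
) -> list[PccHit]:
    """Full PCC ranking, descending; ties broken by protein id ascending."""
    if not proteome:
        raise ValidationError("proteome must be non-empty")
    hits = [PccHit(v.protein_id, composition_pcc(query, v)) for v in proteome]
    hits.sort(key=lambda h: (-h.pcc, h.protein_id))
    return hits


def rich_class(v: CompositionVector, thresholds: RichClassConfig | None = None) -> str:
    """Serine-rich category label, or 'none'.

    Serine must itself be enriched for any label; the co-enriched residue(s)
    then decide between SR- (arginine), SAP- (alanine + proline), PS-
    (proline dominant over serine) and SP-rich (proline co-enriched).
    """
    cfg = thresholds or RichClassConfig()

    def enriched(aa: str) -> bool:
        return v.freq(aa) >= cfg.multiplier * cfg.background[aa]

    if not enriched("S"):
        return "none"
    if enriched("R"):
        return "SR-rich"
    if enriched("A") and enriched("P"):
        return "SAP-rich"
    if enriched("P"):
        return "PS-rich" if v.freq("P") > v.freq("S") else "SP-rich"
    return "none"


def composition_ratio(a: CompositionVector, b: CompositionVector) -> dict[str, float | None]:
    """Per-residue frequency ratio a/b rounded to 2 decimals (None when b is 0)."""
    out: dict[str, float | None] = {}
    for aa in AA_ORDER:
        fb = b.freq(aa)
        out[aa] = round(a.freq(aa) / fb, 2) if fb > 0 else None
    return out
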