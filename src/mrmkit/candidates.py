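"""Surrogate-peptide library construction.

In-silico tryptic digestion of blood-protein sequences, rule-based
prioritization of the resulting peptides, per-protein surrogate selection,
and precursor/y-ion m/z computation for light and heavy (stable-isotope
labeled) forms.

The selection rules encode standard proteotypic-peptide practice for short
gradient MRM assays on neat serum/plasma: favor lengths of 6-16 residues,
avoid chemically unstable residues (Cys, Met, N-terminal Trp), avoid
N-glycosylation sequons (N-X-S/T, X != P), avoid extreme hydrophobicity
(poor retention-time reproducibility), and avoid ragged C-termini
(K/R-K/R dipeptides prone to variable tryptic cleavage).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import InputError

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MONO = 18.0105646863
PROTON_MASS = 1.00727646688

# 13C-12C and 15N-14N mass differences; the heavy labels are
# K(13C6,15N2) and R(13C6,15N4).
_D13C = 1.003355
_D15N = 0.997035
HEAVY_SHIFT_K = 6 * _D13C + 2 * _D15N  # 8.01420 Da
HEAVY_SHIFT_R = 6 * _D13C + 4 * _D15N  # 10.00827 Da

#: C-terminal dipeptides resistant to tryptic cleavage. KP/RP suppress
#: cleavage during digestion; RR/KK/RK/KR mark ragged peptide C-termini.
CLEAVAGE_RESISTANT_PAIRS = frozenset({"RR", "KK", "RK", "KR", "KP", "RP"})


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence entry (uppercase, 20 standard residues)."""

    protein_id: str
    sequence: str

    def validate(self) -> None:
        if not self.sequence:
            raise InputError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise InputError(
                f"protein {self.protein_id!r}: invalid residues {sorted(bad)}"
            )


@dataclass
class PeptideCandidate:
    """A tryptic peptide with digestion coordinates and priority scoring.

    ``start``/``end`` are 0-based half-open coordinates in the parent
    protein. ``flags`` collects violated selection criteria;
    ``priority_tier`` is 1 + number of flags (1 = best). ``selected``
    marks the peptide chosen as the protein's surrogate.
    """

    protein_id: str
    sequence: str
    start: int
    end: int
    gravy: float = 0.0
    flags: set[str] = field(default_factory=set)
    priority_tier: int = 1
    selected: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable thresholds for candidate scoring and surrogate selection."""

    length_min: int = 6
    length_max: int = 16
    gravy_bounds: tuple[float, float] = (-2.0, 2.0)
    cleavage_resistant_pairs: frozenset[str] = CLEAVAGE_RESISTANT_PAIRS
    max_peptides_per_protein: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise InputError("length_min must be <= length_max")
        if self.gravy_bounds[0] >= self.gravy_bounds[1]:
            raise InputError("gravy_bounds must satisfy low < high")


@dataclass(frozen=True)
class TransitionSet:
    """Precursor plus product y-ions for one peptide in one label state."""

    sequence: str
    precursor_charge: int
    precursor_mz: float
    product_ions: tuple[tuple[str, int, int, float], ...]  # (type, index, z, mz)
    label_state: str  # "light" | "heavy"
    heavy_shift: float  # Da; 0 for light


def _cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin cuts: K/R not followed by P."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest_tryptic(
    protein: ProteinRecord, *, keep_nontryptic_cterm: bool = False
) -> list[PeptideCandidate]:
    """Fully tryptic digestion with zero missed cleavages.

    Cleaves after K/R except before proline. The protein N-terminal
    peptide is always included (its left boundary is the protein start);
    the C-terminal fragment is included only if it ends in K/R, unless
    ``keep_nontryptic_cterm`` is set (then it carries a ``non_tryptic``
    flag). Peptides are returned in N-to-C order.
    """
    protein.validate()
    seq = protein.sequence
    bounds = [0] + _cleavage_sites(seq) + [len(seq)]
    out: list[PeptideCandidate] = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        pep = PeptideCandidate(
            protein_id=protein.protein_id, sequence=seq[start:end],
            start=start, end=end,
        )
        if pep.sequence[-1] not in "KR":
            # only possible for the protein C-terminal fragment
            if keep_nontryptic_cterm:
                pep.flags.add("non_tryptic")
                out.append(pep)
            continue
        out.append(pep)
    return out


def gravy_score(sequence: str) -> float:
    """Kyte-Doolittle grand average of hydropathy."""
    return ProteinAnalysis(sequence).gravy()


def _has_glyco_sequon(sequence: str) -> bool:
    """N-X-[S/T] with X != P anywhere in the peptide."""
    for i in range(len(sequence) - 2):
        if (
            sequence[i] == "N"
            and sequence[i + 1] != "P"
            and sequence[i + 2] in "ST"
        ):
            return True
    return False


def score_candidate(
    peptide: PeptideCandidate, cfg: SelectionConfig = SelectionConfig()
) -> PeptideCandidate:
    """Fill selection flags and the priority tier for one candidate.

    Each violated criterion adds one flag; tier = 1 + number of flags,
    so an unflagged peptide is tier 1 (best).
    """
    flags = {f for f in peptide.flags if f == "non_tryptic"}
    seq = peptide.sequence
    if not (cfg.length_min <= len(seq) <= cfg.length_max):
        flags.add("length_out_of_range")
    g = gravy_score(seq)
    if not (cfg.gravy_bounds[0] <= g <= cfg.gravy_bounds[1]):
        flags.add("hydrophobicity_extreme")
    if "C" in seq:
        flags.add("has_cys")
    if "M" in seq:
        flags.add("has_met")
    if seq[0] == "W":
        flags.add("nterm_trp")
    if _has_glyco_sequon(seq):
        flags.add("glyco_sequon")
    if len(seq) >= 2 and seq[-2:] in cfg.cleavage_resistant_pairs:
        flags.add("ragged_end")
    return PeptideCandidate(
        protein_id=peptide.protein_id, sequence=peptide.sequence,
        start=peptide.start, end=peptide.end, gravy=g,
        flags=flags, priority_tier=1 + len(flags), selected=peptide.selected,
    )


def select_surrogates(
    candidates: list[PeptideCandidate], cfg: SelectionConfig = SelectionConfig()
) -> tuple[list[PeptideCandidate], list[str]]:
    """Pick surrogate peptides per protein from the best available tier.

    Candidates must already be scored. Within the best tier, ties are
    broken by a seeded random choice; proteins whose best tier is > 1
    still get a surrogate (lower-priority fallback). Returns the selected
    candidates (``selected=True``) and the ids of proteins that had no
    candidates at all.
    """
    rng = random.Random(cfg.seed)
    by_protein: dict[str, list[PeptideCandidate]] = {}
    for c in candidates:
        by_protein.setdefault(c.protein_id, []).append(c)
    selected: list[PeptideCandidate] = []
    empty_proteins: list[str] = []
    for pid in sorted(by_protein):
        group = by_protein[pid]
        if not group:
            empty_proteins.append(pid)
            continue
        group = sorted(group, key=lambda c: (c.priority_tier, c.start))
        best_tier = group[0].priority_tier
        pool = [c for c in group if c.priority_tier == best_tier]
        k = min(cfg.max_peptides_per_protein, len(pool))
        picks = pool if len(pool) <= k else rng.sample(pool, k)
        for c in sorted(picks, key=lambda c: c.start):
            c.selected = True
            selected.append(c)
    return selected, empty_proteins


def peptide_monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of an unmodified peptide, Da."""
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise InputError(f"invalid residues {sorted(bad)}")
    if not sequence:
        raise InputError("empty peptide sequence")
    return sum(MONOISOTOPIC_RESIDUE_MASS[a] for a in sequence) + WATER_MONO


def heavy_shift_for(sequence: str) -> float:
    """Mass shift of the C-terminal K/R heavy label, Da."""
    if sequence.endswith("K"):
        return HEAVY_SHIFT_K
    if sequence.endswith("R"):
        return HEAVY_SHIFT_R
    raise InputError(
        f"heavy label requires a C-terminal K or R (got {sequence[-1:]!r})"
    )


def compute_mz(
    sequence: str,
    charge: int = 2,
    label_state: str = "light",
    n_products: int = 3,
) -> TransitionSet:
    """Precursor and top product y-ion m/z values for one peptide.

    The heavy state carries the C-terminal K/R stable-isotope label, so
    the precursor and every y-ion shift by the label mass (divided by
    charge). Products are the three longest singly charged y-ions
    (y_{n-1}, y_{n-2}, y_{n-3}), the usual default when no measured
    intensity ranking is available.
    """
    if charge < 1:
        raise InputError("charge must be >= 1")
    if label_state not in ("light", "heavy"):
        raise InputError(f"unknown label_state {label_state!r}")
    mass = peptide_monoisotopic_mass(sequence)
    shift = heavy_shift_for(sequence) if label_state == "heavy" else 0.0
    precursor_mz = (mass + shift + charge * PROTON_MASS) / charge
    n = len(sequence)
    products = []
    for idx in range(n - 1, max(n - 1 - n_products, 0), -1):
        suffix = sequence[n - idx:]
        y_mass = sum(MONOISOTOPIC_RESIDUE_MASS[a] for a in suffix) + WATER_MONO
        y_mz = (y_mass + shift + PROTON_MASS) / 1
        products.append(("y", idx, 1, y_mz))
    return TransitionSet(
        sequence=sequence, precursor_charge=charge, precursor_mz=precursor_mz,
        product_ions=tuple(products), label_state=label_state,
        heavy_shift=shift if label_state == "heavy" else 0.0,
    )


def build_library(
    proteins: list[ProteinRecord], cfg: SelectionConfig = SelectionConfig()
) -> tuple[list[PeptideCandidate], list[str]]:
    """Digest, score and select one surrogate peptide per protein."""
    scored: list[PeptideCandidate] = []
    for prot in proteins:
        for pep in digest_tryptic(prot):
            scored.append(score_candidate(pep, cfg))
    return select_surrogates(scored, cfg)
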