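"""RNA secondary-structure folding and duplex hybridisation energies.

The default engine is a self-contained minimum-free-energy folder over a
simplified per-pair energy model (GC -3.0, AU -2.0, GU -1.0 kcal/mol, loops
free, no stacking terms).  It is deliberately small enough to verify against
exhaustive enumeration of all nested structures, which is what hairpin
screening needs: a reproducible stability score with a fixed acceptance
threshold, not a faithful thermodynamic ensemble.  A full nearest-neighbour
engine (ViennaRNA) can be swapped in via ``EnergyModel(backend="vienna")``;
thresholds are then applied on that engine's energy scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

__all__ = [
    "EnergyModel",
    "FoldResult",
    "fold_mfe",
    "duplex_energy",
    "perfect_complement_energy",
    "classify_pairs",
    "to_rna",
]

_RNA_ALPHABET = set("ACGU")

# Watson-Crick plus wobble, symmetric.
_PAIR_ENERGY: Dict[frozenset, float] = {
    frozenset(("G", "C")): -3.0,
    frozenset(("A", "U")): -2.0,
    frozenset(("G", "U")): -1.0,
}

_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}


def to_rna(seq: str) -> str:
    """Uppercase and convert a DNA/RNA string to the RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


def _check_alphabet(seq: str) -> None:
    bad = sorted(set(seq) - _RNA_ALPHABET)
    if bad:
        raise ValueError(f"invalid RNA characters: {','.join(bad)}")


def pair_energy(a: str, b: str) -> float:
    """Energy of pairing bases *a* and *b*; 0.0 if they cannot pair."""
    return _PAIR_ENERGY.get(frozenset((a, b)), 0.0)


def can_pair(a: str, b: str) -> bool:
    return frozenset((a, b)) in _PAIR_ENERGY


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the simplified folding model.

    Attributes
    ----------
    pair_energies:
        Per-pair stabilities in kcal/mol; must all be negative.
    min_hairpin_loop:
        Minimum number of unpaired bases closing a hairpin loop (>= 3).
    backend:
        ``"internal"`` for the built-in dynamic program, ``"vienna"`` for
        the ViennaRNA nearest-neighbour engine (optional dependency).
    """

    pair_energies: Dict[frozenset, float] = field(
        default_factory=lambda: dict(_PAIR_ENERGY)
    )
    min_hairpin_loop: int = 3
    backend: str = "internal"

    def __post_init__(self) -> None:
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")
        if any(e >= 0 for e in self.pair_energies.values()):
            raise ValueError("pair energies must be negative")
        if self.backend not in ("internal", "vienna"):
            raise ValueError(f"unknown folding backend: {self.backend!r}")

    def energy(self, a: str, b: str) -> float:
        return self.pair_energies.get(frozenset((a, b)), 0.0)

    def pairable(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.pair_energies


DEFAULT_MODEL = EnergyModel()


@dataclass
class FoldResult:
    """A folded structure: dot-bracket string, MFE and a pair table.

    ``pair_table`` maps each paired 0-based position to its partner
    (both directions present); unpaired positions are absent.
    """

    structure: str
    mfe: float
    pair_table: Dict[int, int]

    def partner(self, i: int) -> Optional[int]:
        return self.pair_table.get(i)


def fold_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL) -> FoldResult:
    """Fold *seq* (RNA; T accepted and converted) to its minimum-energy
    nested structure.

    The internal backend minimises the summed pair energies over all
    pseudoknot-free structures honouring the minimum hairpin loop, by
    interval dynamic programming.  Ties in energy are broken by preferring
    the structure with more pairs, then the one pairing the 5'-most base
    with its leftmost admissible partner.
    """
    rna = to_rna(seq)
    _check_alphabet(rna)
    if len(rna) < 10:
        raise ValueError(f"sequence too short to fold ({len(rna)} < 10 nt)")
    if model.backend == "vienna":
        return _fold_vienna(rna)
    return _fold_internal(rna, model)


def _fold_internal(rna: str, model: EnergyModel) -> FoldResult:
    n = len(rna)
    h = model.min_hairpin_loop
    NEG = (0.0, 0)  # (energy, -pairs) of the empty structure

    # best[(i, j)] = (energy, -npairs) over interval [i, j] inclusive
    best: Dict[Tuple[int, int], Tuple[float, int]] = {}

    def get(i: int, j: int) -> Tuple[float, int]:
        if i > j:
            return NEG
        return best[(i, j)]

    for span in range(0, n):
        for i in range(0, n - span):
            j = i + span
            if span < h + 1:
                best[(i, j)] = NEG
                continue
            # option: i unpaired
            opt = get(i + 1, j)
            # option: i paired with k
            for k in range(i + h + 1, j + 1):
                if not model.pairable(rna[i], rna[k]):
                    continue
                e_in = get(i + 1, k - 1)
                e_out = get(k + 1, j)
                cand = (
                    model.energy(rna[i], rna[k]) + e_in[0] + e_out[0],
                    e_in[1] + e_out[1] - 1,
                )
                if cand < opt:
                    opt = cand
            best[(i, j)] = opt

    # traceback, preferring "pair i with leftmost k" over "leave i unpaired"
    pairs: Dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i > j or j - i < h + 1:
            continue
        target = get(i, j)
        placed = False
        for k in range(i + h + 1, j + 1):
            if not model.pairable(rna[i], rna[k]):
                continue
            e_in = get(i + 1, k - 1)
            e_out = get(k + 1, j)
            cand = (
                model.energy(rna[i], rna[k]) + e_in[0] + e_out[0],
                e_in[1] + e_out[1] - 1,
            )
            if cand == target:
                pairs[i] = k
                pairs[k] = i
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                placed = True
                break
        if not placed:
            stack.append((i + 1, j))

    structure = "".join(
        "(" if pairs.get(i, -1) > i else (")" if i in pairs else ".")
        for i in range(n)
    )
    mfe = get(0, n - 1)[0]
    return FoldResult(structure=structure, mfe=mfe, pair_table=pairs)


def _fold_vienna(rna: str) -> FoldResult:
    try:
        import RNA  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional backend
        raise ImportError(
            "the 'vienna' folding backend requires the ViennaRNA python "
            "bindings (pip install viennarna)"
        ) from exc
    structure, mfe = RNA.fold(rna)
    return FoldResult(
        structure=structure,
        mfe=float(mfe),
        pair_table=pair_table_from_dotbracket(structure),
    )


def pair_table_from_dotbracket(structure: str) -> Dict[int, int]:
    """Parse a dot-bracket string into a symmetric position->partner map."""
    stack = []
    pairs: Dict[int, int] = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def classify_pairs(mirna: str, target_site: str) -> list:
    """Classify an ungapped antiparallel miRNA/target duplex per position.

    ``target_site`` is the target window written 5'->3'; miRNA position
    ``i`` (0-based from the miRNA 5' end) faces target position
    ``L - 1 - i``.  Returns a list of ``"WC"``, ``"GU"`` or ``"MM"`` of the
    miRNA's length.
    """
    mi = to_rna(mirna)
    tg = to_rna(target_site)
    if len(mi) != len(tg):
        raise ValueError(
            f"miRNA ({len(mi)} nt) and target window ({len(tg)} nt) "
            "must have equal length for an ungapped duplex"
        )
    _check_alphabet(mi)
    _check_alphabet(tg)
    out = []
    L = len(mi)
    for i in range(L):
        a, b = mi[i], tg[L - 1 - i]
        if _WC_PARTNER[a] == b:
            out.append("WC")
        elif frozenset((a, b)) == frozenset(("G", "U")):
            out.append("GU")
        else:
            out.append("MM")
    return out


def duplex_energy(
    mirna: str,
    target_site: str,
    alignment: Optional[Sequence[Tuple[int, Optional[int]]]] = None,
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Hybridisation energy of a miRNA/target duplex.

    *alignment* pairs each miRNA position (0-based) with a target position
    or ``None`` for a gap; by default the ungapped antiparallel alignment
    ``i <-> L-1-i`` is used.  Aligned positions that form Watson-Crick or
    GU pairs contribute their pair energy; mismatches and gaps contribute 0.
    """
    mi = to_rna(mirna)
    tg = to_rna(target_site)
    _check_alphabet(mi)
    _check_alphabet(tg)
    if alignment is None:
        if len(mi) != len(tg):
            raise ValueError("default alignment requires equal lengths")
        alignment = [(i, len(tg) - 1 - i) for i in range(len(mi))]
    total = 0.0
    for i, j in alignment:
        if j is None:
            continue
        if not (0 <= i < len(mi)) or not (0 <= j < len(tg)):
            raise IndexError(f"alignment position ({i},{j}) out of range")
        total += model.energy(mi[i], tg[j])
    return total


def perfect_complement_energy(
    mirna: str, model: EnergyModel = DEFAULT_MODEL
) -> float:
    """Energy of *mirna* bound to its exact Watson-Crick complement."""
    mi = to_rna(mirna)
    _check_alphabet(mi)
    if not mi:
        warnings.warn("perfect_complement_energy of empty sequence is 0.0")
    return sum(model.energy(b, _WC_PARTNER[b]) for b in mi)
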