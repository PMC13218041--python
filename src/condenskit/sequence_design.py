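"""ssDNA library design: shuffled pools, palindrome screening, stability
ranking by nested base-pair maximization, chimera assembly, and charge
bookkeeping for peptide/DNA stoichiometry.

Conventions
-----------
* Nucleotide alphabet is strictly ``{A, C, G, T}``.
* A *palindrome* is a reverse-complement palindrome: a segment equal to
  the reverse complement of itself.  Such segments always have even
  length.  ``find_palindromes`` reports *maximal* hits (not extendable
  by one base on each side); overlapping maximal hits are allowed.
* All intervals are 0-based and half-open.
* Stability ranking uses nested Watson-Crick base-pair maximization as
  an ordinal proxy: fewer attainable pairs means less predicted
  structure, i.e. a less stable (higher free energy) fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NucleotideSequence",
    "PalindromeHit",
    "FoldPrediction",
    "PeptideSequence",
    "AlphabetError",
    "EmptySelectionError",
    "reverse_complement",
    "find_palindromes",
    "shuffle_library",
    "fold_proxy",
    "select_candidate",
    "assemble_chimera",
    "peptide_net_charge",
    "charge_stoichiometry",
    "molar_ratio",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")


class AlphabetError(ValueError):
    """Raised when a sequence contains a symbol outside its alphabet."""


class EmptySelectionError(ValueError):
    """Raised when candidate selection filters out every library member."""


def _validate_bases(bases: str) -> None:
    for pos, b in enumerate(bases):
        if b not in _COMPLEMENT:
            raise AlphabetError(
                f"invalid nucleotide {b!r} at position {pos}; alphabet is A/C/G/T"
            )


@dataclass(frozen=True)
class NucleotideSequence:
    """A labelled ssDNA sequence over the A/C/G/T alphabet."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        _validate_bases(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def composition(self) -> dict[str, int]:
        return {b: self.bases.count(b) for b in "ACGT"}


@dataclass(frozen=True)
class PalindromeHit:
    """A maximal reverse-complement palindromic segment."""

    start: int
    length: int
    segment: str

    def __post_init__(self) -> None:
        if self.length % 2 != 0:
            raise ValueError("reverse-complement palindromes have even length")
        if len(self.segment) != self.length:
            raise ValueError("segment/length mismatch")


@dataclass(frozen=True)
class FoldPrediction:
    """Maximum nested Watson-Crick pairing of a sequence.

    ``pairs`` holds 0-based (i, j) index pairs with i < j; ``structure``
    is the dot-bracket rendering.  ``pair_count`` serves as an ordinal
    stability score (more pairs = more predicted structure).
    """

    pair_count: int
    pairs: tuple[tuple[int, int], ...]
    structure: str


@dataclass(frozen=True)
class PeptideSequence:
    """One-letter amino-acid sequence with its side-chain net charge."""

    id: str
    residues: str
    net_charge: int = field(init=False)

    def __post_init__(self) -> None:
        for pos, r in enumerate(self.residues):
            if r not in _AA_CODES:
                raise AlphabetError(
                    f"invalid residue {r!r} at position {pos}; "
                    "expected one-letter canonical code"
                )
        object.__setattr__(self, "net_charge", _net_charge(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


def _as_bases(seq: "NucleotideSequence | str") -> str:
    if isinstance(seq, NucleotideSequence):
        return seq.bases
    _validate_bases(seq)
    return seq


def reverse_complement(seq: "NucleotideSequence | str") -> "NucleotideSequence | str":
    """Reverse complement; an involution on every valid sequence."""
    bases = _as_bases(seq)
    rc = "".join(_COMPLEMENT[b] for b in reversed(bases))
    if isinstance(seq, NucleotideSequence):
        return NucleotideSequence(id=f"{seq.id}_rc", bases=rc)
    return rc


def find_palindromes(
    seq: "NucleotideSequence | str", min_len: int = 6
) -> list[PalindromeHit]:
    """All maximal reverse-complement palindromic segments of length >= min_len.

    Expands around each of the n-1 inter-base centers; each center yields
    at most one maximal hit.  Hits are sorted by start position.
    """
    if min_len % 2 != 0:
        raise ValueError(
            f"min_len must be even (reverse-complement palindromes have "
            f"even length), got {min_len}"
        )
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    bases = _as_bases(seq)
    n = len(bases)
    hits: list[PalindromeHit] = []
    for center in range(1, n):
        # expand symmetrically: bases[center-1-k] must pair bases[center+k]
        radius = 0
        while (
            center - 1 - radius >= 0
            and center + radius < n
            and _COMPLEMENT[bases[center - 1 - radius]] == bases[center + radius]
        ):
            radius += 1
        length = 2 * radius
        if length >= min_len:
            start = center - radius
            hits.append(
                PalindromeHit(start=start, length=length, segment=bases[start : start + length])
            )
    hits.sort(key=lambda h: (h.start, h.length))
    return hits


def shuffle_library(
    seq: NucleotideSequence, n: int, seed: int
) -> list[NucleotideSequence]:
    """A pool of ``n`` seeded mononucleotide shuffles of ``seq``.

    Every output is a permutation of the input bases (identical base
    composition); the same seed yields a byte-identical library.
    """
    if n < 1:
        raise ValueError(f"library size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq.bases))
    library = []
    for i in range(n):
        shuffled = "".join(rng.permutation(letters))
        library.append(NucleotideSequence(id=f"{seq.id}_shuf{i:03d}", bases=shuffled))
    return library


def fold_proxy(seq: "NucleotideSequence | str", min_loop: int = 3) -> FoldPrediction:
    """Maximum nested Watson-Crick pairing with a minimum hairpin loop.

    Dynamic program over intervals: N[i][j] is the largest number of
    nested A-T / G-C pairs in bases[i..j] subject to j - i - 1 >= min_loop
    for every pair (i, j).  Traceback yields one optimal pair set and its
    dot-bracket structure.  Used only ordinally, as a stability proxy.
    """
    if min_loop < 0:
        raise ValueError(f"min_loop must be >= 0, got {min_loop}")
    bases = _as_bases(seq)
    n = len(bases)

    def can_pair(i: int, j: int) -> bool:
        return _COMPLEMENT[bases[i]] == bases[j]

    # N[i][j] for i <= j; zero below the min-loop diagonal
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k):
                    left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = N[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            N[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        if N[i, j] == N[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(i, k):
                left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = N[k + 1, j] if k + 1 <= j else 0
                if 1 + left + right == N[i, j]:
                    pairs.append((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break

    pairs.sort()
    structure = ["." for _ in range(n)]
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return FoldPrediction(
        pair_count=int(N[0, n - 1]) if n > 1 else 0,
        pairs=tuple(pairs),
        structure="".join(structure),
    )


def select_candidate(
    library: list[NucleotideSequence],
    min_palindrome: int = 6,
    rank: int = 1,
    min_loop: int = 3,
) -> NucleotideSequence:
    """Pick the ``rank``-th least structured palindrome-free library member.

    Sequences containing any palindrome of length >= ``min_palindrome``
    are excluded; survivors are ranked by ascending ``fold_proxy`` pair
    count (fewest pairs = least predicted stability).  Ties keep library
    order (stable sort).  ``rank`` is 1-based.
    """
    if not library:
        raise ValueError("library is empty")
    survivors = [
        s for s in library if not find_palindromes(s, min_len=min_palindrome)
    ]
    if not survivors:
        raise EmptySelectionError(
            f"every sequence contains a palindrome of length >= {min_palindrome}"
        )
    if rank < 1 or rank > len(survivors):
        raise ValueError(
            f"rank {rank} out of range; {len(survivors)} sequences survive screening"
        )
    ordered = sorted(
        survivors, key=lambda s: fold_proxy(s, min_loop=min_loop).pair_count
    )
    return ordered[rank - 1]


def assemble_chimera(
    ordered: NucleotideSequence,
    disordered: NucleotideSequence,
    regions: list[tuple[int, int]],
) -> NucleotideSequence:
    """Splice ``ordered`` segments into a ``disordered`` backbone.

    ``regions`` are 0-based half-open intervals taken from the ordered
    parent; everything else comes from the disordered parent.
    """
    if len(ordered) != len(disordered):
        raise ValueError(
            f"parents differ in length: {len(ordered)} vs {len(disordered)}"
        )
    n = len(ordered)
    taken = np.zeros(n, dtype=bool)
    for start, stop in regions:
        if not (0 <= start <= stop <= n):
            raise ValueError(f"interval ({start}, {stop}) out of bounds for length {n}")
        if taken[start:stop].any():
            raise ValueError(f"interval ({start}, {stop}) overlaps a previous interval")
        taken[start:stop] = True
    bases = "".join(
        ordered.bases[i] if taken[i] else disordered.bases[i] for i in range(n)
    )
    return NucleotideSequence(id=f"{ordered.id}x{disordered.id}", bases=bases)


def _net_charge(residues: str) -> int:
    pos = sum(residues.count(r) for r in "KR")
    neg = sum(residues.count(r) for r in "DE")
    return pos - neg


def peptide_net_charge(pep: "PeptideSequence | str") -> int:
    """Side-chain net charge at neutral pH: count(K,R) - count(D,E).

    Histidine and the free termini contribute zero.
    """
    if isinstance(pep, PeptideSequence):
        return pep.net_charge
    for pos, r in enumerate(pep):
        if r not in _AA_CODES:
            raise AlphabetError(f"invalid residue {r!r} at position {pos}")
    return _net_charge(pep)


def charge_stoichiometry(
    dna_length: int, peptide_charge: int
) -> tuple[float, int]:
    """Peptides per DNA at a 1:1 charge ratio.

    DNA carries one negative charge per phosphodiester bond, i.e.
    ``dna_length - 1`` charges.  Returns the exact ratio and its nearest
    integer.
    """
    if dna_length < 2:
        raise ValueError(f"dna_length must be >= 2, got {dna_length}")
    if peptide_charge <= 0:
        raise ValueError(f"peptide_charge must be positive, got {peptide_charge}")
    ratio = (dna_length - 1) / peptide_charge
    return ratio, int(round(ratio))


def molar_ratio(conc_a: float, conc_b: float) -> float:
    """Ratio of two concentrations given in the same units."""
    if conc_a < 0 or conc_b <= 0:
        raise ValueError("concentrations must be positive")
    return conc_a / conc_b
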