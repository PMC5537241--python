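"""In-silico restriction digestion of tandem repeat arrays.

Models the classical Southern-blot satellite assay: digesting genomic DNA
with an enzyme whose site is conserved once per monomer releases a ladder of
monomer multimers.  Methylation-sensitive isoschizomers (HpaII/MspI on CCGG)
are modelled through per-site sensitivity rules evaluated against the array's
cytosine methylation map, and partial digestion as an independent Bernoulli
cut per susceptible site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .seqio import reverse_complement

__all__ = [
    "Enzyme",
    "TandemArray",
    "FragmentSpectrum",
    "ENZYMES",
    "find_sites",
    "digest",
    "ladder_profile",
    "load_enzyme_table",
]

# A sensitivity rule receives (site_start_0based, recognition, methylation_map,
# array_length) and returns True when the site can be cut.
SensitivityRule = Callable[[int, str, frozenset, int], bool]


def _rule_insensitive(start, recog, meth, n) -> bool:
    return True


def _ccgg_positions(start: int, n: int) -> dict[str, tuple[int, int]]:
    """1-based (position, strand-coded) cytosines of a CCGG site at `start`.

    Direct-strand Cs sit at offsets 0 (outer) and 1 (inner); the complementary
    strand of the palindrome carries its inner C opposite the G at offset 2
    and its outer C opposite the G at offset 3.
    """
    p = lambda off: (start + off) % n + 1
    return {
        "outer_direct": (p(0), "direct"),
        "inner_direct": (p(1), "direct"),
        "inner_complementary": (p(2), "complementary"),
        "outer_complementary": (p(3), "complementary"),
    }


def _rule_mspi(start, recog, meth, n) -> bool:
    # MspI (C^CGG) tolerates internal-C methylation, blocked by outer-C 5mC
    cs = _ccgg_positions(start, n)
    return cs["outer_direct"] not in meth and cs["outer_complementary"] not in meth


def _rule_hpaii(start, recog, meth, n) -> bool:
    # HpaII (C^CGG): blocked only by full (both-strand) internal-C
    # methylation; hemimethylated sites are still cut.
    cs = _ccgg_positions(start, n)
    return not (cs["inner_direct"] in meth and cs["inner_complementary"] in meth)


RULES: dict[str, SensitivityRule] = {
    "insensitive": _rule_insensitive,
    "mspi_ccgg": _rule_mspi,
    "hpaii_ccgg": _rule_hpaii,
}


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition motif, cut offset, sensitivity rule."""

    name: str
    recognition: str
    cut_offset: int
    sensitivity: str = "insensitive"

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise ValueError("recognition site must be >= 4 bp")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut offset outside recognition site")
        if set(self.recognition) - set("ACGT"):
            raise ValueError("recognition must be over A,C,G,T")
        if self.sensitivity not in RULES:
            raise ValueError(f"unknown sensitivity rule {self.sensitivity!r}")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition

    def can_cut(self, start: int, meth: frozenset, n: int) -> bool:
        return RULES[self.sensitivity](start, self.recognition, meth, n)


ENZYMES: dict[str, Enzyme] = {
    "HaeIII": Enzyme("HaeIII", "GGCC", 2),
    "TaqI": Enzyme("TaqI", "TCGA", 1),
    "PvuII": Enzyme("PvuII", "CAGCTG", 3),
    "MspI": Enzyme("MspI", "CCGG", 1, "mspi_ccgg"),
    "HpaII": Enzyme("HpaII", "CCGG", 1, "hpaii_ccgg"),
}


def load_enzyme_table(path: str | Path) -> dict[str, Enzyme]:
    """Load enzyme definitions from a TSV (name, motif, offset, rule)."""
    out: dict[str, Enzyme] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("name\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: need name, motif, offset[, rule]")
        name, motif, offset = parts[0], parts[1].upper(), int(parts[2])
        rule = parts[3] if len(parts) > 3 else "insensitive"
        out[name] = Enzyme(name, motif, offset, rule)
    return out


@dataclass(frozen=True)
class TandemArray:
    """A concatenated head-to-tail monomer array with a methylation map.

    ``methylation_map`` holds (1-based array position, strand) pairs of
    methylated cytosines; strand is ``direct`` or ``complementary`` (the
    complementary-strand C opposite a direct-strand G is recorded at the
    direct-strand coordinate of that G).
    """

    monomer_ids: tuple[str, ...]
    sequence: str
    methylation_map: frozenset = frozenset()
    circular: bool = False

    def __post_init__(self):
        for pos, strand in self.methylation_map:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"methylation at {pos} outside array")
            base = self.sequence[pos - 1]
            expected = "C" if strand == "direct" else "G"
            if base != expected:
                raise ValueError(
                    f"methylation at ({pos},{strand}) marks {base}, not a cytosine"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentSpectrum:
    """Fragment-length multiset from a digestion, with monomer-unit ladder."""

    lengths: tuple[int, ...]
    unit: int

    def total(self) -> int:
        return sum(self.lengths)

    def ladder(self, tolerance: int = 2) -> dict[int, int]:
        return ladder_profile(self, tolerance)

    def off_ladder_fraction(self, tolerance: int = 2) -> float:
        on = sum(self.ladder(tolerance).values())
        return 1.0 - on / len(self.lengths) if self.lengths else 0.0

    def to_tsv(self, path: str | Path) -> None:
        counts = Counter(self.lengths)
        lines = ["length\tcount"] + [
            f"{length}\t{count}" for length, count in sorted(counts.items())
        ]
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text("\n".join(lines) + "\n")

    def virtual_gel(self, max_rows: int = 20) -> str:
        """Crude text rendering of the band pattern (longest on top)."""
        counts = Counter(self.lengths)
        rows = sorted(counts.items(), reverse=True)[:max_rows]
        peak = max(c for _, c in rows)
        return "\n".join(
            f"{length:>7} bp |{'#' * max(1, round(10 * c / peak))} ({c})"
            for length, c in rows
        )


def find_sites(array: TandemArray, enzyme: Enzyme) -> list[int]:
    """0-based start positions of recognition sites on the array.

    Both strands are searched (reverse-complement matches reported by their
    direct-strand start); palindromes are counted once.  Circular arrays are
    searched across the origin.
    """
    seq = array.sequence
    n = len(seq)
    motifs = {enzyme.recognition}
    if not enzyme.is_palindromic:
        motifs.add(reverse_complement(enzyme.recognition))
    search = seq + (seq[: len(enzyme.recognition) - 1] if array.circular else "")
    sites: set[int] = set()
    for motif in motifs:
        start = search.find(motif)
        while start != -1:
            sites.add(start % n)
            start = search.find(motif, start + 1)
    return sorted(sites)


def digest(
    array: TandemArray,
    enzyme: Enzyme,
    partial_probability: float = 1.0,
    seed: int | None = None,
    unit: int | None = None,
) -> FragmentSpectrum:
    """Digest the array, honouring methylation sensitivity and partial cutting.

    Each site passing the enzyme's sensitivity rule is cut independently with
    probability `partial_probability`.  Fragment lengths between successive
    realized cuts are returned; an uncut linear array yields itself as a
    single fragment.  `unit` defaults to array length / number of monomers.
    """
    if not 0 < partial_probability <= 1:
        raise ValueError("partial_probability must be in (0, 1]")
    n = len(array)
    if unit is None:
        unit = n // max(len(array.monomer_ids), 1)
    rng = np.random.default_rng(seed)
    cuts: list[int] = []  # 0-based cut coordinates (between pos-1 and pos)
    for start in find_sites(array, enzyme):
        if not enzyme.can_cut(start, array.methylation_map, n):
            continue
        if partial_probability < 1 and rng.random() >= partial_probability:
            continue
        cuts.append((start + enzyme.cut_offset) % n)
    cuts = sorted(set(cuts))

    if not cuts:
        return FragmentSpectrum((n,), unit)
    lengths: list[int] = []
    if array.circular:
        for a, b in zip(cuts, cuts[1:] + [cuts[0] + n]):
            lengths.append(b - a)
    else:
        bounds = [0] + cuts + [n]
        lengths = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return FragmentSpectrum(tuple(lengths), unit)


def ladder_profile(spec: FragmentSpectrum, tolerance: int = 2) -> dict[int, int]:
    """Assign fragments to monomer-multimer rungs within +/- tolerance bp."""
    if spec.unit <= 0:
        raise ValueError("monomer unit must be positive")
    ladder: Counter[int] = Counter()
    for length in spec.lengths:
        k = round(length / spec.unit)
        if k >= 1 and abs(length - k * spec.unit) <= tolerance:
            ladder[k] += 1
    return dict(sorted(ladder.items()))
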