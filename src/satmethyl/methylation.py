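"""Bisulfite methylation calling on satellite monomers.

Sanger-cloned bisulfite reads (one molecule per read) are aligned against the
native monomer consensus with a bisulfite-aware scoring in which read-T
against reference-C counts as a match.  Per monomer position and strand, the
proportion of cytosine remaining after conversion is normalized by the
proportion of C+T in the untransformed monomer library at that column, which
removes the bias introduced by spontaneous C->T point mutations segregating in
the native repeat pool.  Cytosine context (CG / CHG / CHH) is classified on
the strand consensus with circular wraparound, reflecting the head-to-tail
tandem organization of the repeat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .diversity import WindowTrack
from .seqio import ConsensusProfile, MonomerAlignment, SeqRecord, reverse_complement

__all__ = [
    "BisulfiteRead",
    "MethylationCall",
    "ContextSummary",
    "ReadRejected",
    "bisulfite_align",
    "classify_context",
    "call_methylation",
    "summarize_by_context",
    "estimate_conversion_efficiency",
    "sliding_window_methylation",
    "correlate_tracks",
]

STRANDS = ("direct", "complementary")
CONTEXTS = ("CG", "CHG", "CHH")


class ReadRejected(ValueError):
    """A bisulfite read failed alignment QC; the message carries the reason."""


@dataclass(frozen=True)
class BisulfiteRead:
    """A cloned, bisulfite-converted monomer sequence.

    ``primer_mask`` lists 1-based inclusive intervals (in read coordinates)
    derived from PCR primers; masked positions never contribute evidence.
    """

    id: str
    sequence: str
    strand: str
    fragment_class: str = "internal"
    primer_mask: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"read {self.id!r}: unknown strand {self.strand!r}")
        if self.fragment_class not in ("external", "internal"):
            raise ValueError(
                f"read {self.id!r}: unknown fragment class {self.fragment_class!r}"
            )
        for start, end in self.primer_mask:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(f"read {self.id!r}: mask ({start},{end}) out of bounds")

    def masked_positions(self) -> set[int]:
        out: set[int] = set()
        for start, end in self.primer_mask:
            out.update(range(start, end + 1))
        return out

    def unmasked_length(self) -> int:
        return len(self.sequence) - len(self.masked_positions())


@dataclass(frozen=True)
class MethylationCall:
    """Normalized methylation estimate at one monomer position and strand.

    ``position`` is 1-based on the direct-strand monomer regardless of strand.
    ``m_normalized`` is NaN when the position lacks coverage or a usable
    native denominator; values that exceeded 1 by sampling noise are clamped
    to 1 with ``clamped=True``.  With the optional incomplete-conversion
    correction the estimate may dip slightly below 0 at unmethylated
    positions; it is left uncensored so position averages stay unbiased.
    """

    position: int
    strand: str
    context: str
    n_reads: int
    bis_C_fraction: float
    native_C_fraction: float
    native_CT_fraction: float
    m_normalized: float
    clamped: bool = False


@dataclass(frozen=True)
class ContextSummary:
    """Per (context x strand) mean methylation with observation weights."""

    table: pd.DataFrame  # fractions; index CG/CHG/CHH/All C, cols direct/complementary/both
    weights: pd.DataFrame

    def percent(self) -> pd.DataFrame:
        return self.table * 100.0

    def to_tsv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.percent().to_csv(path, sep="\t", float_format="%.2f", na_rep="NA")


def classify_context(seq: str, pos: int, circular: bool = True) -> str:
    """Cytosine context at 1-based `pos` of a strand sequence.

    Returns ``CG`` when the next base is G, ``CHG`` when the base two ahead is
    G, ``CHH`` otherwise (H = A, C or T), or ``non_C`` when the base itself is
    not a cytosine.  With ``circular=True`` successor positions wrap modulo
    the sequence length (tandem-array context).  An N among the needed
    successors yields ``CHH_unresolved``, which summaries exclude.
    """
    n = len(seq)
    if not 1 <= pos <= n:
        raise ValueError(f"position {pos} outside sequence of length {n}")
    if seq[pos - 1] != "C":
        return "non_C"

    def base_at(i: int) -> str | None:
        if 1 <= i <= n:
            return seq[i - 1]
        if circular:
            return seq[(i - 1) % n]
        return None

    nxt, nxt2 = base_at(pos + 1), base_at(pos + 2)
    if nxt is None or nxt == "N":
        return "CHH_unresolved"
    if nxt == "G":
        return "CG"
    if nxt2 is None or nxt2 == "N":
        return "CHH_unresolved"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def _bisulfite_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet="ACGTN-", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = 1.0 if a == b else -1.0
    m["C", "T"] = 1.0  # reference C read as T: converted cytosine, a match
    for x in "ACGTN-":
        m["N", x] = m[x, "N"] = 0.0
        m["-", x] = m[x, "-"] = -1.0
    return m


_BIS_MATRIX = _bisulfite_matrix()


def _bisulfite_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BIS_MATRIX
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    # free end gaps on both sides (reads may be shorter than the reference)
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def bisulfite_align(
    read: BisulfiteRead,
    consensus: ConsensusProfile | str,
    min_identity: float = 0.70,
) -> dict[int, int]:
    """Map read positions onto strand-local monomer coordinates.

    The read is globally aligned (free end gaps) against the strand-appropriate
    consensus — the reverse complement for complementary-strand reads — under a
    scoring scheme in which read-T against reference-C is a match.  The result
    maps each aligned, unmasked 1-based read position to the 1-based coordinate
    of the strand reference.  Reads shorter than 50 bp after primer masking, or
    below `min_identity` bisulfite-aware identity, are rejected.
    """
    ref = consensus.consensus if isinstance(consensus, ConsensusProfile) else consensus
    if read.strand == "complementary":
        ref = reverse_complement(ref)
    ref = ref.replace("-", "N")  # consensus gap columns carry no base identity

    if read.unmasked_length() <= 50:
        raise ReadRejected(
            f"read {read.id!r}: only {read.unmasked_length()} bp after masking"
        )
    aln = _bisulfite_aligner().align(ref, read.sequence)[0]
    masked = read.masked_positions()
    mapping: dict[int, int] = {}
    matches = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for t, q in zip(range(t0, t1), range(q0, q1)):
            rb, qb = ref[t], read.sequence[q]
            if rb == qb or (rb == "C" and qb == "T") or "N" in (rb, qb):
                matches += 1
            if (q + 1) not in masked:
                mapping[q + 1] = t + 1
    # denominator = full read length so unaligned overhangs count against it
    identity = matches / len(read.sequence)
    if identity < min_identity:
        raise ReadRejected(
            f"read {read.id!r}: bisulfite-aware identity {identity:.2f} < {min_identity}"
        )
    return mapping


def _column_fractions(aln: MonomerAlignment, pos: int) -> tuple[float, float]:
    """(native_C_fraction, native_CT_fraction) at a strand-local column."""
    col = aln.column(pos)
    counts = {b: col.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        return float("nan"), float("nan")
    return counts["C"] / total, (counts["C"] + counts["T"]) / total


def call_methylation(
    native: MonomerAlignment,
    reads: Iterable[BisulfiteRead],
    consensus: ConsensusProfile,
    normalization: str = "ct",
    conversion_efficiency: float | None = None,
    min_identity: float = 0.70,
) -> list[MethylationCall]:
    """Per-position, per-strand normalized methylation estimates.

    For every monomer position whose native column carries any C or T on the
    given strand, the fraction of mapped reads retaining C is divided by the
    native C+T fraction (``normalization="ct"``, the mutation-bias correction)
    or by the native C fraction (``normalization="c_only"``).  When
    `conversion_efficiency` e is given, incomplete-conversion background is
    removed via m = (m_raw - (1 - e)) / e before clamping.  Reads failing
    alignment QC are skipped with a warning.
    """
    if normalization not in ("ct", "c_only"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if conversion_efficiency is not None and not 0 < conversion_efficiency <= 1:
        raise ValueError("conversion efficiency must be in (0, 1]")

    reads = list(reads)
    width = consensus.width
    calls: list[MethylationCall] = []
    for strand in STRANDS:
        strand_native = native if strand == "direct" else native.reverse_complement()
        strand_ref = (
            consensus.consensus
            if strand == "direct"
            else reverse_complement(consensus.consensus)
        )
        cover = np.zeros(width + 1, dtype=int)  # 1-based strand-local coords
        c_count = np.zeros(width + 1, dtype=int)
        for read in reads:
            if read.strand != strand:
                continue
            try:
                mapping = bisulfite_align(read, consensus, min_identity=min_identity)
            except ReadRejected as exc:
                warnings.warn(str(exc), stacklevel=2)
                continue
            for read_pos, ref_pos in mapping.items():
                if ref_pos > width:
                    continue
                cover[ref_pos] += 1
                if read.sequence[read_pos - 1] == "C":
                    c_count[ref_pos] += 1

        for pos in range(1, width + 1):
            native_c, native_ct = _column_fractions(strand_native, pos)
            if not (native_ct > 0):
                continue
            context = classify_context(strand_ref, pos, circular=True)
            n = int(cover[pos])
            clamped = False
            if n == 0:
                bis_c = m = float("nan")
            else:
                bis_c = c_count[pos] / n
                denom = native_ct if normalization == "ct" else native_c
                if denom > 0:
                    m = bis_c / denom
                    if conversion_efficiency is not None:
                        # background subtraction; small negatives are kept so
                        # that averaging across positions stays unbiased
                        m = (m - (1.0 - conversion_efficiency)) / conversion_efficiency
                    if m > 1.0:
                        m, clamped = 1.0, True
                else:
                    m = float("nan")
            monomer_pos = pos if strand == "direct" else width - pos + 1
            calls.append(
                MethylationCall(
                    position=monomer_pos,
                    strand=strand,
                    context=context,
                    n_reads=n,
                    bis_C_fraction=bis_c,
                    native_C_fraction=native_c,
                    native_CT_fraction=native_ct,
                    m_normalized=m,
                    clamped=clamped,
                )
            )
    return calls


def calls_to_frame(calls: Sequence[MethylationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [c.position for c in calls],
            "strand": [c.strand for c in calls],
            "context": [c.context for c in calls],
            "n_reads": [c.n_reads for c in calls],
            "bis_C": [c.bis_C_fraction for c in calls],
            "native_C": [c.native_C_fraction for c in calls],
            "native_CT": [c.native_CT_fraction for c in calls],
            "m_normalized": [c.m_normalized for c in calls],
            "clamped": [c.clamped for c in calls],
        }
    )


def summarize_by_context(
    calls: Sequence[MethylationCall], mode: str = "observation"
) -> ContextSummary:
    """Table-1-style summary: mean methylation per context and strand.

    ``mode="observation"`` weights each position by its read count
    (methylation events / opportunities); ``mode="site"`` averages positions
    unweighted.  The "All C" row pools the three contexts; the "both" column
    pools the two strands.  Empty cells are NA.
    """
    if not calls:
        raise ValueError("no calls to summarize")
    if mode not in ("observation", "site"):
        raise ValueError(f"unknown mode {mode!r}")

    rows = list(CONTEXTS) + ["All C"]
    cols = list(STRANDS) + ["both"]
    num = pd.DataFrame(0.0, index=rows, columns=cols)
    den = pd.DataFrame(0.0, index=rows, columns=cols)
    for c in calls:
        if c.context not in CONTEXTS or c.n_reads == 0 or math.isnan(c.m_normalized):
            continue
        w = float(c.n_reads) if mode == "observation" else 1.0
        for row in (c.context, "All C"):
            for col in (c.strand, "both"):
                num.loc[row, col] += w * c.m_normalized
                den.loc[row, col] += w
    table = num / den.where(den > 0)
    return ContextSummary(table=table, weights=den)


def estimate_conversion_efficiency(
    control_reads: Iterable[BisulfiteRead],
    reference: SeqRecord,
    min_identity: float = 0.70,
) -> float:
    """Bisulfite conversion efficiency from unmethylated control reads.

    Controls derive from PCR product and carry no methylation, so every
    reference cytosine should read as T; the efficiency is the fraction of
    covered reference-C positions that did.  Primer-masked positions are
    excluded.
    """
    converted = covered = 0
    for read in control_reads:
        # bisulfite_align works in strand-local coordinates (it reverse
        # complements the reference itself for complementary-strand reads)
        strand_ref = (
            reference.sequence
            if read.strand == "direct"
            else reverse_complement(reference.sequence)
        )
        try:
            mapping = bisulfite_align(read, reference.sequence, min_identity=min_identity)
        except ReadRejected as exc:
            warnings.warn(str(exc), stacklevel=2)
            continue
        for read_pos, ref_pos in mapping.items():
            if strand_ref[ref_pos - 1] != "C":
                continue
            covered += 1
            if read.sequence[read_pos - 1] == "T":
                converted += 1
    if covered == 0:
        raise ValueError("control reads cover no reference cytosines")
    return converted / covered


def sliding_window_methylation(
    calls: Sequence[MethylationCall],
    window: int = 10,
    step: int = 1,
    strand: str = "direct",
    width: int | None = None,
) -> WindowTrack:
    """Observation-weighted sliding-window methylation track.

    Each window's value is sum(n_reads * m) / sum(n_reads) over C-capable
    positions (context CG/CHG/CHH) inside it; windows without any covered
    C-capable position are NaN.  ``strand`` may be ``direct``,
    ``complementary`` or ``both`` (pooling observations from both strands at
    shared monomer coordinates).
    """
    wanted = STRANDS if strand == "both" else (strand,)
    use = [
        c
        for c in calls
        if c.strand in wanted
        and c.context in CONTEXTS
        and c.n_reads > 0
        and not math.isnan(c.m_normalized)
    ]
    if not use:
        raise ValueError(f"no usable calls for strand {strand!r}")
    if width is None:
        width = max(c.position for c in calls)
    num = np.zeros(width + 1)
    den = np.zeros(width + 1)
    for c in use:
        num[c.position] += c.n_reads * c.m_normalized
        den[c.position] += c.n_reads
    starts, values = [], []
    for start in range(1, width - window + 2, step):
        n = num[start : start + window].sum()
        d = den[start : start + window].sum()
        starts.append(start)
        values.append(n / d if d > 0 else float("nan"))
    return WindowTrack(window, step, tuple(starts), tuple(values))


def correlate_tracks(
    meth: WindowTrack | Sequence[float],
    pi: WindowTrack | Sequence[float],
    method: str = "t",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman correlation between a methylation and a diversity track.

    Pairs with a NaN in either series are dropped; at least 5 pairs are
    required.  ``method="t"`` uses the large-sample t approximation,
    ``method="permutation"`` a seeded exact-style permutation test.  Constant
    series yield (nan, nan).
    """
    x = np.asarray(meth.values if isinstance(meth, WindowTrack) else meth, dtype=float)
    y = np.asarray(pi.values if isinstance(pi, WindowTrack) else pi, dtype=float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")

    rho, p_t = stats.spearmanr(x, y)
    if method == "t":
        return float(rho), float(p_t)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ry)
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            hits += 1
    return float(rho), (hits + 1) / (n_permutations + 1)
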