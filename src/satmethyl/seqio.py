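"""Sequence records, FASTA I/O, monomer-alignment handling and consensus derivation.

The unit of analysis is the satellite monomer: a short (~315 bp) tandem-repeat
unit cloned and sequenced many times per species.  Monomer collections are kept
as equal-width alignments so that per-column statistics (consensus, diversity,
methylation denominators) share a single coordinate system.  All coordinates
exposed to users are 1-based inclusive on the monomer; BED export converts to
0-based half-open.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

ALPHABET = set("ACGTN-")
BASES = "ACGT-"

__all__ = [
    "SeqRecord",
    "MonomerAlignment",
    "ConsensusProfile",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_sample_sheet",
    "enforce_alignment",
    "build_consensus",
    "gc_content",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N,-} alphabet (gaps preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class SeqRecord:
    """A single monomer (or read) sequence with a species label.

    The species is parsed from the record-ID prefix before the first
    underscore (``SSU_m01`` -> species ``SSU``) unless given explicitly.
    """

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}"
            )
        if not self.species:
            object.__setattr__(self, "species", self.id.split("_", 1)[0])

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def reverse_complement(self) -> "SeqRecord":
        return SeqRecord(self.id, reverse_complement(self.sequence), self.species)


@dataclass(frozen=True)
class MonomerAlignment:
    """An equal-width collection of monomer sequences."""

    records: tuple[SeqRecord, ...]
    width: int = field(default=0)

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment needs at least one record")
        widths = {len(r) for r in self.records}
        if len(widths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(widths)}")
        object.__setattr__(self, "width", widths.pop())
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate record IDs: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def column(self, pos: int) -> str:
        """Column at 1-based position `pos` as a string, one char per record."""
        return "".join(r.sequence[pos - 1] for r in self.records)

    def subset_species(self, species: str) -> "MonomerAlignment":
        kept = tuple(r for r in self.records if r.species == species)
        if not kept:
            raise ValueError(f"no records for species {species!r}")
        return MonomerAlignment(kept)

    def reverse_complement(self) -> "MonomerAlignment":
        return MonomerAlignment(tuple(r.reverse_complement() for r in self.records))

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species)
        return list(seen)


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-column base frequencies plus a majority-rule consensus string.

    ``freqs`` is a (width, 5) array over the ordering A,C,G,T,-; each row sums
    to 1.  N bases are excluded from the denominators.
    """

    width: int
    freqs: np.ndarray
    consensus: str

    def __post_init__(self):
        if self.freqs.shape != (self.width, 5):
            raise ValueError("frequency matrix shape mismatch")
        if len(self.consensus) != self.width:
            raise ValueError("consensus length mismatch")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (multi-)FASTA file into records.

    Sequences are upper-cased and U is mapped to T.  Raises
    :class:`FastaParseError` for malformed input (naming the offending line)
    and for duplicate IDs.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    text = path.read_text()
    # light structural validation so errors can name the line
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            continue
        bad = set(stripped.upper().replace("U", "T")) - ALPHABET
        if bad:
            raise FastaParseError(
                f"{path}:{lineno}: invalid sequence characters {sorted(bad)!r}"
            )
    first = next((l for l in text.splitlines() if l.strip()), None)
    if first is None:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
        return []
    if not first.lstrip().startswith(">"):
        raise FastaParseError(f"{path}:1: expected '>' header, got {first[:30]!r}")

    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record ID {rec.id!r}")
        seen.add(rec.id)
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(SeqRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at `width` columns."""
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_sample_sheet(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a TSV sample sheet keyed by record id.

    Expected header columns: ``id`` plus any of ``species``, ``strand``,
    ``fragment_class``, ``primer_mask`` (comma-separated 1-based
    ``start-end`` intervals).
    """
    import csv

    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValueError(f"{path}: sample sheet must have an 'id' column")
        for row in reader:
            out[row["id"]] = {k: v for k, v in row.items() if k != "id" and v}
    return out


def _edit_aligner() -> Align.PairwiseAligner:
    # linear (non-affine) gap cost; gaps cost more than a mismatch so the
    # aligner never trades a substitution for an insertion+deletion pair
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def enforce_alignment(
    records: Sequence[SeqRecord], reference: SeqRecord | None = None
) -> MonomerAlignment:
    """Coerce monomer records into an equal-width alignment.

    Records already sharing one length pass through unchanged.  Otherwise each
    off-length record is globally aligned (unit gap cost) to the reference —
    the longest record when none is given — and the induced gap columns are
    merged across the collection.  A record whose length differs from the
    reference by more than 20% is rejected as not belonging to the monomer
    family.  The operation is idempotent.
    """
    if not records:
        raise ValueError("no records to align")
    widths = {len(r) for r in records}
    if len(widths) == 1:
        return MonomerAlignment(tuple(records))

    ref = reference or max(records, key=len)
    ref_seq = ref.ungapped()
    for r in records:
        if abs(len(r.ungapped()) - len(ref_seq)) > 0.2 * len(ref_seq):
            raise ValueError(
                f"record {r.id!r} length {len(r.ungapped())} differs from the "
                f"reference ({len(ref_seq)} bp) by more than 20%"
            )

    aligner = _edit_aligner()
    # Pairwise-align each record to the ungapped reference, then merge the
    # insertions each alignment induces in reference coordinates.
    pairwise: list[tuple[str, str]] = []  # (aligned_ref, aligned_seq)
    for r in records:
        aln = aligner.align(ref_seq, r.ungapped())[0]
        a, b = str(aln[0]), str(aln[1])
        pairwise.append((a, b))

    # max insertion length after each reference position (0 = before first)
    inserts: Counter[int] = Counter()
    for a, _ in pairwise:
        pos, run = 0, 0
        for ch in a:
            if ch == "-":
                run += 1
            else:
                if run:
                    inserts[pos] = max(inserts[pos], run)
                    run = 0
                pos += 1
        if run:
            inserts[pos] = max(inserts[pos], run)

    merged: list[SeqRecord] = []
    for (a, b), rec in zip(pairwise, records):
        out: list[str] = []
        pos, run_chars = 0, []
        pending: list[str] = []

        def flush(pos: int, pending: list[str]) -> None:
            pad = inserts.get(pos, 0) - len(pending)
            out.extend(pending)
            out.append("-" * pad)
            pending.clear()

        for ra, rb in zip(a, b):
            if ra == "-":
                pending.append(rb)
            else:
                flush(pos, pending)
                out.append(rb)
                pos += 1
        flush(pos, pending)
        merged.append(SeqRecord(rec.id, "".join(out), rec.species))
    return MonomerAlignment(tuple(merged))


def build_consensus(
    aln: MonomerAlignment, tie_rule: str = "first_alphabetical"
) -> ConsensusProfile:
    """Majority-rule consensus with per-column base/gap frequencies.

    Gaps enter the frequency denominator; a column emits ``-`` only when the
    gap frequency is >= 0.5, otherwise the majority base among A,C,G,T is
    chosen.  Ties are broken alphabetically by default, or collapsed to an
    IUPAC ambiguity code with ``tie_rule="iupac"``.  N bases never count.
    """
    if len(aln) < 2:
        raise ValueError("consensus requires at least 2 records")
    if tie_rule not in ("first_alphabetical", "iupac"):
        raise ValueError(f"unknown tie rule {tie_rule!r}")

    iupac = {
        frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
        frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
        frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
        frozenset("CGT"): "B", frozenset("ACGT"): "N",
    }

    freqs = np.zeros((aln.width, 5))
    consensus: list[str] = []
    for pos in range(1, aln.width + 1):
        col = aln.column(pos)
        counts = Counter(ch for ch in col if ch != "N")
        total = sum(counts.values())
        if total == 0 or set(counts) == {"-"}:
            if total:
                freqs[pos - 1, 4] = 1.0
            warnings.warn(f"column {pos}: gaps only, consensus '-'", stacklevel=2)
            consensus.append("-")
            continue
        for i, base in enumerate(BASES):
            freqs[pos - 1, i] = counts.get(base, 0) / total
        if counts.get("-", 0) / total >= 0.5:
            consensus.append("-")
            continue
        base_counts = {b: counts.get(b, 0) for b in "ACGT"}
        best = max(base_counts.values())
        winners = sorted(b for b, c in base_counts.items() if c == best)
        if len(winners) == 1 or tie_rule == "first_alphabetical":
            consensus.append(winners[0])
        else:
            consensus.append(iupac[frozenset(winners)])
    return ConsensusProfile(aln.width, freqs, "".join(consensus))


def gc_content(records: SeqRecord | Iterable[SeqRecord]) -> float:
    """Fraction (G+C)/(A+C+G+T) pooled over records; gaps and N excluded."""
    if isinstance(records, SeqRecord):
        records = [records]
    gc = at = 0
    for r in records:
        c = Counter(r.sequence)
        gc += c.get("G", 0) + c.get("C", 0)
        at += c.get("A", 0) + c.get("T", 0)
    if gc + at == 0:
        raise ValueError("no non-gap bases in input")
    return gc / (gc + at)
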