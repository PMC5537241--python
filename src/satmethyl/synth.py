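"""Synthetic satellite families, methylation states and bisulfite clone sets.

The generator emulates the data a monomer-cloning + bisulfite-cloning study
produces: a ~315 bp monomer family diverged from a common ancestral repeat by
independent per-site substitutions (intraspecific Pi around 0.03 at the
default rate), occasional single-base deletions, per-context cytosine
methylation at rates of a few percent (CG > CHH > CHG), and bisulfite
conversion that misses a small fraction of unmethylated cytosines
(efficiency ~0.987).  Every operation is deterministic under its seed, and
:func:`make_dataset` writes a ground-truth JSON alongside the FASTA inputs so
recovery tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .digestor import TandemArray
from .methylation import BisulfiteRead, classify_context
from .seqio import MonomerAlignment, SeqRecord, reverse_complement, write_fasta

__all__ = [
    "FamilyConfig",
    "MethylationConfig",
    "generate_family",
    "assign_methylation",
    "bisulfite_convert",
    "make_reads",
    "make_control_reads",
    "make_dataset",
    "tandem_array",
]



@dataclass(frozen=True)
class FamilyConfig:
    """Parameters of a simulated satellite monomer family.

    ``blocks`` modulate the per-site substitution probability multiplicatively
    inside 1-based inclusive intervals: conserved blocks reduce it (factor
    ``conserved_factor``), variable blocks raise it (``variable_factor``),
    mimicking the conserved/variable mosaic real monomers show.  Indels are
    modelled as at most one single-base deletion per monomer, so the family
    alignment keeps the ancestral width.
    """

    monomer_length: int = 315
    n_monomers: dict[str, int] = field(default_factory=lambda: {"SSU": 39})
    per_site_substitution_prob: float | dict[str, float] = 0.015
    indel_prob: float = 0.025
    gc_target: float = 0.4405
    conserved_blocks: tuple[tuple[int, int], ...] = ()
    conserved_factor: float = 0.1
    variable_blocks: tuple[tuple[int, int], ...] = ()
    variable_factor: float = 4.0
    transition_bias: float = 1.0  # relative weight of the transition vs each transversion
    # motifs written into the ancestral repeat at 1-based positions before
    # divergence (e.g. restriction sites the real monomer is known to carry);
    # with exclusive_motifs, chance occurrences of the same motifs elsewhere
    # in the ancestral are disrupted so planted copies are the only ones
    ancestral_motifs: tuple[tuple[int, str], ...] = ()
    exclusive_motifs: bool = False
    # exact_composition shuffles a fixed base multiset at the G+C target
    # instead of drawing each base independently (no compositional noise)
    exact_composition: bool = False
    seed: int = 0

    def rate_for(self, species: str) -> float:
        if isinstance(self.per_site_substitution_prob, dict):
            return self.per_site_substitution_prob[species]
        return self.per_site_substitution_prob

    def site_factor(self, pos: int) -> float:
        for start, end in self.conserved_blocks:
            if start <= pos <= end:
                return self.conserved_factor
        for start, end in self.variable_blocks:
            if start <= pos <= end:
                return self.variable_factor
        return 1.0

    def validate(self) -> None:
        for p in ([self.indel_prob, self.gc_target]
                  + ([self.per_site_substitution_prob]
                     if isinstance(self.per_site_substitution_prob, float)
                     else list(self.per_site_substitution_prob.values()))):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0,1]")
        for start, end in self.conserved_blocks + self.variable_blocks:
            if not 1 <= start <= end <= self.monomer_length:
                raise ValueError(f"block ({start},{end}) outside monomer")
        for pos, motif in self.ancestral_motifs:
            if set(motif) - set("ACGT") or not 1 <= pos <= self.monomer_length - len(motif) + 1:
                raise ValueError(f"motif {motif!r} at {pos} invalid")


@dataclass(frozen=True)
class MethylationConfig:
    """Per-context methylation rates and bisulfite-conversion parameters.

    Default rates are a few percent with CG > CHH > CHG; ``hot_blocks`` get a
    multiplicative elevation (default x3).  ``strand_symmetric`` applies the
    same rates to both strands (independent draws per strand — hemimethylated
    sites therefore occur); when False only the direct strand is methylated.
    ``over_conversion`` is the probability a *methylated* C is wrongly
    converted (0 by default).
    """

    rates: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.0565, "CHG": 0.0179, "CHH": 0.0269}
    )
    strand_symmetric: bool = True
    hot_blocks: tuple[tuple[int, int], ...] = ()
    hot_multiplier: float = 3.0
    conversion_efficiency: float = 0.987
    over_conversion: float = 0.0
    n_reads_direct: int = 33
    n_reads_complementary: int = 26
    seed: int = 0

    def rate_at(self, context: str, pos: int) -> float:
        rate = self.rates.get(context, 0.0)
        for start, end in self.hot_blocks:
            if start <= pos <= end:
                return min(1.0, rate * self.hot_multiplier)
        return rate

    def validate(self) -> None:
        for r in self.rates.values():
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0,1]")
        if not 0 < self.conversion_efficiency <= 1:
            raise ValueError("conversion efficiency must be in (0,1]")


def _random_sequence(
    rng: np.random.Generator, length: int, gc: float, exact: bool = False
) -> str:
    if exact:
        n_g = int(round(length * gc / 2))
        n_c = int(round(length * gc)) - n_g
        n_a = (length - n_g - n_c + 1) // 2
        pool = list("G" * n_g + "C" * n_c + "A" * n_a + "T" * (length - n_g - n_c - n_a))
        return "".join(rng.permutation(pool))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def generate_family(cfg: FamilyConfig) -> tuple[SeqRecord, MonomerAlignment]:
    """Simulate a monomer family: (ancestral sequence, aligned monomers).

    Each monomer derives from the ancestral repeat by independent per-site
    substitution (uniform among the three alternatives unless
    ``transition_bias`` != 1) at the species rate scaled by the site's block
    factor, plus at most one single-base deletion with probability
    ``indel_prob``.  Deletions appear as ``-`` in the alignment, keeping the
    ancestral width.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    anc_seq = list(
        _random_sequence(rng, cfg.monomer_length, cfg.gc_target, cfg.exact_composition)
    )
    for pos, motif in cfg.ancestral_motifs:
        anc_seq[pos - 1 : pos - 1 + len(motif)] = motif
    if cfg.exclusive_motifs and cfg.ancestral_motifs:
        planted = {
            i
            for pos, motif in cfg.ancestral_motifs
            for i in range(pos - 1, pos - 1 + len(motif))
        }
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for _ in range(10):  # re-scan: a fix could create a new match
            dirty = False
            s = "".join(anc_seq)
            for _, motif in cfg.ancestral_motifs:
                start = s.find(motif)
                while start != -1:
                    span = range(start, start + len(motif))
                    if not all(i in planted for i in span):
                        flip = next(i for i in span if i not in planted)
                        anc_seq[flip] = transition[anc_seq[flip]]
                        dirty = True
                    start = s.find(motif, start + 1)
            if not dirty:
                break
    ancestral = SeqRecord("ancestral_ref", "".join(anc_seq))

    # bases as ints A=0 C=1 G=2 T=3: transition partner is b^2, the two
    # transversions are b^1 and b^3
    lut = {b: i for i, b in enumerate("ACGT")}
    anc_int = np.array([lut[b] for b in ancestral.sequence], dtype=np.int8)
    site_factors = np.array(
        [cfg.site_factor(p) for p in range(1, cfg.monomer_length + 1)]
    )
    p_transition = cfg.transition_bias / (cfg.transition_bias + 2.0)

    records: list[SeqRecord] = []
    for species in sorted(cfg.n_monomers):
        site_rates = np.minimum(cfg.rate_for(species) * site_factors, 1.0)
        for i in range(cfg.n_monomers[species]):
            seq_int = anc_int.copy()
            hit = rng.random(cfg.monomer_length) < site_rates
            if hit.any():
                b = seq_int[hit]
                r = rng.random(int(hit.sum()))
                mutated = np.where(
                    r < p_transition,
                    b ^ 2,
                    np.where(r < (1 + p_transition) / 2, b ^ 1, b ^ 3),
                )
                seq_int[hit] = mutated
            seq = [("ACGT")[v] for v in seq_int]
            if rng.random() < cfg.indel_prob:
                seq[rng.integers(0, cfg.monomer_length)] = "-"
            records.append(SeqRecord(f"{species}_m{i + 1:02d}", "".join(seq), species))
    return ancestral, MonomerAlignment(tuple(records))


def assign_methylation(
    monomers: MonomerAlignment, mcfg: MethylationConfig, rng: np.random.Generator | None = None
) -> dict[str, frozenset]:
    """Per-molecule methylation maps: id -> {(position, strand), ...}.

    Positions are 1-based on the ungapped molecule (direct-strand
    coordinates); a complementary-strand methylated C is recorded at the
    coordinate of its paired direct-strand G.  Contexts are classified on the
    molecule itself, circularly (tandem organization).
    """
    mcfg.validate()
    if rng is None:
        rng = np.random.default_rng(mcfg.seed)
    maps: dict[str, frozenset] = {}
    for rec in monomers:
        s = rec.ungapped()
        n = len(s)
        marks: set[tuple[int, str]] = set()
        for pos in range(1, n + 1):
            if s[pos - 1] == "C":
                ctx = classify_context(s, pos, circular=True)
                if rng.random() < mcfg.rate_at(ctx, pos):
                    marks.add((pos, "direct"))
        if mcfg.strand_symmetric:
            t = reverse_complement(s)
            for j in range(1, n + 1):
                if t[j - 1] == "C":
                    ctx = classify_context(t, j, circular=True)
                    direct_pos = n - j + 1
                    if rng.random() < mcfg.rate_at(ctx, direct_pos):
                        marks.add((direct_pos, "complementary"))
        maps[rec.id] = frozenset(marks)
    return maps


def bisulfite_convert(
    molecule: SeqRecord,
    methylation_map: frozenset,
    efficiency: float,
    strand: str,
    rng: np.random.Generator,
    read_id: str | None = None,
    fragment_class: str = "internal",
    over_conversion: float = 0.0,
) -> BisulfiteRead:
    """Bisulfite-convert one molecule strand into a clone read.

    Unmethylated C -> T with probability `efficiency` (a conversion failure
    leaves C); methylated C stays C unless `over_conversion` fires; other
    bases pass through.  Complementary-strand reads are produced from the
    reverse complement before conversion.
    """
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0,1]")
    s = molecule.ungapped()
    n = len(s)
    if strand == "direct":
        template = s
        methylated = {p for p, st in methylation_map if st == "direct"}
    elif strand == "complementary":
        template = reverse_complement(s)
        methylated = {n - p + 1 for p, st in methylation_map if st == "complementary"}
    else:
        raise ValueError(f"unknown strand {strand!r}")

    out = []
    for i, base in enumerate(template, start=1):
        if base != "C":
            out.append(base)
        elif i in methylated:
            out.append("T" if rng.random() < over_conversion else "C")
        else:
            out.append("T" if rng.random() < efficiency else "C")
    return BisulfiteRead(
        id=read_id or f"{molecule.id}_{strand[0]}",
        sequence="".join(out),
        strand=strand,
        fragment_class=fragment_class,
    )


def make_reads(
    monomers: MonomerAlignment,
    maps: dict[str, frozenset],
    mcfg: MethylationConfig,
    rng: np.random.Generator | None = None,
    species: str | None = None,
) -> list[BisulfiteRead]:
    """Draw bisulfite clone reads from random molecules of one species."""
    if rng is None:
        rng = np.random.default_rng(mcfg.seed + 1)
    pool = monomers.records if species is None else tuple(
        r for r in monomers if r.species == species
    )
    reads: list[BisulfiteRead] = []
    for strand, n_reads, tag in (
        ("direct", mcfg.n_reads_direct, "bsD"),
        ("complementary", mcfg.n_reads_complementary, "bsC"),
    ):
        for i in range(n_reads):
            mol = pool[rng.integers(0, len(pool))]
            reads.append(
                bisulfite_convert(
                    mol,
                    maps[mol.id],
                    mcfg.conversion_efficiency,
                    strand,
                    rng,
                    read_id=f"{tag}_r{i + 1:02d}",
                    fragment_class="external" if i % 2 == 0 else "internal",
                    over_conversion=mcfg.over_conversion,
                )
            )
    return reads


def make_control_reads(
    reference: SeqRecord,
    efficiency: float,
    n_reads: int = 30,
    seed: int = 0,
) -> list[BisulfiteRead]:
    """Unmethylated PCR-product controls for conversion-efficiency estimation."""
    rng = np.random.default_rng(seed)
    return [
        bisulfite_convert(
            reference,
            frozenset(),
            efficiency,
            "direct" if i % 2 == 0 else "complementary",
            rng,
            read_id=f"ctrl_r{i + 1:02d}",
        )
        for i in range(n_reads)
    ]


def tandem_array(
    monomers: MonomerAlignment,
    maps: dict[str, frozenset] | None = None,
    order: list[str] | None = None,
    circular: bool = False,
) -> TandemArray:
    """Concatenate molecules head-to-tail into a digestible array."""
    by_id = {r.id: r for r in monomers}
    order = order or [r.id for r in monomers]
    seq_parts: list[str] = []
    marks: set[tuple[int, str]] = set()
    offset = 0
    for mid in order:
        s = by_id[mid].ungapped()
        seq_parts.append(s)
        if maps:
            for pos, strand in maps.get(mid, frozenset()):
                marks.add((offset + pos, strand))
        offset += len(s)
    return TandemArray(tuple(order), "".join(seq_parts), frozenset(marks), circular)


def make_dataset(
    cfg: FamilyConfig,
    mcfg: MethylationConfig,
    out_dir: str | Path,
    n_control_reads: int = 30,
) -> dict[str, Path]:
    """Write a complete pipeline input set plus ground truth.

    Emits ``native.fasta`` (ungapped monomers), ``bisulfite.fasta`` (clone
    reads from the first species), ``controls.fasta`` (unmethylated
    conversion controls), ``sample_sheet.tsv`` and ``truth.json``.  Fully
    reproducible: the same configs give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ancestral, monomers = generate_family(cfg)
    maps = assign_methylation(monomers, mcfg)
    first_species = sorted(cfg.n_monomers)[0]
    reads = make_reads(monomers, maps, mcfg, species=first_species)
    controls = make_control_reads(
        ancestral, mcfg.conversion_efficiency, n_control_reads, seed=mcfg.seed + 2
    )

    paths = {
        "native": out / "native.fasta",
        "bisulfite": out / "bisulfite.fasta",
        "controls": out / "controls.fasta",
        "sample_sheet": out / "sample_sheet.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(
        [SeqRecord(r.id, r.ungapped(), r.species) for r in monomers], paths["native"]
    )
    write_fasta(
        [SeqRecord(r.id, r.sequence) for r in reads], paths["bisulfite"]
    )
    write_fasta(
        [SeqRecord(r.id, r.sequence) for r in controls], paths["controls"]
    )
    sheet_lines = ["id\tspecies\tstrand\tfragment_class"]
    for r in reads + controls:
        sheet_lines.append(f"{r.id}\t{first_species}\t{r.strand}\t{r.fragment_class}")
    paths["sample_sheet"].write_text("\n".join(sheet_lines) + "\n")

    truth = {
        "seed_family": cfg.seed,
        "seed_methylation": mcfg.seed,
        "rates": mcfg.rates,
        "hot_blocks": [list(b) for b in mcfg.hot_blocks],
        "hot_multiplier": mcfg.hot_multiplier,
        "conversion_efficiency": mcfg.conversion_efficiency,
        "conserved_blocks": [list(b) for b in cfg.conserved_blocks],
        "variable_blocks": [list(b) for b in cfg.variable_blocks],
        "ancestral": ancestral.sequence,
        "methylation_maps": {
            mid: sorted([p, s] for p, s in marks) for mid, marks in maps.items()
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return paths
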