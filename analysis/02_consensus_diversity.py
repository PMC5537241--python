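#!/usr/bin/env python
"""Consensus, nucleotide diversity, and conserved/variable segments.

Reads the simulated monomer library (analysis/01), derives the majority-rule
consensus, computes overall and per-species Pi, the 10 bp sliding-window
diversity track, and the mean +/- 2 SD segment classification.  Writes the
consensus FASTA, the window track TSV, and the segment BED/TSV under
results/diversity/.
"""

import argparse
import json
import warnings
from pathlib import Path

from satmethyl import (
    SeqRecord,
    build_consensus,
    classify_segments,
    gc_content,
    nucleotide_diversity,
    read_fasta,
    sliding_window_pi,
    write_fasta,
)
from satmethyl.seqio import enforce_alignment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    parser.add_argument("--out", type=Path, default=Path("results/diversity"))
    args = parser.parse_args()
    warnings.filterwarnings("ignore")

    aln = enforce_alignment(read_fasta(args.dataset / "native.fasta"))
    consensus = build_consensus(aln.subset_species("SSU"))
    track = sliding_window_pi(aln.subset_species("SSU"))
    segments = classify_segments(track, width=aln.width)

    args.out.mkdir(parents=True, exist_ok=True)
    write_fasta([SeqRecord("consensus", consensus.consensus)],
                args.out / "consensus.fasta")
    track.to_tsv(args.out / "pi_track.tsv")
    segments.to_bed(args.out / "segments.bed")
    segments.to_tsv(args.out / "segments.tsv")

    per_species = {
        sp: nucleotide_diversity(aln.subset_species(sp)) for sp in aln.species
    }
    report = {
        "pi_pooled": nucleotide_diversity(aln),
        "pi_per_species": per_species,
        "gc_content": gc_content(list(aln.subset_species("SSU"))),
        "track_mean": track.mean,
        "track_sd": track.sd,
        "variable_segments": segments.labelled("variable"),
        "conserved_segments": segments.labelled("conserved"),
    }
    (args.out / "diversity.json").write_text(json.dumps(report, indent=1) + "\n")

    print(f"pooled Pi = {report['pi_pooled']:.4f}; per species: "
          + ", ".join(f"{sp} {pi:.4f}" for sp, pi in per_species.items()))
    print(f"G+C = {100 * report['gc_content']:.2f}%")
    print(f"window track: mean {track.mean:.4f}, SD {track.sd:.4f}")
    print(f"variable segments (> mean+2SD): {report['variable_segments']}")
    print(f"conserved segments (< mean-2SD): {report['conserved_segments']}")
    print("note: diversity is concentrated in the planted variable regions; "
          "broad conserved domains depress the local track without crossing "
          "the two-SD line (see docs/methods.md)")


if __name__ == "__main__":
    main()
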