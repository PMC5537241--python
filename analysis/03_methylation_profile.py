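#!/usr/bin/env python
"""Bisulfite methylation profile of the simulated monomer library.

Estimates conversion efficiency from the unmethylated controls, calls
per-position methylation on both strands with the C+T mutation-bias
normalization and incomplete-conversion correction, summarizes rates by
CG/CHG/CHH context, builds 10 bp methylation tracks, and correlates them
with the diversity track.  Writes calls, the context summary, tracks, and
the correlation report under results/methylation/.
"""

import argparse
import json
import warnings
from pathlib import Path

from satmethyl import (
    SeqRecord,
    build_consensus,
    call_methylation,
    correlate_tracks,
    estimate_conversion_efficiency,
    read_fasta,
    sliding_window_methylation,
    sliding_window_pi,
    summarize_by_context,
)
from satmethyl.cli import _load_reads  # shared sample-sheet loader
from satmethyl.methylation import calls_to_frame
from satmethyl.seqio import enforce_alignment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    parser.add_argument("--out", type=Path, default=Path("results/methylation"))
    args = parser.parse_args()
    warnings.filterwarnings("ignore")

    native = enforce_alignment(
        read_fasta(args.dataset / "native.fasta")
    ).subset_species("SSU")
    consensus = build_consensus(native)
    sheet = args.dataset / "sample_sheet.tsv"
    reads = _load_reads(args.dataset / "bisulfite.fasta", sheet)
    controls = _load_reads(args.dataset / "controls.fasta", sheet)

    efficiency = estimate_conversion_efficiency(
        controls, SeqRecord("ref", consensus.consensus)
    )
    calls = call_methylation(
        native, reads, consensus, conversion_efficiency=efficiency
    )
    summary = summarize_by_context(calls)
    pi_track = sliding_window_pi(native)

    args.out.mkdir(parents=True, exist_ok=True)
    calls_to_frame(calls).to_csv(args.out / "calls.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    summary.to_tsv(args.out / "context_summary.tsv")

    correlation = {}
    for strand in ("direct", "complementary", "both"):
        track = sliding_window_methylation(
            calls, strand=strand, width=consensus.width
        )
        track.to_tsv(args.out / f"meth_track_{strand}.tsv")
        rho, p = correlate_tracks(track, pi_track)
        correlation[strand] = {"rho": rho, "p": p}
    (args.out / "correlation.json").write_text(
        json.dumps(correlation, indent=1) + "\n"
    )

    print(f"conversion efficiency (controls): {100 * efficiency:.2f}%")
    print("methylated cytosines (%), by context and strand:")
    print(summary.percent().round(2).to_string())
    for strand, c in correlation.items():
        print(f"methylation vs diversity, {strand}: "
              f"rho = {c['rho']:+.4f}, p = {c['p']:.4g}")
    print("negative correlations reflect the design: methylation hot blocks "
          "sit inside the conserved domains")


if __name__ == "__main__":
    main()
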