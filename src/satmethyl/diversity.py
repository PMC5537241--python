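"""Nucleotide diversity (Pi), sliding-window tracks, and segment classification.

Pi is the average uncorrected p-distance over all unordered sequence pairs,
with pairwise deletion of gap/N columns — the convention of the classical
population-genetics estimators for satellite monomer libraries.  The window
track slides a fixed-width window (default 10 bp, step 1) along the monomer
and a segment is called conserved or variable only where the window value
departs from the track mean by more than a configurable multiple (default 2)
of its standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqio import MonomerAlignment

__all__ = [
    "WindowTrack",
    "SegmentClassification",
    "pairwise_differences",
    "nucleotide_diversity",
    "sliding_window_pi",
    "classify_segments",
]

_MISSING = {"-", "N"}


@dataclass(frozen=True)
class WindowTrack:
    """A sliding-window scalar track over monomer coordinates (1-based starts)."""

    window_width: int
    step: int
    starts: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.starts) != len(self.values):
            raise ValueError("starts/values length mismatch")
        diffs = np.diff(self.starts)
        if len(diffs) and not np.all(diffs == self.step):
            raise ValueError("window starts must increase by the step size")

    @property
    def finite_values(self) -> np.ndarray:
        v = np.asarray(self.values, dtype=float)
        return v[np.isfinite(v)]

    @property
    def mean(self) -> float:
        return float(np.mean(self.finite_values))

    @property
    def sd(self) -> float:
        v = self.finite_values
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "start": self.starts,
                "end": [s + self.window_width - 1 for s in self.starts],
                "value": self.values,
            }
        )
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class SegmentClassification:
    """Maximal-run segments labelled conserved / variable / intermediate.

    Segments tile ``[1, width]`` (1-based inclusive) without overlap.
    """

    segments: tuple[tuple[int, int, str], ...]

    def __post_init__(self):
        prev_end = 0
        for start, end, label in self.segments:
            if start != prev_end + 1 or end < start:
                raise ValueError("segments must tile the monomer without gaps")
            if label not in ("conserved", "variable", "intermediate"):
                raise ValueError(f"unknown label {label!r}")
            prev_end = end

    def labelled(self, label: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, lab in self.segments if lab == label]

    def to_bed(self, path: str | Path, chrom: str = "monomer") -> None:
        """0-based half-open BED export."""
        lines = [
            f"{chrom}\t{s - 1}\t{e}\t{lab}" for s, e, lab in self.segments
        ]
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text("\n".join(lines) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["start\tend\tlabel"] + [
            f"{s}\t{e}\t{lab}" for s, e, lab in self.segments
        ]
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text("\n".join(lines) + "\n")


def pairwise_differences(a: str, b: str) -> tuple[int, int]:
    """(mismatches, compared_sites) between two aligned sequences.

    Columns where either sequence carries a gap or N are excluded from the
    comparison (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    mism = comp = 0
    for x, y in zip(a, b):
        if x in _MISSING or y in _MISSING:
            continue
        comp += 1
        if x != y:
            mism += 1
    return mism, comp


def _pair_cumsums(aln: MonomerAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair cumulative mismatch and comparable-site counts along columns.

    Returns (cum_mism, cum_comp), each of shape (n_pairs, width + 1) so that
    counts over columns [a, b) are ``cum[:, b] - cum[:, a]``.  Pairs follow
    ``itertools.combinations`` order.
    """
    mat = np.frombuffer(
        "".join(r.sequence for r in aln.records).encode(), dtype=np.uint8
    ).reshape(len(aln), aln.width)
    valid = (mat != ord("-")) & (mat != ord("N"))
    iu, ju = np.triu_indices(len(aln), k=1)
    both = valid[iu] & valid[ju]
    mism = (mat[iu] != mat[ju]) & both
    zero = np.zeros((len(iu), 1), dtype=np.int64)
    return (
        np.hstack([zero, np.cumsum(mism, axis=1)]),
        np.hstack([zero, np.cumsum(both, axis=1)]),
    )


def nucleotide_diversity(aln: MonomerAlignment) -> float:
    """Pi: mean uncorrected p-distance over all unordered record pairs.

    Columns with a gap or N in either member of a pair are excluded for that
    pair only (pairwise deletion); pairs sharing no comparable site are
    dropped with a warning.
    """
    if len(aln) < 2:
        raise ValueError("Pi needs at least 2 sequences")
    cum_mism, cum_comp = _pair_cumsums(aln)
    mism = cum_mism[:, -1].astype(float)
    comp = cum_comp[:, -1].astype(float)
    usable = comp > 0
    if not usable.all():
        ids = [r.id for r in aln.records]
        for k, (i, j) in enumerate(zip(*np.triu_indices(len(aln), k=1))):
            if not usable[k]:
                warnings.warn(
                    f"pair ({ids[i]}, {ids[j]}) shares no comparable sites; excluded",
                    stacklevel=2,
                )
    if not usable.any():
        raise ValueError("no comparable pairs")
    return float(np.mean(mism[usable] / comp[usable]))


def sliding_window_pi(
    aln: MonomerAlignment, window: int = 10, step: int = 1
) -> WindowTrack:
    """Pi in overlapping windows fully inside the alignment."""
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > aln.width:
        raise ValueError("window exceeds alignment width")
    cum_mism, cum_comp = _pair_cumsums(aln)
    starts, values = [], []
    for start in range(1, aln.width - window + 2, step):
        a, b = start - 1, start - 1 + window
        mism = cum_mism[:, b] - cum_mism[:, a]
        comp = cum_comp[:, b] - cum_comp[:, a]
        usable = comp > 0
        starts.append(start)
        values.append(
            float(np.mean(mism[usable] / comp[usable]))
            if usable.any()
            else float("nan")
        )
    return WindowTrack(window, step, tuple(starts), tuple(values))


def classify_segments(
    track: WindowTrack, sd_multiplier: float = 2.0, width: int | None = None
) -> SegmentClassification:
    """Label monomer positions by the mean +/- k*SD window rule.

    A window is *variable* if its value exceeds mean + k*sd and *conserved*
    if it falls below mean - k*sd; otherwise intermediate.  Window labels are
    projected onto positions — a position takes the extreme label of any
    covering window, variable winning on conflict — and maximal runs become
    segments.  With sd = 0 everything is intermediate.
    """
    if len(track.starts) < 3:
        raise ValueError("need at least 3 windows to classify")
    if width is None:
        width = track.starts[-1] + track.window_width - 1
    mean, sd = track.mean, track.sd

    labels = ["intermediate"] * width  # index 0 = position 1
    if sd > 0:
        hi, lo = mean + sd_multiplier * sd, mean - sd_multiplier * sd
        for start, value in zip(track.starts, track.values):
            if not np.isfinite(value):
                continue
            if value > hi:
                lab = "variable"
            elif value < lo:
                lab = "conserved"
            else:
                continue
            for pos in range(start, min(start + track.window_width, width + 1)):
                if lab == "variable" or labels[pos - 1] == "intermediate":
                    labels[pos - 1] = lab

    segments: list[tuple[int, int, str]] = []
    run_start = 1
    for pos in range(2, width + 1):
        if labels[pos - 1] != labels[run_start - 1]:
            segments.append((run_start, pos - 1, labels[run_start - 1]))
            run_start = pos
    segments.append((run_start, width, labels[run_start - 1]))
    return SegmentClassification(tuple(segments))
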