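"""Candidate window selection and signal-matrix assembly.

Candidate enhancers and promoters are 200 bp windows carrying an
enhancer-related (states 10-18) or promoter-related (states 1-4, 22, 23)
chromatin-state label in at least ``min_samples`` of the input
segmentations. Per-mark signal is averaged from 25 bp bins onto the window
grid and arranged as a windows × samples matrix with the group design
attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import (
    ChromatinStateSegmentation,
    GenomicWindow,
    GroupDesign,
    SignalTrack,
)

logger = logging.getLogger(__name__)

#: Chromatin states treated as enhancer-related and promoter-related.
ENHANCER_STATES = frozenset({10, 11, 12, 13, 14, 15, 16, 17, 18})
PROMOTER_STATES = frozenset({1, 2, 3, 4, 22, 23})


@dataclass(frozen=True)
class RegionClass:
    """A named set of chromatin states defining one candidate region class."""

    label: str
    state_set: frozenset[int]


ENHANCER = RegionClass("enhancer", ENHANCER_STATES)
PROMOTER = RegionClass("promoter", PROMOTER_STATES)


@dataclass
class SignalMatrix:
    """Windows × samples signal table for one mark and one region class.

    ``values[k, s]`` is the mark signal of sample ``samples[s]`` averaged
    over window ``windows[k]``. Group means are computable for every group
    in ``design``.
    """

    mark: str
    region_class: str
    windows: list[GenomicWindow]
    samples: list[str]
    values: np.ndarray
    design: GroupDesign
    _group_cols: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.windows), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.windows)}, {len(self.samples)})"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("signal matrix contains non-finite values")
        sample_idx = {s: i for i, s in enumerate(self.samples)}
        self._group_cols = {
            g: np.array([sample_idx[s] for s in self.design.samples_in(g)])
            for g in self.design.groups
        }

    @property
    def groups(self) -> list[str]:
        return self.design.groups

    def group_values(self, group: str) -> np.ndarray:
        """Windows × samples-in-group slice of the matrix."""
        return self.values[:, self._group_cols[group]]

    def restrict(self, window_mask: np.ndarray) -> "SignalMatrix":
        """New matrix keeping only windows where ``window_mask`` is True."""
        kept = [w for w, keep in zip(self.windows, window_mask) if keep]
        return SignalMatrix(
            mark=self.mark,
            region_class=self.region_class,
            windows=kept,
            samples=self.samples,
            values=self.values[np.asarray(window_mask, bool)],
            design=self.design,
        )


def compress_to_windows(track: SignalTrack, factor: int = 8,
                        truncate_tail: bool = False) -> SignalTrack:
    """Average every ``factor`` consecutive bins (25 bp → 200 bp by default).

    The mean is conserved: sum(output) * factor == sum(input) whenever the
    length divides. A trailing partial block errors unless ``truncate_tail``
    is set, in which case it is dropped and logged.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out: dict[str, np.ndarray] = {}
    for chrom, vals in track.values.items():
        n = len(vals)
        tail = n % factor
        if tail:
            if not truncate_tail:
                raise ValueError(
                    f"{chrom}: length {n} not a multiple of {factor}; "
                    "pass truncate_tail=True to drop the partial block"
                )
            logger.info("%s: dropping trailing partial block of %d bin(s)",
                        chrom, tail)
            vals = vals[: n - tail]
        out[chrom] = vals.reshape(-1, factor).mean(axis=1)
    return SignalTrack(
        sample_id=track.sample_id,
        mark=track.mark,
        resolution=track.resolution * factor,
        values=out,
    )


def select_candidate_windows(
    segmentations: list[ChromatinStateSegmentation],
    region_class: RegionClass,
    min_samples: int = 1,
) -> list[GenomicWindow]:
    """Windows labelled with a state of ``region_class`` in >= min_samples
    segmentations, sorted by (chrom, start).

    With min_samples=1 this is the union over samples of per-sample
    candidate sets.
    """
    if not segmentations:
        raise ValueError("empty segmentation list")
    counts: dict[GenomicWindow, int] = {}
    for seg in segmentations:
        for window, state in seg.records:
            if state in region_class.state_set:
                counts[window] = counts.get(window, 0) + 1
    return sorted(
        (w for w, c in counts.items() if c >= min_samples),
        key=lambda w: (w.chrom, w.start),
    )


def build_signal_matrix(
    tracks: list[SignalTrack],
    windows: list[GenomicWindow],
    design: GroupDesign,
    region_class: str = "",
) -> SignalMatrix:
    """Assemble a windows × samples matrix from per-sample tracks.

    Tracks must already be at window resolution. Samples are ordered
    canonically (sorted ids) regardless of input order; a window beyond the
    end of a track reads as 0 (gap rule), logged once per track.
    """
    by_sample = {t.sample_id: t for t in tracks}
    marks = {t.mark for t in tracks}
    if len(marks) > 1:
        raise ValueError(f"tracks mix marks {sorted(marks)}")
    missing = [s for s in design.samples if s not in by_sample]
    if missing:
        raise ValueError(f"samples missing a track: {missing}")
    samples = design.samples
    values = np.zeros((len(windows), len(samples)))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {w.chrom for w in windows}:
        rows = np.array([k for k, w in enumerate(windows) if w.chrom == chrom])
        starts = np.array([windows[k].start for k in rows])
        by_chrom[chrom] = (rows, starts)
    for j, sample in enumerate(samples):
        track = by_sample[sample]
        n_off = 0
        for chrom, (rows, starts) in by_chrom.items():
            arr = track.values.get(chrom)
            idx = starts // track.resolution
            if arr is None:
                n_off += len(rows)
                continue
            inside = idx < len(arr)
            values[rows[inside], j] = arr[idx[inside]]
            n_off += int((~inside).sum())
        if n_off:
            logger.warning("%s: %d window(s) outside track, filled with 0",
                           sample, n_off)
    return SignalMatrix(
        mark=marks.pop() if marks else "",
        region_class=region_class,
        windows=list(windows),
        samples=samples,
        values=values,
        design=design,
    )


def matrix_to_frame(matrix: SignalMatrix):
    """Export a SignalMatrix as a DataFrame (chrom/start/end + sample cols)."""
    import pandas as pd

    df = pd.DataFrame(matrix.values, columns=matrix.samples)
    df.insert(0, "chrom", [w.chrom for w in matrix.windows])
    df.insert(1, "start", [w.start for w in matrix.windows])
    df.insert(2, "end", [w.end for w in matrix.windows])
    return df
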