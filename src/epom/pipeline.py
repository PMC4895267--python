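"""End-to-end composition of the three-step procedure.

Ties the stages together: candidate selection from segmentations, matrix
assembly per mark, association testing, combination across marks, and the
EPOM score matrix. Used by the CLI, the examples and the recovery tests;
each stage remains independently callable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assoc import (
    AssociationResult,
    TestingThresholds,
    associate,
    combine_marks,
)
from .io import ChromatinStateSegmentation, GroupDesign, SignalTrack
from .overlap import EPOMMatrix, epom_matrix
from .prep import (
    ENHANCER,
    PROMOTER,
    RegionClass,
    SignalMatrix,
    build_signal_matrix,
    compress_to_windows,
    select_candidate_windows,
)


@dataclass
class PipelineResult:
    region_class: str
    candidates: list
    per_mark: dict[str, AssociationResult]
    combined: AssociationResult
    matrix: EPOMMatrix | None


def run_region_class(
    segmentations: list[ChromatinStateSegmentation],
    tracks: dict[str, dict[str, SignalTrack]],
    design: GroupDesign,
    region_class: RegionClass,
    thresholds: TestingThresholds | None = None,
    combine_mode: str = "union",
    min_samples: int = 1,
    window_size: int = 200,
) -> PipelineResult:
    """Run candidate selection → association → EPOM for one region class.

    ``tracks`` maps mark → sample → SignalTrack; tracks at finer than
    window resolution are averaged up first.
    """
    thresholds = thresholds or TestingThresholds()
    candidates = select_candidate_windows(segmentations, region_class,
                                          min_samples=min_samples)
    per_mark: dict[str, AssociationResult] = {}
    for mark, per_sample in tracks.items():
        prepared = []
        for track in per_sample.values():
            if track.resolution < window_size:
                track = compress_to_windows(
                    track, window_size // track.resolution)
            prepared.append(track)
        matrix = build_signal_matrix(prepared, candidates, design,
                                     region_class=region_class.label)
        per_mark[mark] = associate(matrix, thresholds)
    combined = (combine_marks(list(per_mark.values()), combine_mode)
                if len(per_mark) > 1 else next(iter(per_mark.values())))
    matrix_result = None
    if len(combined.groups) >= 2 and combined.population():
        matrix_result = epom_matrix(combined)
    return PipelineResult(
        region_class=region_class.label,
        candidates=candidates,
        per_mark=per_mark,
        combined=combined,
        matrix=matrix_result,
    )


def run_both_classes(segmentations, tracks, design,
                     thresholds=None, combine_mode="union",
                     min_samples=1, window_size=200
                     ) -> dict[str, PipelineResult]:
    """Run the full procedure for enhancers and promoters."""
    return {
        rc.label: run_region_class(
            segmentations, tracks, design, rc,
            thresholds=thresholds, combine_mode=combine_mode,
            min_samples=min_samples, window_size=window_size,
        )
        for rc in (ENHANCER, PROMOTER)
    }
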