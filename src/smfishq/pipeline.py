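"""End-to-end orchestration: simulate (or load) a position, detect spots,
build the single-molecule reference, find transcription sites, assemble
per-cell records, and aggregate a cohort.

The batch convention mirrors interactive single-position tuning followed by
batch processing: detection settings (including the intensity bounds refined
on the single-molecule intensity histogram) are established once, then
applied identically to every position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ImageStack, DetectionSettings, CellOutline
from .simulate import Scene, ScenarioParams, sample_scene, render_stack, scene_outlines
from .detect import SpotTable, detect_spots, suggest_threshold
from .average import average_molecule, reference_intensity
from .ts import TSRecord, find_ts
from .cells import CellRecord, ScoringThresholds, build_cell_records
from .report import SummaryTable, summarize_cells

__all__ = ["PositionResult", "analyze_position", "run_synthetic_cohort", "refine_q_bounds"]


@dataclass
class PositionResult:
    position_id: str
    table: SpotTable
    Q_ref: float
    ts_records: list[TSRecord]
    records: list[CellRecord]
    unassigned: list


def refine_q_bounds(table: SpotTable, width: float = 0.5) -> DetectionSettings:
    """Set the single-molecule intensity window to ``[1-width, 1+width]`` times
    the median accepted Q — the batch equivalent of refining the min/max
    intensity cursors on the histogram.  Doublets and transcription sites
    fall above the window; dim spurious fits below."""
    qs = np.array([s.Q for s in table.accepted])
    if qs.size == 0:
        return table.settings
    med = float(np.median(qs))
    return replace(table.settings, accept_Q=((1 - width) * med, (1 + width) * med))


def analyze_position(
    fish: ImageStack,
    outlines: list[CellOutline],
    settings: DetectionSettings,
    if_stack: ImageStack | None = None,
    ref_mode: str = "robust",
    refine_bounds: bool = True,
    thresholds: ScoringThresholds = ScoringThresholds(),
    manual_groups: dict[str, str] | None = None,
) -> PositionResult:
    """Analyze one stage position end to end."""
    table = detect_spots(fish, settings)
    if refine_bounds and table.accepted:
        from .detect import filter_spots

        table = filter_spots(table, refine_q_bounds(table))
    if table.accepted:
        avg = average_molecule(fish, table)
        q_ref = reference_intensity(avg, mode=ref_mode)
    else:
        q_ref = float("nan")
    ts_records = find_ts(table, outlines, q_ref, table.settings) if np.isfinite(q_ref) else []
    records, unassigned = build_cell_records(
        table, ts_records, outlines, if_stack=if_stack, thresholds=thresholds,
        manual_groups=manual_groups, Q_ref=q_ref if np.isfinite(q_ref) else None,
    )
    return PositionResult(fish.position_id, table, q_ref, ts_records, records, unassigned)


def run_synthetic_cohort(
    n_positions: int,
    params: ScenarioParams,
    settings: DetectionSettings | None = None,
    with_if: bool = True,
    seed: int | None = None,
) -> tuple[list[PositionResult], list[Scene]]:
    """Simulate and analyze ``n_positions`` independent fields with shared
    detection settings (the batch-processing scenario).  Per-position seeds
    are derived from ``seed`` (default ``params.seed``)."""
    base_seed = params.seed if seed is None else seed
    settings = settings or DetectionSettings(voxel_size=params.voxel_size)
    results: list[PositionResult] = []
    scenes: list[Scene] = []
    for i in range(n_positions):
        p = replace(params, seed=(base_seed + 7919 * i) % (2**31 - 1))
        scene = sample_scene(p, position_id=f"pos_{i:02d}")
        fish = render_stack(scene, "FISH")
        if_stack = render_stack(scene, "IF") if with_if else None
        outlines = scene_outlines(scene)
        results.append(analyze_position(fish, outlines, settings, if_stack=if_stack))
        scenes.append(scene)
    return results, scenes


def pool_results(results: list[PositionResult]) -> tuple[list[CellRecord], list[TSRecord]]:
    records = [r for res in results for r in res.records]
    ts = [t for res in results for t in res.ts_records]
    return records, ts
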