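"""End-to-end screening pipeline: database -> match -> kinetics -> inclusion.

Stage counts are recorded so every run leaves a reduction trail
(theoretical clusters, matched clusters, detected peaks, surviving
candidates); candidate sets can only shrink from stage to stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .database import DbParams, TheoreticalDatabase, build_database, db_stats
from .enumeration import Substrate
from .matching import (
    CandidateRecord,
    FilterParams,
    InclusionList,
    KineticTrace,
    build_traces,
    detect_peaks,
    extract_xic,
    group_candidates,
    kinetic_filter,
    match_clusters,
)


@dataclass
class PipelineResult:
    database: TheoreticalDatabase
    matched_cluster_ids: list[int]
    traces: list[KineticTrace]
    candidates: list[CandidateRecord]
    inclusion: InclusionList
    step_counts: dict[str, int] = field(default_factory=dict)

    @property
    def candidate_cluster_ids(self) -> set[int]:
        return {c.cluster_id for c in self.candidates}


def screen_peaklists(
    db: TheoreticalDatabase,
    peaks: pd.DataFrame,
    filter_params: FilterParams | None = None,
    d_max: int = 15,
) -> PipelineResult:
    """Run stages 2-4 of the screen against a combined observation table."""
    fp = filter_params or FilterParams()
    reps = [c.representative for c in db.clusters]
    matched = match_clusters(reps, peaks, fp.mz_tolerance)

    traces: list[KineticTrace] = []
    time_grid = sorted(set(peaks["digestion_time"].astype(float))) or [0.0]
    if 0.0 not in time_grid:
        time_grid = [0.0] + time_grid
    for ci in matched:
        mz = reps[ci]
        xic = extract_xic(peaks, mz, fp.mz_tolerance)
        apexes = [rt for rt, _ in detect_peaks(xic, fp.delta)]
        traces.extend(build_traces(peaks, ci, mz, apexes, fp, time_grid))

    candidates = kinetic_filter(traces, fp)
    inclusion = group_candidates(candidates, d_max)
    counts = {
        "clusters": len(db.clusters),
        "matched_clusters": len(matched),
        "detected_peaks": len(traces),
        "candidates": len(candidates),
        "inclusion_groups": inclusion.n_groups,
        "inclusion_subgroups": inclusion.n_subgroups,
    }
    return PipelineResult(db, matched, traces, candidates, inclusion, counts)


def run_pipeline(
    substrates: Substrate | Sequence[Substrate],
    peaks: pd.DataFrame,
    db_params: DbParams | None = None,
    filter_params: FilterParams | None = None,
    d_max: int = 15,
) -> PipelineResult:
    db = build_database(substrates, db_params or DbParams())
    result = screen_peaklists(db, peaks, filter_params, d_max)
    result.step_counts = {**db_stats(db), **result.step_counts}
    return result
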