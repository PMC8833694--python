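"""End-to-end orchestration: cohort -> morphometry -> perfusion -> scores -> report.

The pipeline is deterministic given a cohort and a configuration; every
output table carries the configuration hash so a changed threshold is
visible in the artifacts.  Stages log per node; a hard error in a stage
aborts with the stage name and node id, while per-node CEUS failures
degrade to unavailable scores (the motion-corrupted-control behaviour).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .diagnostics import DiagnosticResult, report_table, threshold_sweep
from .errors import LnscoreError, PairingError
from .morphometry import ContourStack, measure_stack
from .perfusion import PerfusionParams, TimeIntensityCurve, analyze_tic
from .scoring import LNRecord, ScoreCard, build_scorecard, group_paired_ttest
from .synthetic import SyntheticSubject

__all__ = ["PipelineResult", "run_pipeline", "subjects_to_inputs"]

log = logging.getLogger("lnscore")


@dataclass
class PipelineResult:
    """All tables produced by one pipeline run."""

    morphometry: pd.DataFrame
    perfusion: pd.DataFrame
    scorecards: pd.DataFrame
    group_stats: pd.DataFrame
    report: pd.DataFrame
    cards: list[ScoreCard]
    pathology: dict[str, bool]

    def sweep(self) -> dict[int, DiagnosticResult]:
        return threshold_sweep(self.cards, self.pathology)

    def write(self, outdir: str | Path, config: lio.PipelineConfig) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("morphometry", "perfusion", "scorecards", "group_stats", "report"):
            lio.write_table(getattr(self, name), outdir / f"{name}.csv", config)


@dataclass
class _NodeInput:
    subject_id: str
    group: str
    side: str
    node_id: str
    contours: ContourStack
    tic: TimeIntensityCurve | None
    hilum_visible: bool
    pathology_positive: bool


def subjects_to_inputs(subjects: list[SyntheticSubject]) -> list[_NodeInput]:
    """Adapt in-memory synthetic subjects to pipeline node inputs."""
    out = []
    for s in subjects:
        for node, path_pos in ((s.left, s.pathology_positive_left),
                               (s.right, s.pathology_positive_right)):
            out.append(
                _NodeInput(
                    subject_id=s.subject_id,
                    group=s.group,
                    side=node.side,
                    node_id=node.node_id,
                    contours=node.contours,
                    tic=node.tic,
                    hilum_visible=node.hilum_visible,
                    pathology_positive=path_pos,
                )
            )
    return out


def _inputs_from_cohort(cohort: lio.CohortTable) -> list[_NodeInput]:
    out = []
    for _, row in cohort.table.iterrows():
        contours = lio.read_contours(cohort.root / row["contour_path"], row["node_id"])
        tic = None
        if row["tic_path"]:
            tic = lio.read_tic(cohort.root / row["tic_path"], row["node_id"])
        out.append(
            _NodeInput(
                subject_id=str(row["subject_id"]),
                group=row["group"],
                side=row["side"],
                node_id=str(row["node_id"]),
                contours=contours,
                tic=tic,
                hilum_visible=bool(row["hilum_visible"]),
                pathology_positive=bool(row["pathology_positive"]),
            )
        )
    return out


def run_pipeline(
    config: lio.PipelineConfig,
    cohort: lio.CohortTable | list[SyntheticSubject],
) -> PipelineResult:
    """Run every stage on a loaded cohort (or in-memory synthetic subjects)."""
    if isinstance(cohort, lio.CohortTable):
        nodes = _inputs_from_cohort(cohort)
    else:
        nodes = subjects_to_inputs(cohort)

    records: dict[tuple[str, str], LNRecord] = {}
    morpho_rows, perf_rows = [], []
    for node in nodes:
        log.info("measuring node %s", node.node_id)
        try:
            morpho = measure_stack(
                node.contours,
                angle_tol_deg=config.angle_tol_deg,
                densify_points=config.densify_points,
            )
        except LnscoreError as exc:
            raise type(exc)(f"morphometry stage, node {node.node_id}: {exc}") from exc
        perf: PerfusionParams | None = None
        if node.tic is not None:
            log.info("analyzing TIC of node %s", node.node_id)
            perf = analyze_tic(
                node.tic,
                max_excluded_fraction=config.quality_gate_max_excluded,
                k_sd=config.arrival_k_sd,
                wir_source=config.wir_source,
            )
        records[(node.subject_id, node.side)] = LNRecord(
            node_id=node.node_id,
            subject_id=node.subject_id,
            side=node.side,
            morphometry=morpho,
            perfusion=perf,
            hilum_visible=node.hilum_visible,
        )
        morpho_rows.append(
            {
                "node_id": node.node_id,
                "subject_id": node.subject_id,
                "side": node.side,
                "volume_mm3": morpho.volume_mm3,
                "length_mm": morpho.length_mm,
                "width_mm": morpho.width_mm,
                "lw_ratio": morpho.lw_ratio,
                "is_round": int(morpho.is_round),
            }
        )
        if perf is not None:
            perf_rows.append(
                {
                    "node_id": node.node_id,
                    "subject_id": node.subject_id,
                    "side": node.side,
                    "usable": int(perf.usable),
                    "excluded_fraction": perf.excluded_fraction,
                    "t_arrival_s": perf.t_arrival_s,
                    "ttp_s": perf.ttp_s,
                    "wir_au_per_s": perf.wir_au_per_s,
                    "peak_enhancement_au": perf.peak_enhancement_au,
                    "fit_rmse": perf.fit_rmse,
                }
            )

    subject_ids = list(dict.fromkeys(n.subject_id for n in nodes))
    cards, card_rows = [], []
    pathology: dict[str, bool] = {
        n.subject_id: n.pathology_positive for n in nodes if n.side == "left"
    }
    groups = {n.subject_id: n.group for n in nodes}
    for sid in subject_ids:
        left = records.get((sid, "left"))
        right = records.get((sid, "right"))
        if left is None or right is None:
            raise PairingError(f"scoring stage, subject {sid}: missing a side")
        card = build_scorecard(
            left,
            right,
            ratio_threshold=config.volume_ratio_threshold,
            roundness_cutoff=config.roundness_cutoff,
            ttp_rel_margin=config.ttp_rel_margin,
            wir_rel_margin=config.wir_rel_margin,
        )
        cards.append(card)
        card_rows.append(
            {
                "subject_id": sid,
                "group": groups[sid],
                **{
                    k: ("NA" if v is None else v)
                    for k, v in card.scores.items()
                },
                "sum_score": card.sum_score,
                "available_count": card.available_count,
                "sum_percent": card.sum_percent_display,
                "pathology_positive": int(pathology[sid]),
            }
        )

    group_stats = _group_stats(records, groups)
    report = report_table(cards, pathology, config.confidence)
    return PipelineResult(
        morphometry=pd.DataFrame(morpho_rows),
        perfusion=pd.DataFrame(perf_rows),
        scorecards=pd.DataFrame(card_rows),
        group_stats=group_stats,
        report=report,
        cards=cards,
        pathology=pathology,
    )


def _group_stats(
    records: dict[tuple[str, str], LNRecord], groups: dict[str, str]
) -> pd.DataFrame:
    """Cohort-level paired t-tests (left vs right) within the tumor group."""
    tumor_ids = [sid for sid, g in groups.items() if g == "tumor_injected"]
    extractors = {
        "volume_mm3": lambda r: r.morphometry.volume_mm3,
        "lw_ratio": lambda r: r.morphometry.lw_ratio,
        "ttp_s": lambda r: r.perfusion.ttp_s if r.perfusion_usable else np.nan,
        "wir_au_per_s": lambda r: (
            r.perfusion.wir_au_per_s if r.perfusion_usable else np.nan
        ),
    }
    rows = []
    for name, get in extractors.items():
        lv = np.array([get(records[(sid, "left")]) for sid in tumor_ids])
        rv = np.array([get(records[(sid, "right")]) for sid in tumor_ids])
        keep = ~(np.isnan(lv) | np.isnan(rv))
        lv, rv = lv[keep], rv[keep]
        row = {"parameter": name, "n_pairs": int(lv.size),
               "left_mean": lv.mean() if lv.size else np.nan,
               "right_mean": rv.mean() if rv.size else np.nan}
        try:
            t, p = group_paired_ttest(lv, rv)
            row.update(t_statistic=t, p_value=p)
        except LnscoreError:
            row.update(t_statistic=np.nan, p_value=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
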