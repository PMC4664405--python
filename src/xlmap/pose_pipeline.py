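"""Restraint-based screening of docking pose ensembles.

Rigid-body docking proposes many ligand placements; chemical cross-links
arbitrate between them.  A pose is accepted when every evidence restraint
(receptor-ligand lysine pair) is within the distance cap and the internal
control cross-link — a receptor-internal lysine pair whose distance
validates the receptor model independently of the docking hypothesis —
also passes.  The module also renders the single-ligand bridging verdict:
whether one ligand molecule could satisfy two cross-links on opposite
receptor subunits at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .structure_restraints import (
    BS3_SPACER,
    DEFAULT_CAP,
    BridgingResult,
    RestraintResult,
    StructureModel,
    XLRestraint,
    bridging_feasibility,
    evaluate_restraints,
)

__all__ = [
    "PoseSet",
    "PoseEvaluation",
    "ScreenParams",
    "screen_poses",
    "exclusivity_report",
    "ExclusivityReport",
    "evaluations_to_dataframe",
]


@dataclass
class PoseSet:
    """A receptor plus an ordered ensemble of ligand placements."""

    receptor: StructureModel
    poses: list[tuple[str, StructureModel]]

    def __post_init__(self) -> None:
        rc = set(self.receptor.chains)
        for pid, ligand in self.poses:
            overlap = rc & set(ligand.chains)
            if overlap:
                raise ValueError(
                    f"pose {pid}: ligand chain ids {sorted(overlap)} collide with receptor"
                )


@dataclass(frozen=True)
class ScreenParams:
    cap: float = DEFAULT_CAP
    control_rule: str = "cap"      # "cap" | "spacer_slack"
    control_slack: float = 1.0     # Å, spacer_slack rule only

    def __post_init__(self) -> None:
        if self.control_rule not in ("cap", "spacer_slack"):
            raise ValueError(f"unknown control rule {self.control_rule!r}")


@dataclass
class PoseEvaluation:
    pose_id: str
    records: list[RestraintResult]
    control_ok: bool | None        # None when no control restraint given
    verdict: str                   # "accepted" | "rejected" | "unevaluable"
    reasons: list[str] = field(default_factory=list)


def _control_passes(rec: RestraintResult, params: ScreenParams) -> bool:
    if not rec.evaluable or rec.distance is None:
        return False
    if params.control_rule == "cap":
        return rec.distance <= rec.restraint.cap
    return rec.distance <= rec.restraint.spacer + params.control_slack


def screen_poses(
    pose_set: PoseSet,
    restraints: Sequence[XLRestraint],
    params: ScreenParams = ScreenParams(),
) -> tuple[list[PoseEvaluation], dict]:
    """Evaluate every pose independently against the restraint list.

    Evidence restraints must all be satisfied at their caps; control
    restraints must pass the configured control rule.  Poses with
    unresolvable anchors are reported unevaluable, not accepted.
    """
    evaluations: list[PoseEvaluation] = []
    for pose_id, ligand in pose_set.poses:
        composite = pose_set.receptor.merged_with(ligand, model_id=pose_id)
        records = evaluate_restraints(composite, restraints)
        reasons: list[str] = []
        unevaluable = [r for r in records if not r.evaluable]
        evidence = [r for r in records if r.restraint.role == "evidence" and r.evaluable]
        controls = [r for r in records if r.restraint.role == "control" and r.evaluable]

        if unevaluable:
            for r in unevaluable:
                reasons.append(f"unevaluable restraint {r.restraint.label!r}: {r.note}")
            evaluations.append(PoseEvaluation(pose_id, records, None, "unevaluable", reasons))
            continue

        control_ok: bool | None = None
        if controls:
            control_ok = all(_control_passes(r, params) for r in controls)
            if not control_ok:
                reasons.append("internal-control cross-link violated")
        violated = [r for r in evidence if not r.satisfied]
        for r in violated:
            reasons.append(
                f"restraint {r.restraint.label!r}: {r.distance:.1f} A > cap {r.restraint.cap:.1f} A"
            )
        accepted = not violated and (control_ok is None or control_ok)
        evaluations.append(
            PoseEvaluation(pose_id, records, control_ok, "accepted" if accepted else "rejected", reasons)
        )
    summary = {
        "n_poses": len(pose_set.poses),
        "n_accepted": sum(e.verdict == "accepted" for e in evaluations),
        "n_rejected": sum(e.verdict == "rejected" for e in evaluations),
        "n_unevaluable": sum(e.verdict == "unevaluable" for e in evaluations),
        "cap": params.cap,
        "control_rule": params.control_rule,
    }
    return evaluations, summary


@dataclass
class ExclusivityReport:
    d_receptor: float
    d_ligand: float | None
    cap: float
    paper_mode: BridgingResult
    triangle_mode: BridgingResult | None
    verdict: str
    text: str


def exclusivity_report(
    d_receptor: float,
    d_ligand: float | None = None,
    cap: float = DEFAULT_CAP,
) -> ExclusivityReport:
    """Single-ligand bridging verdict for two receptor-side anchors.

    ``d_receptor`` is the (closest achievable) distance between the two
    receptor anchors; ``d_ligand`` the distance between the two ligand
    anchors, when available.  The colocated-ligand bound (2*cap) decides
    the headline verdict; the triangle bound is reported alongside when
    d_ligand is known.
    """
    paper = bridging_feasibility(d_receptor, d_ligand, cap, mode="paper")
    triangle = (
        bridging_feasibility(d_receptor, d_ligand, cap, mode="triangle")
        if d_ligand is not None
        else None
    )
    if paper.feasible:
        verdict = "feasible"
        text = (
            f"receptor anchors {d_receptor:.1f} A apart: within the combined-reach "
            f"bound of {paper.bound:.0f} A; one ligand molecule could bridge both sites"
        )
    else:
        verdict = "infeasible"
        text = (
            f"receptor anchors {d_receptor:.1f} A apart: exceeds the {paper.bound:.0f} A "
            f"combined-reach bound; one ligand molecule cannot engage both sites "
            f"simultaneously (mutually exclusive binding)"
        )
    if triangle is not None:
        text += (
            f"; triangle bound with ligand anchors {d_ligand:.1f} A apart: "
            f"{'feasible' if triangle.feasible else 'infeasible'}"
        )
    return ExclusivityReport(d_receptor, d_ligand, cap, paper, triangle, verdict, text)


def evaluations_to_dataframe(evaluations: Sequence[PoseEvaluation]) -> pd.DataFrame:
    rows = []
    for e in evaluations:
        for r in e.records:
            rows.append(
                {
                    "pose_id": e.pose_id,
                    "restraint": r.restraint.label,
                    "role": r.restraint.role,
                    "distance": r.distance,
                    "satisfied": r.satisfied,
                    "evaluable": r.evaluable,
                    "verdict": e.verdict,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pose_id", "restraint", "role", "distance", "satisfied", "evaluable", "verdict"],
    )


def write_screen_outputs(
    out_tsv: str | Path,
    out_json: str | Path | None,
    evaluations: Sequence[PoseEvaluation],
    summary: dict,
) -> None:
    evaluations_to_dataframe(evaluations).to_csv(out_tsv, sep="\t", index=False)
    if out_json is not None:
        with open(out_json, "w") as fh:
            json.dump(summary, fh, indent=2)
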