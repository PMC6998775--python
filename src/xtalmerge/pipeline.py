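"""End-to-end assembly driver: wedges -> classes -> rejection -> best dataset.

:func:`run_pipeline` executes the three workflow steps on a study loaded
from the tabular format (or passed in memory), writes the full output tree
(per-crystal wedge report, check-style classification report, dendrogram,
one directory per assembled dataset, and a ranked summary) and returns the
results programmatically.  Every number in the reports is recomputable from
the emitted reflection tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .classify import ClassAssignment, classify_datasets, export_dendrogram
from .core import CrystalDataset, PointGroup, ResolutionConfig
from .io import (
    FLOAT_FMT,
    read_observations,
    write_amplitudes,
    write_merged,
    write_stats,
)
from .rejection import AssemblyResult, RejectionConfig, assemble_class, select_best
from .wedges import WedgeStats, select_dataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("xtalmerge")


@dataclass
class RunConfig:
    """Configuration of one assembly run (defaults mirror the CLI)."""

    observations: Optional[str] = None
    cells: Optional[str] = None
    outdir: str = "assembly_out"
    pointgroup: str = "222"
    n_classes: int = 1
    linkage: str = "ward"
    q_total: int = 10
    reso: float = 3.0
    reso_cchalf: Optional[float] = None
    reject_crystals: bool = False
    xtal_step: int = 10
    reject_frames: bool = False
    decay_sequence: tuple[float, ...] = (5.0, 3.0, 2.0, 1.0)
    completeness_threshold: float = 90.0
    criterion: str = "cc_half"
    anomalous: bool = False
    rfree_fraction: float = 0.05
    seed: int = 0
    write_outputs: bool = True

    def __post_init__(self) -> None:
        if self.reject_frames and not self.reject_crystals:
            raise ValueError(
                "frame rejection (--rjframe) requires crystal rejection (--rjxtal)"
            )
        if self.criterion not in ("cc_half", "delanom"):
            raise ValueError("criterion must be cc_half or delanom")
        self.resolution = ResolutionConfig(self.reso, self.reso_cchalf)
        self.reso_cchalf = self.resolution.reso_cchalf
        if self.criterion == "delanom":
            self.anomalous = True

    def rejection_config(self) -> RejectionConfig:
        return RejectionConfig(
            xtal_step=self.xtal_step,
            decay_sequence=tuple(self.decay_sequence),
            completeness_threshold=self.completeness_threshold,
            reject_crystals=self.reject_crystals,
            reject_frames=self.reject_frames,
        )


@dataclass
class PipelineResult:
    """Everything one run produced, in memory."""

    selected: dict[str, CrystalDataset]
    excluded: list[str]
    wedge_report: pd.DataFrame
    assignment: Optional[ClassAssignment]
    results: list[AssemblyResult]
    best: dict[str, Optional[AssemblyResult]]
    summary: pd.DataFrame
    outdir: Optional[Path]


def _wedge_report_frame(rows: list[tuple[str, WedgeStats]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "crystal_id": cid,
                "q": w.q,
                "last_frame": w.last_frame,
                "cc_half": float("nan") if w.cc_half is None else w.cc_half,
                "n_obs": w.n_obs,
            }
            for cid, w in rows
        ]
    )


def _summary_frame(results: Sequence[AssemblyResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = {
            "class": r.class_label,
            "iteration": r.iteration,
            "decay": float("nan") if r.decay is None else r.decay,
            "n_crystals": r.n_crystals,
        }
        d.update(
            {
                k: (float("nan") if v is None else v)
                for k, v in r.stats.as_dict().items()
            }
        )
        rows.append(d)
    return pd.DataFrame(rows)


def _result_dirname(r: AssemblyResult) -> str:
    tag = f"class_{r.class_label:02d}/it{r.iteration:02d}"
    if r.decay is not None:
        tag += f"_decay{r.decay:g}"
    return tag


def run_pipeline(
    config: RunConfig, datasets: Optional[Sequence[CrystalDataset]] = None
) -> PipelineResult:
    """Run the full assembly workflow.

    ``datasets`` may be passed directly (e.g. from the simulator); otherwise
    they are read from ``config.observations`` / ``config.cells``.  Classes
    that end up unusable (all crystals excluded, undefined statistics) are
    logged and skipped, never fatal mid-run.
    """
    if datasets is None:
        if config.observations is None or config.cells is None:
            raise ValueError("either pass datasets or set observations/cells paths")
        datasets = read_observations(config.observations, config.cells)
    pg = PointGroup.from_name(config.pointgroup)
    outdir = Path(config.outdir) if config.write_outputs else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    # step 1: progressive wedges, best-CC1/2 selection
    selected: dict[str, CrystalDataset] = {}
    excluded: list[str] = []
    wedge_rows: list[tuple[str, WedgeStats]] = []
    best_cc: dict[str, float] = {}
    for ds in sorted(datasets, key=lambda d: d.crystal_id):
        trimmed, scored = select_dataset(
            ds, pg, config.resolution.reso_cchalf, q_total=config.q_total, seed=config.seed
        )
        wedge_rows.extend((ds.crystal_id, w) for w in scored)
        if trimmed is None:
            excluded.append(ds.crystal_id)
            log.warning("crystal %s excluded: no wedge with defined CC1/2", ds.crystal_id)
        else:
            selected[ds.crystal_id] = trimmed
            defined = [w.cc_half for w in scored if w.cc_half is not None]
            best_cc[ds.crystal_id] = max(defined)
    wedge_report = _wedge_report_frame(wedge_rows)
    if outdir is not None:
        wedge_report.to_csv(outdir / "wedges.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # step 2: unit-cell classification
    assignment: Optional[ClassAssignment] = None
    if len(selected) >= 2 and config.n_classes < len(selected):
        assignment = classify_datasets(
            [selected[cid].cell for cid in sorted(selected)],
            sorted(selected),
            n_classes=config.n_classes,
            linkage=config.linkage,
        )
    elif len(selected) >= 2:
        assignment = classify_datasets(
            [selected[cid].cell for cid in sorted(selected)],
            sorted(selected),
            n_classes=min(config.n_classes, len(selected)),
            linkage=config.linkage,
        )
    labels = (
        assignment.labels
        if assignment is not None
        else {cid: 1 for cid in selected}
    )
    check = pd.DataFrame(
        [
            {
                "crystal_id": cid,
                **dict(zip(("a", "b", "c", "alpha", "beta", "gamma"), selected[cid].cell.as_tuple())),
                "best_cc_half": best_cc.get(cid, float("nan")),
                "class": labels[cid],
            }
            for cid in sorted(selected)
        ]
    )
    if outdir is not None:
        check.to_csv(outdir / "check.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        if assignment is not None:
            export_dendrogram(assignment, outdir / "dendrogram.pdf")

    # step 3: per-class assembly with rejection loops
    rej_cfg = config.rejection_config()
    results: list[AssemblyResult] = []
    for class_label in sorted(set(labels.values())):
        members = [selected[cid] for cid in sorted(selected) if labels[cid] == class_label]
        if not members:
            continue
        try:
            class_results = assemble_class(
                members,
                rej_cfg,
                pg,
                config.reso,
                class_label=class_label,
                seed=config.seed + class_label,
                anomalous=config.anomalous,
                keep_merged=True,
            )
        except ValueError as exc:
            log.warning("class %d skipped: %s", class_label, exc)
            continue
        results.extend(class_results)
        if outdir is not None:
            for r in class_results:
                rdir = outdir / _result_dirname(r)
                rdir.mkdir(parents=True, exist_ok=True)
                write_merged(r.merged, rdir / "merged.tsv")
                write_stats(r.stats, rdir / "stats.tsv")
                prov = r.provenance()
                (rdir / "provenance.json").write_text(json.dumps(prov, indent=1) + "\n")

    summary = _summary_frame(results)
    best: dict[str, Optional[AssemblyResult]] = {}
    for criterion in ("cc_half", "delanom"):
        try:
            best[criterion] = select_best(results, criterion)
        except ValueError:
            best[criterion] = None
    if outdir is not None and len(summary):
        ranked = summary.sort_values(
            config.criterion, ascending=False, na_position="last"
        ).reset_index(drop=True)
        ranked.to_csv(outdir / "summary.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        chosen = best[config.criterion]
        if chosen is not None and chosen.merged is not None and len(chosen.merged.table):
            write_amplitudes(
                chosen.merged,
                outdir / f"best_{config.criterion}_amplitudes.tsv",
                rfree_fraction=config.rfree_fraction,
                seed=config.seed,
            )
    return PipelineResult(
        selected=selected,
        excluded=excluded,
        wedge_report=wedge_report,
        assignment=assignment,
        results=results,
        best=best,
        summary=summary,
        outdir=outdir,
    )
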