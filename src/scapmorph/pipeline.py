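"""End-to-end orchestration: screening → landmarks → morphometrics → model.

The pipeline consumes meshes with landmark sidecars (or a ready cohort CSV),
applies the screening exclusion criteria, measures every specimen, and runs
the model-building stage, writing a reproducible result bundle (records
table, selection JSON, screening report and a run manifest).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import __version__
from .geometry import build_frame
from .landmarks import LandmarkSet, detect_missing_landmarks
from .model import collinearity_loop, loocv_best_subset, pearson_screen
from .morphometrics import OUTCOME_COLUMN, assemble_record
from .synthetic import ScreeningRecord

__all__ = [
    "PipelineConfig",
    "ScreeningReport",
    "screen_cohort",
    "screening_records_from_df",
    "measure_mesh",
    "measure_cohort",
    "group_percentages",
    "run_pipeline",
]

log = logging.getLogger("scapmorph")

EXCLUSION_CRITERIA = (
    "slice_thickness",   # insufficient resolution (> 1 mm)
    "gross_deformity",   # glenoid/acromial deformity
    "artefact",          # beam hardening, arthrography, ...
    "incomplete",        # scapula not fully captured
)


@dataclass(frozen=True)
class ScreeningReport:
    """Disposition of every screened scan plus per-criterion tallies."""

    n_screened: int
    exclusions: dict[str, int]
    n_included: int
    dispositions: pd.DataFrame  # scan_id, included, reason

    def __post_init__(self) -> None:
        if self.n_screened != self.n_included + sum(self.exclusions.values()):
            raise ValueError("screening counts do not balance")


def _disposition(r: ScreeningRecord) -> str | None:
    """First matching exclusion criterion, in the stated order."""
    if r.slice_thickness_mm > 1.0:  # strictly greater: 1.0 mm is included
        return "slice_thickness"
    if r.gross_deformity:
        return "gross_deformity"
    if r.artefact:
        return "artefact"
    if not r.complete_scapula:
        return "incomplete"
    return None


def screen_cohort(records: list[ScreeningRecord]) -> ScreeningReport:
    """Apply the exclusion criteria; a scan is excluded once, under the
    first criterion it violates."""
    rows = []
    tallies = {c: 0 for c in EXCLUSION_CRITERIA}
    for r in records:
        reason = _disposition(r)
        if reason is not None:
            tallies[reason] += 1
        rows.append({
            "scan_id": r.scan_id,
            "included": reason is None,
            "reason": reason or "",
        })
    df = pd.DataFrame(rows, columns=["scan_id", "included", "reason"])
    return ScreeningReport(
        n_screened=len(records),
        exclusions=tallies,
        n_included=int(df["included"].sum()) if len(df) else 0,
        dispositions=df,
    )


def screening_records_from_df(df: pd.DataFrame) -> list[ScreeningRecord]:
    return [
        ScreeningRecord(
            scan_id=str(r.scan_id),
            slice_thickness_mm=float(r.slice_thickness_mm),
            gross_deformity=bool(r.gross_deformity),
            artefact=bool(r.artefact),
            complete_scapula=bool(r.complete_scapula),
        )
        for r in df.itertuples(index=False)
    ]


def group_percentages(df: pd.DataFrame, group_col: str, category_col: str) -> pd.DataFrame:
    """Within-group percentage of each category (demographic summaries)."""
    counts = df.groupby([group_col, category_col]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def measure_mesh(
    mesh: trimesh.Trimesh, landmarks: LandmarkSet
) -> dict[str, float]:
    """Morphometric record for one mesh as a cohort-table row."""
    frame = build_frame(
        landmarks.C, landmarks.M, landmarks.I,
        side=landmarks.side, anterior_hint=landmarks.anterior_hint,
    )
    lm = detect_missing_landmarks(mesh, frame, landmarks)
    return assemble_record(mesh, lm, frame).to_dict()


def measure_cohort(
    specimens: list[tuple[str, trimesh.Trimesh, LandmarkSet]],
) -> tuple[pd.DataFrame, list[dict]]:
    """Measure many specimens; failures are logged and excluded.

    Returns the cohort table (indexed by specimen id) and a failure list.
    """
    rows, failures = {}, []
    for sid, mesh, lm in specimens:
        try:
            rows[sid] = measure_mesh(mesh, lm)
        except Exception as exc:  # noqa: BLE001 - per-specimen isolation
            log.warning("specimen %s failed: %s", sid, exc)
            failures.append({"specimen": sid, "error": str(exc)})
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df, failures


@dataclass
class PipelineConfig:
    """Inputs, options and output location for one pipeline run."""

    output_dir: Path
    mesh_dir: Path | None = None            # meshes + <stem>.landmarks.json
    cohort_csv: Path | None = None          # ready cohort table instead
    screening_csv: Path | None = None
    vif_threshold: float = 10.0
    cv_mode: str = "honest"                 # or "fixed"
    max_subset_size: int | None = None
    run_collinearity_loop: bool = True
    seed: int = 0

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def _load_specimens(mesh_dir: Path):
    specimens = []
    for mesh_path in sorted(mesh_dir.glob("*")):
        if mesh_path.suffix.lower() not in (".ply", ".stl", ".obj"):
            continue
        lm_path = mesh_path.with_suffix(".landmarks.json")
        if not lm_path.exists():
            log.warning("no landmark sidecar for %s; skipped", mesh_path.name)
            continue
        mesh = trimesh.load(mesh_path, process=False, force="mesh")
        lm = LandmarkSet.load_json(lm_path)
        specimens.append((mesh_path.stem, mesh, lm))
    return specimens


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and write the result bundle.

    Stage outputs are written incrementally (screening report, cohort
    table, model JSON) so the statistics stage can be rerun from the saved
    cohort table without re-measuring meshes.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"stages": []}

    if config.screening_csv is not None:
        records = screening_records_from_df(pd.read_csv(config.screening_csv))
        report = screen_cohort(records)
        report.dispositions.to_csv(out / "screening_dispositions.csv", index=False)
        bundle["screening"] = {
            "n_screened": report.n_screened,
            "exclusions": report.exclusions,
            "n_included": report.n_included,
        }
        bundle["stages"].append("screening")

    table: pd.DataFrame | None = None
    if config.mesh_dir is not None:
        specimens = _load_specimens(Path(config.mesh_dir))
        table, failures = measure_cohort(specimens)
        table.to_csv(out / "cohort_table.csv", index_label="specimen")
        bundle["morphometrics"] = {
            "n_measured": len(table),
            "n_failed": len(failures),
            "failures": failures,
        }
        bundle["stages"].append("morphometrics")
    elif config.cohort_csv is not None:
        table = pd.read_csv(config.cohort_csv)
        if "specimen" in table.columns:
            table = table.set_index("specimen")

    if table is not None:
        if len(table) < 3:
            raise RuntimeError(
                f"only {len(table)} usable records; at least 3 are required"
            )
        screen = pearson_screen(table, outcome=OUTCOME_COLUMN)
        screen.to_csv(out / "pearson_screen.csv", header=True)
        if config.run_collinearity_loop:
            results, trace = collinearity_loop(
                table,
                vif_threshold=config.vif_threshold,
                max_size=config.max_subset_size,
                cv=config.cv_mode,
            )
        else:
            results = loocv_best_subset(
                table, max_size=config.max_subset_size, cv=config.cv_mode
            )
            trace = []
        d = results.to_json_dict()
        d["drop_one"] = results.drop_one().table.reset_index().rename(
            columns={"index": "variable"}
        ).to_dict(orient="records")
        diag = results.diagnostics()
        d["diagnostics"] = {
            "skew": diag.skew,
            "excess_kurtosis": diag.excess_kurtosis,
            "probplot_r": diag.probplot_r,
            "het_abs_resid_corr": diag.het_abs_resid_corr,
            "heteroscedastic": diag.heteroscedastic,
        }
        d["collinearity_trace"] = trace
        (out / "model_selection.json").write_text(json.dumps(d, indent=1))
        (out / "model_summary.txt").write_text(results.summary())
        bundle["model"] = d
        bundle["stages"].append("model")

    bundle["manifest"] = {
        "config": config.to_json_dict(),
        "seed": config.seed,
        "versions": {
            "scapmorph": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "trimesh": trimesh.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=1))
    (out / "bundle.json").write_text(json.dumps(bundle, indent=1, default=str))
    return bundle
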