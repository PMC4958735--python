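"""File-contract pipeline: simulate -> score -> qc -> cav -> aggregate -> agree.

Each stage reads and writes plain CSV/JSON in a run directory, so the
stages compose identically whether driven by :func:`run_pipeline`, by
the command line, or called one at a time.  Every run writes a
``run_log.json`` holding the configuration snapshot, seeds, input
hashes and per-stage counts, which together fully describe the run.

File contracts (UTF-8 CSV, comma, header row, '.' decimal; undefined
scores are empty fields, never 0):

* ``manifest.csv`` — core_id, tma_id, subject_id, study_id, is_control,
  control_kind, image_path, truth_path
* ``scores.csv`` — core_id, method, n_pos, n_neg, total, ki67_percent
* ``qc.csv`` — core_id, status, reasons, category
* ``subjects.csv`` — subject_id, score, n_cores
* ``agreement.json`` — kappa/agreement/AUC report (overall + strata)
"""

from __future__ import annotations

import hashlib
import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import agreement_report, subject_average
from .cav import cav_score
from .classifier import CoreResult, score_core
from .config import ClassifierConfig, universal_config
from .image import load_core_image
from .qc import PathologistAnnotation, assign_category, check_controls, post_analytical_qc
from .synthetic import CoreSpec, generate_tma, write_tma


@dataclass
class RunConfig:
    """Everything a pipeline run depends on (echoed into the run log)."""

    outdir: Path
    image_dir: Path | None = None  # defaults to outdir/cores
    classifier_config: Path | None = None  # None -> bundled universal
    seed: int = 0
    dichotomy_cutoff: float = 10.0
    qc_min_nuclei: int = 50
    qc_max_nuclei: int = 15_000
    control_min_positive: float = 50.0
    control_max_negative: float = 5.0
    pooled_quartiles: bool = True
    cav_mean_of_fields: bool = False
    threads: int = 1
    # simulation block (used when no manifest exists yet)
    sim_n_cores: int = 30
    sim_nuclei_range: tuple[int, int] = (100, 2500)
    sim_fraction_range: tuple[float, float] = (0.0, 0.5)
    sim_artifact_fraction: float = 0.0
    um_per_px: float = 0.5

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.image_dir is None:
            self.image_dir = self.outdir / "cores"
        self.image_dir = Path(self.image_dir)
        if self.classifier_config is not None:
            self.classifier_config = Path(self.classifier_config)
            if not self.classifier_config.exists():
                raise FileNotFoundError(f"classifier config not found: {self.classifier_config}")

    def load_classifier(self) -> ClassifierConfig:
        if self.classifier_config is None:
            return universal_config()
        return ClassifierConfig.load(self.classifier_config)

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = str(v) if isinstance(v, Path) else v
        return d


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> pd.DataFrame:
    """Generate a synthetic TMA under the run config; returns the manifest."""
    from .experiments import SUBOPTIMAL_ARTIFACTS

    rng = np.random.default_rng(config.seed)
    layout = []
    n_sub = int(round(config.sim_artifact_fraction * config.sim_n_cores))
    subopt = np.zeros(config.sim_n_cores, dtype=bool)
    if n_sub:
        subopt[rng.choice(config.sim_n_cores, size=n_sub, replace=False)] = True
    for i in range(config.sim_n_cores):
        layout.append(
            CoreSpec(
                core_id=f"core_{i:03d}",
                n_nuclei=int(rng.integers(*config.sim_nuclei_range)),
                positive_fraction=float(rng.uniform(*config.sim_fraction_range)),
                um_per_px=config.um_per_px,
                subject_id=f"subj_{i // 2:03d}",  # two cores per subject
                artifact_levels=dict(SUBOPTIMAL_ARTIFACTS) if subopt[i] else {},
            )
        )
    cores = generate_tma(layout, include_controls=True, seed=config.seed, tma_id="tma_01")
    manifest = write_tma(cores, config.image_dir)
    # pathologist-style annotation: artifacted cores flagged suboptimal
    ann = pd.DataFrame(
        {
            "core_id": [s.core_id for s in layout],
            "tumour_type": "invasive",
            "malignant_nuclei": [s.n_nuclei for s in layout],
            "issues": ["background_staining" if s.artifact_levels else "" for s in layout],
        }
    )
    _write_csv(ann, config.image_dir / "annotations.csv")
    return manifest


def stage_score(config: RunConfig) -> pd.DataFrame:
    """Score every core in the manifest; failures are recorded, not fatal."""
    classifier = config.load_classifier()
    manifest = pd.read_csv(config.image_dir / "manifest.csv").fillna("")
    errors: list[dict] = []

    def one(row) -> CoreResult | None:
        path = config.image_dir / row.image_path
        try:
            image = load_core_image(
                path,
                core_id=row.core_id,
                tma_id=str(row.tma_id),
                subject_id=str(row.subject_id),
                study_id=str(row.study_id),
            )
        except (FileNotFoundError, ValueError) as exc:
            errors.append({"core_id": row.core_id, "error": str(exc)})
            return None
        image.is_control = bool(row.is_control)
        image.control_kind = str(row.control_kind)
        return score_core(image, classifier)

    rows = list(manifest.itertuples(index=False))
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(one, rows))
    else:
        results = [one(r) for r in rows]
    records = [
        {
            "core_id": r.core_id,
            "method": "automated",
            "n_pos": r.n_positive,
            "n_neg": r.n_negative,
            "total": r.total_nuclei,
            "ki67_percent": r.ki67_percent,
            "is_control": r.is_control,
            "control_kind": r.control_kind,
        }
        for r in results
        if r is not None
    ]
    scores = pd.DataFrame(records).sort_values("core_id", ignore_index=True)
    _write_csv(scores, config.outdir / "scores.csv")
    _write_csv(pd.DataFrame(errors, columns=["core_id", "error"]), config.outdir / "errors.csv")
    return scores


def stage_qc(config: RunConfig) -> pd.DataFrame:
    """Post-analytical QC + category assignment + TMA control check."""
    scores = pd.read_csv(config.outdir / "scores.csv").fillna({"control_kind": ""})
    ann_path = config.image_dir / "annotations.csv"
    categories: dict[str, str] = {}
    if ann_path.exists():
        ann = pd.read_csv(ann_path).fillna("")
        for row in ann.itertuples(index=False):
            issues = tuple(i for i in str(row.issues).split(";") if i)
            categories[row.core_id] = assign_category(
                PathologistAnnotation(
                    core_id=row.core_id,
                    tumour_type=(row.tumour_type or None),
                    malignant_nuclei=int(row.malignant_nuclei) if row.malignant_nuclei != "" else None,
                    issues=issues,
                )
            )
    decisions = []
    results = []
    for row in scores.itertuples(index=False):
        result = CoreResult(
            core_id=row.core_id,
            n_positive=int(row.n_pos),
            n_negative=int(row.n_neg),
            is_control=bool(row.is_control),
            control_kind=str(row.control_kind),
        )
        results.append(result)
        if result.is_control:
            continue  # controls are checked separately, never excluded here
        qc = post_analytical_qc(
            result,
            min_nuclei=config.qc_min_nuclei,
            max_nuclei=config.qc_max_nuclei,
            category=categories.get(row.core_id, "unknown"),
        )
        decisions.append(
            {
                "core_id": qc.core_id,
                "status": qc.status,
                "reasons": ";".join(qc.reasons),
                "category": qc.category,
            }
        )
    qc_table = pd.DataFrame(decisions)
    _write_csv(qc_table, config.outdir / "qc.csv")
    report = check_controls(
        results,
        tma_id="",
        min_positive_ki67=config.control_min_positive,
        max_negative_ki67=config.control_max_negative,
        max_blank_nuclei=config.qc_min_nuclei,
    )
    (config.outdir / "controls.json").write_text(json.dumps(report.__dict__, indent=2))
    return qc_table


def stage_cav(config: RunConfig) -> pd.DataFrame:
    """CAV-score every non-control core from its ground-truth table."""
    manifest = pd.read_csv(config.image_dir / "manifest.csv").fillna("")
    rows = []
    for i, row in enumerate(manifest.itertuples(index=False)):
        if bool(row.is_control):
            continue
        truth = pd.read_csv(config.image_dir / row.truth_path)
        score = cav_score(
            truth,
            seed=config.seed + 20_000 + i,
            mean_of_fields=config.cav_mean_of_fields,
            core_id=row.core_id,
        )
        rows.append(
            {
                "core_id": row.core_id,
                "method": "CAV",
                "n_pos": score.pos_counted,
                "n_neg": score.neg_counted,
                "total": score.total_counted,
                "ki67_percent": score.cav_percent,
                "fields": score.fields_counted,
                "low_tissue": score.low_tissue,
            }
        )
    cav_table = pd.DataFrame(rows)
    _write_csv(cav_table, config.outdir / "cav.csv")
    return cav_table


def stage_aggregate(config: RunConfig) -> pd.DataFrame:
    """Subject-level scores: mean automated score over QC-passing cores."""
    scores = pd.read_csv(config.outdir / "scores.csv")
    qc = pd.read_csv(config.outdir / "qc.csv")
    manifest = pd.read_csv(config.image_dir / "manifest.csv").fillna("")
    passing = set(qc.loc[qc["status"] == "pass", "core_id"])
    merged = scores.merge(manifest[["core_id", "subject_id"]], on="core_id", how="left")
    merged = merged[merged["subject_id"].astype(str) != ""]
    table = merged.rename(columns={"ki67_percent": "score"})[["subject_id", "core_id", "score"]]
    subjects = subject_average(table, passing_core_ids=passing)
    counts = (
        table[table["core_id"].isin(passing)].groupby("subject_id").size().rename("n_cores")
    )
    subjects = subjects.merge(counts, on="subject_id", how="left")
    _write_csv(subjects, config.outdir / "subjects.csv")
    return subjects


def stage_agree(config: RunConfig) -> dict:
    """Agreement report of automated vs CAV scores on QC-passing cores."""
    scores = pd.read_csv(config.outdir / "scores.csv")
    cav = pd.read_csv(config.outdir / "cav.csv")
    qc = pd.read_csv(config.outdir / "qc.csv")
    merged = (
        scores[~scores["is_control"].astype(bool)][["core_id", "ki67_percent"]]
        .rename(columns={"ki67_percent": "auto"})
        .merge(
            cav[["core_id", "ki67_percent"]].rename(columns={"ki67_percent": "visual"}),
            on="core_id",
        )
        .merge(qc[["core_id", "status", "category"]], on="core_id")
    )
    merged = merged[merged["status"] == "pass"].dropna(subset=["auto", "visual"])
    strata = merged["category"].map(
        lambda c: "satisfactory" if str(c).startswith("satisfactory") else str(c)
    )
    report = agreement_report(
        merged["auto"].to_numpy(),
        merged["visual"].to_numpy(),
        strata=strata.to_numpy(),
        cutoff=config.dichotomy_cutoff,
        pooled_quartiles=config.pooled_quartiles,
        seed=config.seed,
    )
    out = report.to_dict()
    (config.outdir / "agreement.json").write_text(json.dumps(out, indent=2))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the provenance log; returns a summary.

    When ``image_dir`` has no manifest the simulation stage runs first.
    Re-running with identical config and seed reproduces identical
    outputs.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    if not (config.image_dir / "manifest.csv").exists():
        manifest = stage_simulate(config)
        counts["simulated_cores"] = len(manifest)
    scores = stage_score(config)
    counts["scored_cores"] = len(scores)
    qc_table = stage_qc(config)
    counts["qc_pass"] = int((qc_table["status"] == "pass").sum())
    counts["qc_excluded"] = int((qc_table["status"] == "excluded").sum())
    cav_table = stage_cav(config)
    counts["cav_scored"] = len(cav_table)
    subjects = stage_aggregate(config)
    counts["subjects"] = len(subjects)
    agreement = stage_agree(config)
    log = {
        "config": config.to_dict(),
        "stage_counts": counts,
        "input_hashes": {
            "manifest.csv": _sha256(config.image_dir / "manifest.csv"),
        },
        "agreement": agreement,
    }
    (config.outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return log
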