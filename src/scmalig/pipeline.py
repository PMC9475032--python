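"""End-to-end pipeline: simulate/load -> QC -> cluster -> CNV/malignant ->
programs -> scoring -> edges -> drug prediction.

A single YAML-configurable object drives all stages. One global seed is
fanned out deterministically to per-stage seeds, so identical config and
seed reproduce byte-identical stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from scmalig import cnv_malig, drugpred, interactions, programs, qc_norm, signatures, syndata
from scmalig.qc_norm import QC_PRESETS, QcThresholds

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "cluster", "cnv", "programs", "score", "edges", "drugpred")


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # input: either a fixture directory or a simulation block
    input_dir: str | None = None
    simulate: dict = field(default_factory=dict)
    # qc
    qc_preset: str | None = None
    min_genes: int = 0
    min_transcripts: int = 0
    max_mito_fraction: float = 1.0
    scale_factor: float = 1e4
    # clustering
    n_neighbors: int = 15
    resolution: float = 1.0
    # cnv
    ref_tissue: str = "normal"
    window_size: int = 101
    cap: float = 3.0
    percentile: float = 90.0
    dominance: float = 0.5
    # programs
    n_factors: int = 4
    n_genes_per_factor: int = 30
    n_pcs: int = 6
    n_genes_per_pole: int = 50
    n_meta_programs: int = 4
    # scoring
    gmt_path: str | None = None
    # edges
    lr_pairs_path: str | None = None
    detection_threshold: float = 0.2
    # drugpred
    panel_expr_path: str | None = None
    panel_auc_path: str | None = None
    n_groups_per_class: int = 50
    n_signature_genes: int = 50
    enable_drugpred: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect all range/existence violations; empty list means valid."""
    errors = []
    if not 0 < config.percentile <= 100:
        errors.append(f"percentile {config.percentile} outside (0, 100]")
    if config.window_size < 3 or config.window_size % 2 == 0:
        errors.append(f"window_size {config.window_size} must be odd and >= 3")
    if config.cap <= 0:
        errors.append("cap must be positive")
    if not 0 <= config.dominance < 1:
        errors.append("dominance must be in [0, 1)")
    if not 0 <= config.max_mito_fraction <= 1:
        errors.append("max_mito_fraction must be in [0, 1]")
    if not 0 <= config.detection_threshold <= 1:
        errors.append("detection_threshold must be in [0, 1]")
    if config.scale_factor <= 0:
        errors.append("scale_factor must be positive")
    if config.qc_preset is not None and config.qc_preset not in QC_PRESETS:
        errors.append(f"unknown qc_preset {config.qc_preset!r}")
    if config.input_dir is not None and not Path(config.input_dir).exists():
        errors.append(f"input_dir {config.input_dir} does not exist")
    for name in ("gmt_path", "lr_pairs_path"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            errors.append(f"{name} {path} does not exist")
    wants_drugpred = config.enable_drugpred or config.panel_expr_path is not None
    if wants_drugpred:
        for name in ("panel_expr_path", "panel_auc_path"):
            path = getattr(config, name)
            if path is None:
                errors.append(f"drug prediction enabled but {name} not set")
            elif not Path(path).exists():
                errors.append(f"{name} {path} does not exist")
    return errors


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0])
        for stage, child in zip(STAGES, children)
    }


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _thresholds(config: PipelineConfig) -> QcThresholds:
    if config.qc_preset:
        return QC_PRESETS[config.qc_preset]
    return QcThresholds(
        min_genes=config.min_genes,
        min_transcripts=config.min_transcripts,
        max_mito_fraction=config.max_mito_fraction,
    )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run record.

    Stage outputs are plain TSV/GMT files under ``config.out_dir``; the run
    record (parameters, checksums, counts, timestamps) is written as
    ``run_record.json``.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    record: dict = {"config": asdict(config), "stages": {}}

    def _finish(stage: str, t0: float, outputs: list[Path], **counts) -> None:
        record["stages"][stage] = {
            "seed": seeds[stage],
            "outputs": {p.name: _checksum(p) for p in outputs},
            "started": t0,
            "finished": time.time(),
            **counts,
        }
        logger.info("[%s] done (%d outputs)", stage, len(outputs))

    # -- simulate / load ---------------------------------------------------
    stage = "simulate"
    t0 = time.time()
    try:
        if config.input_dir is not None:
            counts = qc_norm.read_counts(config.input_dir)
            positions = syndata.read_positions(
                Path(config.input_dir) / syndata.POSITIONS_FILE
            )
            truth = None
            _finish(stage, t0, [], n_cells=counts.n_cells, n_genes=counts.n_genes)
        else:
            sim = dict(config.simulate)
            sim.setdefault("seed", seeds[stage])
            cohort_cfg = syndata.CohortConfig(**sim)
            counts, pos_df, truth = syndata.generate_cohort(cohort_cfg)
            positions = pos_df.set_index("gene")
            written = syndata.write_fixture(counts, pos_df, truth, out / "fixture")
            _finish(stage, t0, written, n_cells=counts.n_cells, n_genes=counts.n_genes)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- qc + normalize ----------------------------------------------------
    stage = "qc"
    t0 = time.time()
    try:
        filtered = qc_norm.qc_filter(counts, _thresholds(config))
        expr = qc_norm.normalize_log(filtered, config.scale_factor)
        qc_path = out / "qc_cells.tsv"
        pd.DataFrame(index=pd.Index(expr.cell_ids, name="cell")).to_csv(
            qc_path, sep="\t"
        )
        _finish(stage, t0, [qc_path], n_cells_in=counts.n_cells, n_cells_out=expr.n_cells)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- clustering --------------------------------------------------------
    stage = "cluster"
    t0 = time.time()
    try:
        clusters = qc_norm.cluster_cells(
            expr, config.n_neighbors, config.resolution, seed=seeds[stage] % 2**31
        )
        cl_path = out / "clusters.tsv"
        clusters.to_csv(cl_path, sep="\t")
        _finish(stage, t0, [cl_path], n_clusters=int(clusters.nunique()))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- cnv + malignant calling -------------------------------------------
    stage = "cnv"
    t0 = time.time()
    try:
        ref_cells = expr.cell_meta.index[
            expr.cell_meta["tissue"] == config.ref_tissue
        ].tolist()
        cnv = cnv_malig.infer_cnv(
            expr, positions, ref_cells, config.window_size, config.cap
        )
        scores = cnv_malig.msd_score(cnv)
        threshold = cnv_malig.malignancy_threshold(
            scores.loc[ref_cells], config.percentile
        )
        calls = cnv_malig.call_malignant(
            scores, threshold, clusters, config.dominance
        )
        calls_path = out / "malignancy_calls.tsv"
        calls.to_csv(calls_path, sep="\t")
        _finish(
            stage, t0, [calls_path],
            threshold=threshold,
            n_malignant=int((calls["final_call"] == "malignant").sum()),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    malignant_cells = calls.index[calls["final_call"] == "malignant"].tolist()
    normal_cells = calls.index[calls["final_call"] == "normal"].tolist()

    # -- programs ----------------------------------------------------------
    stage = "programs"
    t0 = time.time()
    try:
        mal_expr = expr.subset_cells(
            pd.Index(expr.cell_ids).get_indexer(malignant_cells)
        )
        sigs: list[programs.ProgramSignature] = []
        for patient in sorted(mal_expr.cell_meta["patient"].unique()):
            mask = (mal_expr.cell_meta["patient"] == patient).to_numpy()
            if mask.sum() < config.n_factors + 1:
                logger.warning("patient %s has too few malignant cells", patient)
                continue
            p_expr = mal_expr.subset_cells(mask)
            sigs += programs.nmf_programs(
                p_expr, patient, config.n_factors, config.n_genes_per_factor,
                seed=seeds[stage] % 2**31,
            )
        outputs = []
        if len(sigs) >= 2:
            metas, corr = programs.cluster_signatures(
                sigs, mal_expr, k=config.n_meta_programs, seed=seeds[stage] % 2**31
            )
            labels, mp_scores = programs.assign_programs(
                metas, mal_expr, seed=seeds[stage] % 2**31
            )
            gmt_path = out / "meta_programs.gmt"
            syndata.write_gmt({m.name: m.genes for m in metas}, gmt_path)
            lab_path = out / "program_assignments.tsv"
            labels.to_frame().join(mp_scores).to_csv(lab_path, sep="\t")
            corr_path = out / "signature_correlation.tsv"
            corr.to_csv(corr_path, sep="\t")
            outputs = [gmt_path, lab_path, corr_path]
        _finish(stage, t0, outputs, n_signatures=len(sigs))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- gene-set scoring --------------------------------------------------
    stage = "score"
    t0 = time.time()
    try:
        outputs = []
        if config.gmt_path:
            sets = syndata.read_gmt(config.gmt_path)
            cols = {}
            for i, (name, genes) in enumerate(sets.items()):
                cols[name] = signatures.module_score(
                    expr, genes, seed=(seeds[stage] + i) % 2**31
                )
            score_path = out / "module_scores.tsv"
            pd.DataFrame(cols).to_csv(score_path, sep="\t")
            outputs = [score_path]
        _finish(stage, t0, outputs, n_sets=len(outputs))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- ligand-receptor edges ---------------------------------------------
    stage = "edges"
    t0 = time.time()
    try:
        outputs = []
        if config.lr_pairs_path:
            pairs = interactions.read_lr_pairs(config.lr_pairs_path)
            edges = interactions.extract_edges(
                expr, calls["final_call"], pairs, config.detection_threshold
            )
            e_path = out / "edges.tsv"
            edges.to_csv(e_path, sep="\t", index=False)
            outputs = [e_path]
        _finish(stage, t0, outputs)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- drug prediction ---------------------------------------------------
    stage = "drugpred"
    t0 = time.time()
    try:
        outputs = []
        if config.panel_expr_path:
            panel = drugpred.DrugPanel(
                line_expression=pd.read_csv(config.panel_expr_path, index_col=0),
                response=pd.read_csv(config.panel_auc_path),
            )
            bulks = drugpred.pseudobulk_groups(
                expr, calls["final_call"].rename(None).map(
                    {"malignant": "malignant", "normal": "normal"}
                ),
                config.n_groups_per_class,
                seed=seeds[stage] % 2**31,
            )
            deg = signatures.deg_test(expr, malignant_cells, normal_cells)
            sig_genes = (
                deg[deg["log_fc"] > 0]
                .sort_values("adj_p_value")["gene"]
                .head(config.n_signature_genes)
                .tolist()
            )
            if not sig_genes:
                raise ValueError("no upregulated malignant signature genes found")
            tscore = drugpred.tumor_score(bulks, sig_genes, seed=seeds[stage] % 2**31)
            preds = drugpred.ridge_fit_predict(panel, bulks)
            report = drugpred.filter_candidates(preds, bulks.group_class, tscore)
            p_path = out / "drug_predictions.tsv"
            report.to_csv(p_path, sep="\t")
            outputs = [p_path]
            _finish(stage, t0, outputs, n_candidates=int(report["candidate"].sum()))
        else:
            _finish(stage, t0, outputs)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    record_path = out / "run_record.json"
    record_path.write_text(json.dumps(record, indent=2, default=str))
    return record
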