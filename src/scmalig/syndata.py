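"""Synthetic cohorts and cell-line drug panels with planted ground truth.

Counts are drawn from a gamma-Poisson (negative binomial) model around
per-cell per-gene rates. Malignant cells carry planted chromosome-level
copy-number multipliers, a shared malignant marker signature, and mixtures
of four expression programs whose weights move along a one-dimensional
latent progression (cell cycle -> mitochondria -> {metabolism | EMT}).
Cell-line panels reuse the same count model and attach drug AUC values that
depend linearly on planted target-gene expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from scmalig.matrix import MITO_PREFIX, CountMatrix
from scmalig.qc_norm import BARCODES_FILE, GENES_FILE, MTX_FILE, normalize_log

PROGRAM_NAMES = ("cell_cycle", "mitochondria", "metabolism", "emt")

POSITIONS_FILE = "gene_positions.tsv"
PROGRAMS_GMT = "programs.gmt"
PANEL_EXPR_FILE = "panel_expression.csv"
PANEL_AUC_FILE = "panel_response.csv"
TRUTH_CELLS_FILE = "truth_cells.tsv"
TRUTH_DRUGS_FILE = "truth_drugs.tsv"


@dataclass
class CohortConfig:
    """Parameters of a synthetic multi-patient cohort."""

    n_patients: int = 2
    n_cells_per_patient: int = 300
    n_genes: int = 2000
    n_chromosomes: int = 10
    malignant_fraction: float = 0.5
    cnv_events: list[tuple[str, str, float]] = field(default_factory=list)
    program_gene_sets: dict[str, list[str]] | None = None
    library_size_mean: int = 5000
    dispersion: float = 0.3
    mito_gene_fraction: float = 0.02
    seed: int = 0
    # signal strengths (not part of the minimal contract, but needed to
    # control how recoverable the planted structure is)
    program_loading: float = 1.5
    n_program_genes: int = 30
    n_marker_genes: int = 40
    marker_effect: float = 3.0
    normal_tissue_fraction: float = 0.5

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_cells_per_patient < 1:
            raise ValueError("need at least one patient and one cell per patient")
        if not 0 <= self.malignant_fraction <= 1:
            raise ValueError("malignant_fraction must be in [0, 1]")
        if not 0 <= self.mito_gene_fraction <= 1:
            raise ValueError("mito_gene_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for _, _, mult in self.cnv_events:
            if mult <= 0:
                raise ValueError("CNV multipliers must be positive")
        if self.program_gene_sets is not None:
            sets = list(self.program_gene_sets.values())
            if len(sets) != 4:
                raise ValueError("exactly four program gene sets are required")
            all_genes = [g for s in sets for g in s]
            if len(set(all_genes)) != len(all_genes):
                raise ValueError("program gene sets must be pairwise disjoint")
            if len(all_genes) > self.n_genes:
                raise ValueError("program gene sets exceed n_genes")


@dataclass
class GroundTruth:
    """Planted labels attached to a synthetic cohort or drug panel."""

    cell_class: pd.Series | None = None  # malignant / normal
    cell_type: pd.Series | None = None
    program_weights: pd.DataFrame | None = None  # cells x 4, simplex rows
    gene_positions: pd.DataFrame | None = None
    program_gene_sets: dict[str, list[str]] | None = None
    malignant_markers: list[str] | None = None
    drug_sensitive: pd.Series | None = None  # drug -> bool
    drug_effect: pd.Series | None = None  # drug -> beta
    drug_targets: dict[str, list[str]] | None = None


def _gene_universe(config: CohortConfig) -> tuple[list[str], pd.DataFrame]:
    """Gene names and a genome layout: mito genes live on chrM."""
    n_mito = int(round(config.n_genes * config.mito_gene_fraction))
    n_auto = config.n_genes - n_mito
    if n_auto < 2 * config.n_chromosomes:
        raise ValueError("chromosomes would have fewer than 2 genes each")
    if 0 < n_mito < 2:
        n_mito = 2  # chrM must hold >= 2 genes if it exists
        n_auto = config.n_genes - n_mito
    names = [f"G{i:05d}" for i in range(n_auto)]
    names += [f"{MITO_PREFIX}G{i:03d}" for i in range(n_mito)]
    chrom_of = np.array_split(np.arange(n_auto), config.n_chromosomes)
    chroms, starts = [], []
    for ci, block in enumerate(chrom_of):
        chroms += [f"chr{ci + 1}"] * len(block)
        starts += [1000 * k + 1 for k in range(len(block))]
    chroms += ["chrM"] * n_mito
    starts += [100 * k + 1 for k in range(n_mito)]
    positions = pd.DataFrame(
        {"chromosome": chroms, "start": starts}, index=pd.Index(names, name="gene")
    )
    return names, positions


def _progression_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Program weights along a piecewise-linear simplex path.

    Latent t in [0, 1]: cell cycle -> mitochondria on the first half, then
    mitochondria -> a random branch (metabolism or EMT) on the second half.
    """
    t = rng.uniform(0.0, 1.0, size=n)
    branch = rng.integers(0, 2, size=n)  # 0 = metabolism, 1 = emt
    w = np.zeros((n, 4))
    first = t <= 0.5
    w[first, 0] = 1.0 - 2.0 * t[first]
    w[first, 1] = 2.0 * t[first]
    sec = ~first
    w[sec, 1] = 2.0 - 2.0 * t[sec]
    w[sec, 2 + branch[sec]] = 2.0 * t[sec] - 1.0
    return w


def _nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mean`` and extra-Poisson dispersion."""
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = mean * rng.gamma(shape, dispersion, size=mean.shape)
    else:
        lam = mean
    return rng.poisson(lam)


def generate_cohort(
    config: CohortConfig,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Generate a cohort: counts, gene position table and ground truth.

    Per-cell rates start from shared lognormal base rates; malignant cells
    multiply genes on CNV-event chromosomes by the event multiplier, scale
    malignant marker genes by ``marker_effect`` and program genes by
    ``exp(weight * program_loading)``. Counts are gamma-Poisson around these
    rates, so planted mean ratios are exact in expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, positions = _gene_universe(config)
    gene_idx = pd.Index(genes)
    n_genes = len(genes)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base = base / base.sum() * config.library_size_mean

    non_mito = [g for g in genes if not g.startswith(MITO_PREFIX)]
    if config.program_gene_sets is None:
        pool = rng.permutation(len(non_mito))
        sets: dict[str, list[str]] = {}
        k = 0
        for name in PROGRAM_NAMES:
            sets[name] = [non_mito[i] for i in pool[k : k + config.n_program_genes]]
            k += config.n_program_genes
        markers = [non_mito[i] for i in pool[k : k + config.n_marker_genes]]
    else:
        sets = {n: list(g) for n, g in config.program_gene_sets.items()}
        used = {g for s in sets.values() for g in s}
        for g in used:
            if g not in gene_idx:
                raise ValueError(f"program gene {g!r} not in generated gene universe")
        avail = [g for g in non_mito if g not in used]
        markers = avail[: config.n_marker_genes]
    program_cols = {
        name: gene_idx.get_indexer(sets[name]) for name in sets
    }
    marker_cols = gene_idx.get_indexer(markers)

    patients = [f"P{p + 1}" for p in range(config.n_patients)]
    cell_ids, cell_patient, cell_class, cell_tissue = [], [], [], []
    weights_rows = []
    counts = np.zeros((n_genes, config.n_patients * config.n_cells_per_patient), np.int64)

    col = 0
    for patient in patients:
        n_mal = int(round(config.n_cells_per_patient * config.malignant_fraction))
        n_norm = config.n_cells_per_patient - n_mal
        w_mal = _progression_weights(n_mal, rng)
        events = [
            (chrom, mult)
            for (pat, chrom, mult) in config.cnv_events
            if pat == patient or pat == "*"
        ]
        mal_rate_base = base.copy()
        for chrom, mult in events:
            on_chrom = gene_idx.get_indexer(
                positions.index[positions["chromosome"] == chrom]
            )
            mal_rate_base[on_chrom] *= mult
        mal_rate_base[marker_cols] *= config.marker_effect

        mal_i = 0
        for i in range(config.n_cells_per_patient):
            is_mal = i < n_mal
            cid = f"{patient}_C{i:04d}"
            cell_ids.append(cid)
            cell_patient.append(patient)
            if is_mal:
                rate = mal_rate_base.copy()
                w = w_mal[mal_i]
                mal_i += 1
                for p_i, name in enumerate(sets):
                    rate[program_cols[name]] *= np.exp(w[p_i] * config.program_loading)
                weights_rows.append(w)
                cell_class.append("malignant")
                cell_tissue.append("tumor")
            else:
                rate = base
                weights_rows.append(np.zeros(4))
                cell_class.append("normal")
                # split normals between adjacent-normal and in-tumor tissue
                norm_rank = i - n_mal
                in_normal = norm_rank < int(round(n_norm * config.normal_tissue_fraction))
                cell_tissue.append("normal" if in_normal else "tumor")
            counts[:, col] = _nb_counts(rate, config.dispersion, rng)
            col += 1

    cell_index = pd.Index(cell_ids, name="cell")
    meta = pd.DataFrame(
        {
            "patient": cell_patient,
            "tissue": cell_tissue,
            "platform": "STRT",
        },
        index=cell_index,
    )
    count_matrix = CountMatrix(
        values=sp.csr_matrix(counts),
        gene_ids=genes,
        cell_ids=cell_ids,
        cell_meta=meta,
    )
    truth = GroundTruth(
        cell_class=pd.Series(cell_class, index=cell_index, name="true_class"),
        cell_type=pd.Series("epithelial", index=cell_index, name="cell_type"),
        program_weights=pd.DataFrame(
            np.vstack(weights_rows), index=cell_index, columns=list(sets)
        ),
        gene_positions=positions,
        program_gene_sets=sets,
        malignant_markers=markers,
    )
    return count_matrix, positions.reset_index(), truth


def generate_drug_panel(
    n_lines: int,
    n_genes: int,
    drugs: list[str],
    planted_sensitive: list[str],
    effect_size: float = -1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    gene_names: list[str] | None = None,
    signal_genes: list[str] | None = None,
    target_genes: dict[str, list[str]] | None = None,
    n_targets: int = 10,
    intercept: float = 1.0,
    signal_loading: float = 2.0,
    library_size_mean: int = 5000,
    dispersion: float = 0.3,
    source: str = "synthetic",
):
    """Generate a cell-line panel: expression plus linear-in-targets AUC.

    Each line has a latent load u ~ U(0,1) that scales ``signal_genes`` by
    ``exp(u * signal_loading)``; counts are gamma-Poisson and log-normalized.
    ``AUC(drug, line) = intercept + beta * mean(target expression) + noise``
    with ``beta = effect_size`` for planted-sensitive drugs and 0 otherwise.

    Returns ``(DrugPanel, GroundTruth)``.
    """
    from scmalig.drugpred import DrugPanel

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    unknown = set(planted_sensitive) - set(drugs)
    if unknown:
        raise ValueError(f"planted_sensitive drugs not in drug list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    if gene_names is None:
        gene_names = [f"G{i:05d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    gene_idx = pd.Index(gene_names)
    if signal_genes is None:
        signal_genes = list(rng.choice(gene_names, size=min(60, n_genes), replace=False))
    sig_cols = gene_idx.get_indexer(signal_genes)
    if np.any(sig_cols < 0):
        raise ValueError("signal_genes must be a subset of the panel gene universe")

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base = base / base.sum() * library_size_mean
    load = rng.uniform(0.0, 1.0, size=n_lines)
    counts = np.zeros((n_genes, n_lines), np.int64)
    for l in range(n_lines):
        rate = base.copy()
        rate[sig_cols] *= np.exp(load[l] * signal_loading)
        counts[:, l] = _nb_counts(rate, dispersion, rng)
    line_ids = [f"LINE{l:04d}" for l in range(n_lines)]
    cm = CountMatrix(values=sp.csr_matrix(counts), gene_ids=gene_names, cell_ids=line_ids)
    expr = normalize_log(cm).to_frame()  # genes x lines

    if target_genes is None:
        target_genes = {}
    target_genes = {d: list(g) for d, g in target_genes.items()}
    for drug in drugs:
        if drug not in target_genes:
            pool = signal_genes if drug in planted_sensitive else gene_names
            target_genes[drug] = list(
                rng.choice(pool, size=min(n_targets, len(pool)), replace=False)
            )

    rows = []
    betas = {}
    for drug in drugs:
        beta = effect_size if drug in planted_sensitive else 0.0
        betas[drug] = beta
        tcols = gene_idx.get_indexer(target_genes[drug])
        tmean = expr.values[tcols, :].mean(axis=0)
        noise = rng.normal(0.0, noise_sd, size=n_lines) if noise_sd > 0 else 0.0
        auc = intercept + beta * tmean + noise
        for l, line in enumerate(line_ids):
            rows.append((drug, line, float(np.atleast_1d(auc)[l])))
    response = pd.DataFrame(rows, columns=["drug", "line", "auc"])
    panel = DrugPanel(line_expression=expr, response=response, source=source)
    truth = GroundTruth(
        drug_sensitive=pd.Series(
            {d: d in planted_sensitive for d in drugs}, name="sensitive"
        ),
        drug_effect=pd.Series(betas, name="beta"),
        drug_targets=target_genes,
    )
    return panel, truth


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_fixture(
    counts: CountMatrix,
    positions: pd.DataFrame,
    truth: GroundTruth,
    directory: str | Path,
    panel=None,
    panel_truth: GroundTruth | None = None,
) -> list[Path]:
    """Write a cohort (and optional panel) as plain-text fixture files."""
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    mtx = directory / MTX_FILE
    scipy.io.mmwrite(str(mtx), counts.values.tocoo(), field="integer")
    written.append(mtx)

    genes_path = directory / GENES_FILE
    genes_path.write_text("\n".join(counts.gene_ids) + "\n")
    written.append(genes_path)

    barcodes_path = directory / BARCODES_FILE
    counts.cell_meta.to_csv(barcodes_path, sep="\t")
    written.append(barcodes_path)

    pos_path = directory / POSITIONS_FILE
    pos = positions if "gene" in positions.columns else positions.reset_index()
    pos.to_csv(pos_path, sep="\t", index=False)
    written.append(pos_path)

    if truth.program_gene_sets:
        gmt_path = directory / PROGRAMS_GMT
        sets = dict(truth.program_gene_sets)
        if truth.malignant_markers:
            sets["malignant_markers"] = list(truth.malignant_markers)
        write_gmt(sets, gmt_path)
        written.append(gmt_path)

    if truth.cell_class is not None:
        t_path = directory / TRUTH_CELLS_FILE
        tdf = pd.DataFrame({"true_class": truth.cell_class})
        if truth.program_weights is not None:
            tdf = tdf.join(truth.program_weights)
        tdf.to_csv(t_path, sep="\t")
        written.append(t_path)

    if panel is not None:
        e_path = directory / PANEL_EXPR_FILE
        panel.line_expression.to_csv(e_path)
        written.append(e_path)
        a_path = directory / PANEL_AUC_FILE
        panel.response.to_csv(a_path, index=False)
        written.append(a_path)
        if panel_truth is not None and panel_truth.drug_sensitive is not None:
            d_path = directory / TRUTH_DRUGS_FILE
            pd.DataFrame(
                {
                    "sensitive": panel_truth.drug_sensitive,
                    "beta": panel_truth.drug_effect,
                }
            ).to_csv(d_path, sep="\t", index_label="drug")
            written.append(d_path)
    return written


def read_positions(path: str | Path) -> pd.DataFrame:
    pos = pd.read_csv(path, sep="\t")
    required = {"gene", "chromosome", "start"}
    if not required.issubset(pos.columns):
        raise ValueError(f"gene position table needs columns {sorted(required)}")
    return pos.set_index("gene")
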