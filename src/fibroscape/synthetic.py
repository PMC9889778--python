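"""Synthetic single-cell, pseudobulk and survival cohorts with planted truth.

Every generator emulates the statistical structure the downstream analyses
assume, so each stage of the pipeline can be validated against known ground
truth without any external download:

* negative-binomial counts with gene-level dispersion (variance
  ``mu + mu**2 / theta``);
* multiplicative per-patient batch effects on a random subset of genes;
* planted cell-type signatures with a configurable log2 fold change;
* a bifurcating differentiation trajectory (two progenitor branches
  converging on one terminal state) carrying temporally ordered gene
  modules;
* survival cohorts with a planted log hazard ratio on a continuous score.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellMatrix

__all__ = [
    "CohortConfig",
    "TrajectoryConfig",
    "SurvivalConfig",
    "CellTypeSpec",
    "ModuleSpec",
    "generate_cohort",
    "generate_trajectory_dataset",
    "generate_survival_cohort",
]


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass
class CellTypeSpec:
    """One planted cell type: its frequency and expression signature."""

    name: str
    proportion: float
    signature_genes: int = 30
    signature_log2fc: float = 1.5


@dataclass
class CohortConfig:
    """Parameters of a multi-patient scRNA-seq cohort simulation.

    ``batch_sd`` is the standard deviation (log2 scale) of the
    multiplicative per-patient effect applied to a random 30% of genes.
    ``dispersion`` is the NB inverse-dispersion theta; variance is
    ``mu + mu**2 / theta``.
    """

    n_patients: int = 12
    cells_per_patient: int = 500
    n_genes: int = 2000
    cell_type_spec: list[CellTypeSpec] = field(
        default_factory=lambda: [
            CellTypeSpec("adventitial", 0.4, 30, 1.5),
            CellTypeSpec("alveolar", 0.35, 30, 1.5),
            CellTypeSpec("myofibroblast", 0.25, 30, 1.5),
        ]
    )
    batch_sd: float = 0.5
    batch_gene_frac: float = 0.30
    dispersion: float = 10.0
    lib_size_mean: int = 5000
    lib_size_sd_log: float = 0.3
    tissue_assignment: dict[str, str] | None = None
    seed: int = 0

    def validate(self) -> None:
        props = [t.proportion for t in self.cell_type_spec]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"cell type proportions sum to {sum(props)}, expected 1")
        if min(self.n_patients, self.cells_per_patient, self.n_genes, self.lib_size_mean) <= 0:
            raise ValueError("all counts must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        names = [t.name for t in self.cell_type_spec]
        if len(set(names)) != len(names):
            raise ValueError("cell type names must be unique")


@dataclass
class ModuleSpec:
    """A pseudotime gene module active within a window of pseudotime."""

    name: str
    genes: int
    activation_window: tuple[float, float]
    amplitude_log2fc: float = 1.5

    def validate(self) -> None:
        lo, hi = self.activation_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"module {self.name!r}: require 0 <= t_lo < t_hi <= 1")


@dataclass
class TrajectoryConfig:
    """Bifurcating trajectory simulation: two progenitor branches (A, B)
    converge on a shared terminal state; four temporally ordered modules by
    default (progenitor, early-activation, proto-differentiation,
    differentiation)."""

    n_cells: int = 600
    n_genes: int = 1500
    module_spec: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec("progenitor", 50, (0.0, 0.4), 1.5),
            ModuleSpec("early-activation", 50, (0.15, 0.6), 1.5),
            ModuleSpec("proto-differentiation", 50, (0.4, 0.85), 1.5),
            ModuleSpec("differentiation", 50, (0.6, 1.0), 1.5),
        ]
    )
    branch_genes: int = 40
    branch_log2fc: float = 2.0
    terminal_t: float = 0.75
    n_patients: int = 6
    batch_sd: float = 0.3
    batch_gene_frac: float = 0.30
    dispersion: float = 10.0
    lib_size_mean: int = 5000
    lib_size_sd_log: float = 0.3
    n_datasets: int = 3
    tumour_shift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for m in self.module_spec:
            m.validate()
        names = [m.name for m in self.module_spec]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")
        total = sum(m.genes for m in self.module_spec) + 2 * self.branch_genes
        if total > self.n_genes:
            raise ValueError("module + branch genes exceed n_genes (sets must be disjoint)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


@dataclass
class SurvivalConfig:
    """Survival cohort with a planted log hazard ratio per unit of a
    continuous score in [0, 100]. Baseline event times are Weibull
    (shape, scale in months); censoring is the minimum of an
    administrative horizon and a uniform random censoring draw."""

    n_subjects: int = 500
    score_mean: float = 50.0
    score_sd: float = 15.0
    log_hazard_per_unit: float = 0.02
    baseline_shape: float = 1.2
    baseline_scale: float = 60.0
    censor_time: float = 120.0
    #: optional step-hazard model: subjects with score above step_cutpoint
    #: get hazard multiplied by exp(step_log_hr) instead of the linear term
    step_cutpoint: float | None = None
    step_log_hr: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and scale must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------
def _base_means(rng: np.random.Generator, n_genes: int, lib_size_mean: float) -> np.ndarray:
    """Relative gene abundances (lognormal) scaled to the mean library size."""
    w = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    return lib_size_mean * w / w.sum()


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB draw parameterized by mean and inverse-dispersion theta."""
    p = theta / (theta + np.maximum(mean, 1e-12))
    return rng.negative_binomial(theta, p)


def _patient_batch_log2(
    rng: np.random.Generator, n_genes: int, n_patients: int, sd: float, gene_frac: float
) -> np.ndarray:
    """Per-patient log2 multiplicative effects on a random subset of genes."""
    eff = np.zeros((n_patients, n_genes))
    if sd <= 0:
        return eff
    n_hit = int(round(gene_frac * n_genes))
    for p in range(n_patients):
        hit = rng.choice(n_genes, size=n_hit, replace=False)
        eff[p, hit] = rng.normal(0.0, sd, size=n_hit)
    return eff


def _default_tissues(patients: list[str]) -> dict[str, str]:
    cycle = ["control", "LUAD", "LUSC"]
    return {p: cycle[i % 3] for i, p in enumerate(patients)}


# ----------------------------------------------------------------------
# cohort generator
# ----------------------------------------------------------------------
def generate_cohort(config: CohortConfig) -> CellMatrix:
    """Simulate a multi-patient cohort with planted cell-type signatures.

    Per-gene NB mean is ``base_mean * 2**(signature lfc if the gene belongs
    to the cell's type signature) * 2**(patient batch effect) * library-size
    factor``. Truth labels land in ``cell_meta['true_type']``; the planted
    signature gene lists in ``uns['signature_genes']``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    genes = [f"G{i:05d}" for i in range(n_genes)]

    base = _base_means(rng, n_genes, config.lib_size_mean)

    # disjoint signature blocks, assigned from the most expressed genes so
    # planted fold changes are detectable above shot noise
    order = np.argsort(base)[::-1]
    sig_genes: dict[str, np.ndarray] = {}
    cursor = 0
    for t in config.cell_type_spec:
        sig_genes[t.name] = np.sort(order[cursor : cursor + t.signature_genes])
        cursor += t.signature_genes
    if cursor > n_genes:
        raise ValueError("signature genes exceed n_genes")

    patients = [f"P{i:02d}" for i in range(config.n_patients)]
    tissues = config.tissue_assignment or _default_tissues(patients)
    batch = _patient_batch_log2(
        rng, n_genes, config.n_patients, config.batch_sd, config.batch_gene_frac
    )

    n_cells = config.n_patients * config.cells_per_patient
    props = np.array([t.proportion for t in config.cell_type_spec])
    type_names = [t.name for t in config.cell_type_spec]
    type_of_cell = rng.choice(len(type_names), size=n_cells, p=props)
    lib = rng.lognormal(0.0, config.lib_size_sd_log, size=n_cells)

    type_lfc = np.zeros((len(type_names), n_genes))
    for ti, t in enumerate(config.cell_type_spec):
        type_lfc[ti, sig_genes[t.name]] = t.signature_log2fc

    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    meta_rows = []
    cell = 0
    for pi, pat in enumerate(patients):
        for _ in range(config.cells_per_patient):
            ti = type_of_cell[cell]
            log2mu = np.log2(base) + type_lfc[ti] + batch[pi]
            mu = np.exp2(log2mu) * lib[cell]
            counts[:, cell] = _nb_sample(rng, mu, config.dispersion)
            meta_rows.append(
                {
                    "cell_id": f"{pat}_C{cell:05d}",
                    "patient_id": pat,
                    "sample_id": pat,
                    "tissue_type": tissues[pat],
                    "dataset_id": "sim",
                    "true_type": type_names[ti],
                }
            )
            cell += 1

    meta = pd.DataFrame(meta_rows)
    uns = {"signature_genes": {k: [genes[i] for i in v] for k, v in sig_genes.items()}}
    return CellMatrix(counts=counts, genes=genes, cell_meta=meta, uns=uns)


# ----------------------------------------------------------------------
# trajectory generator
# ----------------------------------------------------------------------
def _bump(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth unimodal activation profile supported on [lo, hi].

    Interior windows are raised-cosine bumps peaking at the midpoint.
    Windows touching a pseudotime boundary become monotone half-bumps
    (full amplitude at the boundary), so the progenitor module is ON at
    t = 0 and the differentiation module is ON at t = 1 — the endpoint
    states must differ for the trajectory to have two distinguishable ends.
    """
    x = np.clip((t - lo) / (hi - lo), 0.0, 1.0)
    if lo <= 0.0 < hi < 1.0:
        out = 0.5 * (1.0 + np.cos(np.pi * x))  # decays from 1 at t=0
    elif hi >= 1.0 > lo > 0.0:
        out = 0.5 * (1.0 - np.cos(np.pi * x))  # rises to 1 at t=1
    else:
        out = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
    out = out.copy()
    out[(t < lo) | (t > hi)] = 0.0
    return out


def generate_trajectory_dataset(config: TrajectoryConfig) -> list[CellMatrix]:
    """Simulate ``n_datasets`` replicate cohorts of a bifurcating trajectory.

    Cells carry ``true_pseudotime`` (uniform on [0, 1] per branch) and
    ``true_branch`` (``branchA``/``branchB`` for cells before the
    convergence point ``terminal_t``, ``terminal`` after it). Module genes
    have their NB mean multiplied by ``2**(amplitude * bump(t))`` inside
    their activation window; branch marker genes by
    ``2**(branch_lfc * (1 - t))`` on their own branch so the branches
    converge at the terminal state. Gene-level module truth sits in
    ``uns['module_genes']``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base = _base_means(rng, n_genes, config.lib_size_mean)

    order = np.argsort(base)[::-1]
    cursor = 0
    module_idx: dict[str, np.ndarray] = {}
    for m in config.module_spec:
        module_idx[m.name] = np.sort(order[cursor : cursor + m.genes])
        cursor += m.genes
    branch_idx = {
        "branchA": np.sort(order[cursor : cursor + config.branch_genes]),
        "branchB": np.sort(order[cursor + config.branch_genes : cursor + 2 * config.branch_genes]),
    }

    uns_modules = {k: [genes[i] for i in v] for k, v in module_idx.items()}
    datasets: list[CellMatrix] = []
    for d in range(config.n_datasets):
        drng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        patients = [f"D{d}_P{i:02d}" for i in range(config.n_patients)]
        tissues = {
            p: ("control" if i < config.n_patients // 2 else "LUAD")
            for i, p in enumerate(patients)
        }
        batch = _patient_batch_log2(
            drng, n_genes, config.n_patients, config.batch_sd, config.batch_gene_frac
        )

        n = config.n_cells
        t = drng.uniform(0.0, 1.0, size=n)
        branch = np.where(drng.random(n) < 0.5, "branchA", "branchB")
        pat_of_cell = drng.integers(0, config.n_patients, size=n)
        # tumour-tissue cells sit later in pseudotime when a shift is requested
        if config.tumour_shift > 0:
            is_tum = np.array([tissues[patients[p]] != "control" for p in pat_of_cell])
            t[is_tum] = np.clip(t[is_tum] + config.tumour_shift * drng.random(is_tum.sum()), 0, 1)
        lib = drng.lognormal(0.0, config.lib_size_sd_log, size=n)

        log2mod = np.zeros((n, n_genes))
        for m in config.module_spec:
            lo, hi = m.activation_window
            log2mod[:, module_idx[m.name]] += (
                m.amplitude_log2fc * _bump(t, lo, hi)[:, None]
            )
        # branch-identity genes stay near-full through the first half of the
        # branch, then decay smoothly to zero at the convergence point, so
        # cells past terminal_t share one terminal state while branch
        # membership stays detectable up to it
        hold = 0.5 * config.terminal_t
        for bname, idx in branch_idx.items():
            on = branch == bname
            x = np.clip((t[on] - hold) / (config.terminal_t - hold), 0.0, 1.0)
            fade = 0.5 * (1.0 + np.cos(np.pi * x))
            log2mod[np.ix_(on, idx)] += config.branch_log2fc * fade[:, None]

        counts = np.empty((n_genes, n), dtype=np.int64)
        for c in range(n):
            mu = np.exp2(np.log2(base) + log2mod[c] + batch[pat_of_cell[c]]) * lib[c]
            counts[:, c] = _nb_sample(drng, mu, config.dispersion)

        true_branch = np.where(t >= config.terminal_t, "terminal", branch)
        meta = pd.DataFrame(
            {
                "cell_id": [f"D{d}_C{i:05d}" for i in range(n)],
                "patient_id": [patients[p] for p in pat_of_cell],
                "sample_id": [patients[p] for p in pat_of_cell],
                "tissue_type": [tissues[patients[p]] for p in pat_of_cell],
                "dataset_id": f"dataset_{d}",
                "true_pseudotime": t,
                "true_branch": true_branch,
            }
        )
        datasets.append(
            CellMatrix(counts=counts, genes=genes, cell_meta=meta, uns={"module_genes": uns_modules})
        )
    return datasets


# ----------------------------------------------------------------------
# survival generator
# ----------------------------------------------------------------------
def generate_survival_cohort(config: SurvivalConfig) -> pd.DataFrame:
    """Simulate a survival table with a planted proportional hazard on a score.

    Event times follow a Weibull proportional-hazards model: the subject
    hazard is the baseline hazard multiplied by
    ``exp(log_hazard_per_unit * score)``. Returns columns
    ``subject_id, time_months, event, score, age, stage``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    score = np.clip(rng.normal(config.score_mean, config.score_sd, size=n), 0.0, 100.0)
    if config.step_cutpoint is not None:
        hr = np.exp(np.where(score > config.step_cutpoint, config.step_log_hr, 0.0))
    else:
        hr = np.exp(config.log_hazard_per_unit * score)
    u = rng.uniform(0.0, 1.0, size=n)
    # inverse-CDF of Weibull PH: S(t) = exp(-(t/scale)^shape * hr)
    t_event = config.baseline_scale * (-np.log(u) / hr) ** (1.0 / config.baseline_shape)
    c_rand = rng.uniform(0.0, 2.0 * config.censor_time, size=n)
    t_cens = np.minimum(config.censor_time, c_rand)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)  # time strictly positive
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "time_months": time,
            "event": event,
            "score": score,
            "age": np.round(rng.normal(65.0, 8.0, size=n)).astype(int),
            "stage": rng.integers(1, 5, size=n),
        }
    )


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------
def write_cohort(cm: CellMatrix, outdir, fmt: str = "mtx") -> None:
    """Write counts (MTX + genes.tsv + barcodes.tsv, or a dense CSV) and
    cell metadata TSV under ``outdir``."""
    import os

    import scipy.io as sio
    import scipy.sparse as sp

    os.makedirs(outdir, exist_ok=True)
    if fmt == "mtx":
        sio.mmwrite(os.path.join(outdir, "counts.mtx"), sp.csr_matrix(cm.counts))
        with open(os.path.join(outdir, "genes.tsv"), "w") as fh:
            fh.write("\n".join(cm.genes) + "\n")
        with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(cm.cell_meta["cell_id"].astype(str)) + "\n")
    elif fmt == "csv":
        dense = cm.counts.toarray() if sp.issparse(cm.counts) else cm.counts
        pd.DataFrame(dense, index=cm.genes, columns=cm.cell_meta["cell_id"]).to_csv(
            os.path.join(outdir, "counts.csv")
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    cm.cell_meta.to_csv(os.path.join(outdir, "cell_meta.tsv"), sep="\t", index=False)


def read_cohort(indir) -> CellMatrix:
    """Read a cohort previously written by :func:`write_cohort`."""
    import os

    import scipy.io as sio

    meta = pd.read_csv(os.path.join(indir, "cell_meta.tsv"), sep="\t")
    mtx = os.path.join(indir, "counts.mtx")
    if os.path.exists(mtx):
        counts = sio.mmread(mtx).tocsr()
        with open(os.path.join(indir, "genes.tsv")) as fh:
            genes = [ln.strip() for ln in fh if ln.strip()]
    else:
        df = pd.read_csv(os.path.join(indir, "counts.csv"), index_col=0)
        counts = df.to_numpy()
        genes = list(df.index)
    return CellMatrix(counts=counts, genes=genes, cell_meta=meta)
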