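"""Negative-binomial count simulator with planted tissue-specific markers.

Generates multi-class, two-cohort gene-level count datasets with the
statistical structure the marker analysis assumes: log-normal baseline gene
means, a single NB dispersion (var = mu + alpha mu^2), log-normal
library-size variation, planted target-class markers (mean multiplied by a
fold factor in both cohorts), confounder genes upregulated in one random
non-target class, and a validation cohort of target-tissue samples whose
per-gene baselines carry a log-normal batch shift emulating cultured cells.

The default design mirrors a five-class ocular-surface study: target n=8,
controls n=8/12/7/7, six validation samples, 2000 genes with 50 markers at
fold 8 and 50 confounders, dispersion 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix, SampleSheet, COHORT_TRAINING, COHORT_VALIDATION

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_dataset", "evaluate_recovery"]

DEFAULT_CLASSES = (
    ("pterygium", 8),
    ("healthy_conjunctiva", 8),
    ("melanoma", 12),
    ("scc", 7),
    ("papilloma", 7),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    ``classes`` lists (label, n_samples) for the training cohort; the first
    label is the target class unless ``target_class`` overrides it.
    ``marker_fold`` multiplies the target-class mean of planted markers (and
    the chosen class mean of confounders).  ``validation_batch_log_sd`` is
    the SD of the per-gene log-normal baseline shift applied to the
    validation cohort.
    """

    n_genes: int = 2000
    classes: tuple = DEFAULT_CLASSES
    target_class: str = "pterygium"
    n_validation: int = 6
    n_markers: int = 50
    marker_fold: float = 8.0
    n_background_de: int = 50
    baseline_log_mean: float = 4.0   # natural-log scale
    baseline_log_sd: float = 1.5
    dispersion: float = 0.1
    libsize_log_sd: float = 0.3
    validation_batch_log_sd: float = 0.5
    library_factors: tuple | None = None  # explicit per-sample factors
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [c for c, _ in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate class labels")
        if self.target_class not in labels:
            raise ValueError(f"target class {self.target_class!r} not in classes")
        if self.n_markers + self.n_background_de > self.n_genes:
            raise ValueError("n_markers + n_background_de exceeds n_genes")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if self.n_genes <= 0 or any(n <= 0 for _, n in self.classes):
            raise ValueError("gene and sample counts must be positive")
        if self.dispersion < 0 or self.libsize_log_sd < 0 or self.validation_batch_log_sd < 0:
            raise ValueError("dispersion and log-SDs must be non-negative")
        if self.library_factors is not None:
            total = sum(n for _, n in self.classes) + self.n_validation
            lf = tuple(float(f) for f in self.library_factors)
            if len(lf) != total:
                raise ValueError(
                    f"library_factors must have one entry per sample ({total})"
                )
            if any(f <= 0 for f in lf):
                raise ValueError("library_factors must be positive")
            object.__setattr__(self, "library_factors", lf)


@dataclass
class SimulationTruth:
    """Planted-marker ledger the recovery metrics are scored against."""

    marker_gene_ids: list[str]
    background_de_ids: list[str]
    class_means: pd.DataFrame          # gene x class true means (training)
    validation_means: pd.Series        # gene-wise true validation means
    library_factors: pd.Series         # per-sample true scaling, both cohorts
    target_class: str = "pterygium"

    def __post_init__(self) -> None:
        overlap = set(self.marker_gene_ids) & set(self.background_de_ids)
        if overlap:
            raise ValueError(f"marker and confounder sets overlap: {sorted(overlap)}")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with var = mu + alpha mu^2; Poisson when alpha == 0."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if alpha == 0:
        out[pos] = rng.poisson(mu[pos])
        return out
    size = 1.0 / alpha
    p = size / (size + mu[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, SampleSheet, SimulationTruth]:
    """Generate (train, validation, sheet, truth), reproducible from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels = [c for c, _ in cfg.classes]
    n_per = dict(cfg.classes)
    gene_ids = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)

    special = rng.choice(cfg.n_genes, cfg.n_markers + cfg.n_background_de, replace=False)
    marker_idx = np.sort(special[: cfg.n_markers])
    confound_idx = np.sort(special[cfg.n_markers:])

    class_means = np.tile(baseline[:, None], (1, len(labels)))
    tcol = labels.index(cfg.target_class)
    class_means[marker_idx, tcol] *= cfg.marker_fold
    nontarget_cols = [j for j in range(len(labels)) if j != tcol]
    if len(confound_idx) and nontarget_cols:
        which = rng.choice(nontarget_cols, size=len(confound_idx))
        class_means[confound_idx, which] *= cfg.marker_fold

    # training cohort; explicit library_factors (training in class order,
    # then validation) override the log-normal draws
    fixed_lib = iter(cfg.library_factors) if cfg.library_factors is not None else None
    train_cols, train_ids, train_rows = [], [], []
    lib_factors = {}
    for j, lab in enumerate(labels):
        for i in range(n_per[lab]):
            sid = f"{lab}_{i + 1:02d}"
            lib = (next(fixed_lib) if fixed_lib is not None
                   else rng.lognormal(0.0, cfg.libsize_log_sd))
            lib_factors[sid] = lib
            train_cols.append(_nb_draw(rng, class_means[:, j] * lib, cfg.dispersion))
            train_ids.append(sid)
            train_rows.append((sid, lab, COHORT_TRAINING))
    train_counts = np.column_stack(train_cols)

    # validation cohort: target-class cultured-cell samples with per-gene
    # batch shift on the baseline; markers keep their fold on top
    batch = rng.lognormal(0.0, cfg.validation_batch_log_sd, cfg.n_genes)
    val_means = class_means[:, tcol] * batch
    val_cols, val_ids, val_rows = [], [], []
    for i in range(cfg.n_validation):
        sid = f"{cfg.target_class}_val_{i + 1:02d}"
        lib = (next(fixed_lib) if fixed_lib is not None
               else rng.lognormal(0.0, cfg.libsize_log_sd))
        lib_factors[sid] = lib
        val_cols.append(_nb_draw(rng, val_means * lib, cfg.dispersion))
        val_ids.append(sid)
        val_rows.append((sid, cfg.target_class, COHORT_VALIDATION))
    val_counts = (
        np.column_stack(val_cols) if val_cols
        else np.zeros((cfg.n_genes, 0), dtype=np.int64)
    )

    lengths = rng.integers(500, 5001, cfg.n_genes)
    train = CountMatrix(gene_ids, train_ids, train_counts, lengths)
    validation = CountMatrix(gene_ids, val_ids, val_counts, lengths)

    frame = pd.DataFrame(
        train_rows + val_rows, columns=["sample_id", "tissue_class", "cohort"]
    ).set_index("sample_id")
    sheet = SampleSheet(frame, cfg.target_class)

    truth = SimulationTruth(
        marker_gene_ids=[gene_ids[i] for i in marker_idx],
        background_de_ids=[gene_ids[i] for i in confound_idx],
        class_means=pd.DataFrame(class_means, index=gene_ids, columns=labels),
        validation_means=pd.Series(val_means, index=gene_ids, name="validation_mean"),
        library_factors=pd.Series(lib_factors, name="library_factor"),
        target_class=cfg.target_class,
    )
    return train, validation, sheet, truth


def evaluate_recovery(truth: SimulationTruth, called) -> dict:
    """Score a called gene set against the planted markers.

    sensitivity = |called ∩ markers| / |markers|;
    fdr = |called \\ markers| / max(|called|, 1).
    """
    called = set(called)
    markers = set(truth.marker_gene_ids)
    tp = len(called & markers)
    fp = len(called - markers)
    fn = len(markers - called)
    sensitivity = tp / len(markers) if markers else 0.0
    fdr = fp / max(len(called), 1)
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_called": len(called),
        "n_markers": len(markers),
        "confounders_called": len(called & set(truth.background_de_ids)),
    }
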