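"""Synthetic multi-sample single-cell and bulk cohorts with known ground truth.

The generator emulates the statistical structure of a two-group (primary
tumor ``PT`` vs brain metastasis ``BM``) single-cell study: several tumor
samples per group, cluster-specific marker genes, mitochondrial and
hemoglobin gene families recognizable by name, group-specific cell-type
composition, group-specific within-tumor expression dispersion, and
ligand-receptor co-expression restricted to chosen cluster pairs.  Counts
follow a gamma-Poisson (negative binomial) model with per-sample gene-level
random effects and per-cell lognormal noise whose spread is multiplied by a
group-specific dispersion factor — the quantity the heterogeneity statistic
is designed to recover.

Every draw is governed by a single :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``; identical configurations produce bit-identical
output.  Ground truth (marker assignments, planted ligand-receptor pairs,
group dispersions, informative response genes) is returned as a plain dict
and can be serialized to JSON next to the matrices, so downstream tests read
planted truth from the artifact rather than from generator internals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

GROUPS = ("PT", "BM")


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic two-group single-cell study.

    Defaults describe the desk-scale study conditions used throughout the
    test-suite and analysis scripts: 10 tumors per group, 200 cells per
    tumor, 1,000 genes, 4 cell clusters with 20 markers each boosted by
    log2FC 2, and a 2:1 PT:BM within-tumor dispersion ratio (the primary
    group contrast the heterogeneity statistic recovers).
    """

    n_samples_per_group: int = 10
    n_cells_per_sample: int = 200
    n_genes: int = 1000
    n_clusters: int = 4
    markers_per_cluster: int = 20
    marker_logfc: float = 2.0
    dispersion_by_group: dict[str, float] = field(
        default_factory=lambda: {"PT": 2.0, "BM": 1.0}
    )
    mito_gene_count: int = 10
    hemo_gene_count: int = 5
    lr_pairs_planted: list[tuple[str, str, str, str]] = field(default_factory=list)
    response_informative_genes: int = 10
    seed: int = 0
    # Secondary knobs: fixed study conditions rather than per-run dials.
    composition_shift: float = 0.6
    base_mean: float = 3.0
    nb_dispersion: float = 0.25
    cell_sigma: float = 0.25
    sample_sigma: float = 0.10
    lr_high_mean: float = 8.0
    lr_low_mean: float = 0.02
    response_effect_sd: float = 2.0
    cohort_samples: int = 60

    def validate(self) -> None:
        for name in (
            "n_samples_per_group",
            "n_cells_per_sample",
            "n_genes",
            "n_clusters",
            "markers_per_cluster",
        ):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be a positive integer")
        if self.mito_gene_count < 0 or self.hemo_gene_count < 0:
            raise SimConfigError("mito/hemo gene counts must be non-negative")
        if self.response_informative_genes < 0:
            raise SimConfigError("response_informative_genes must be non-negative")
        n_special = self.mito_gene_count + self.hemo_gene_count
        if self.markers_per_cluster * self.n_clusters > self.n_genes - n_special:
            raise SimConfigError(
                "markers_per_cluster * n_clusters exceeds available gene universe"
            )
        for g in self.dispersion_by_group:
            if g not in GROUPS:
                raise SimConfigError(f"unknown group {g!r}; expected one of {GROUPS}")
            if self.dispersion_by_group[g] <= 0:
                raise SimConfigError("dispersion multipliers must be positive")
        universe = set(self.gene_names())
        clusters = set(self.cluster_names())
        for lig, rec, src, tgt in self.lr_pairs_planted:
            if lig not in universe or rec not in universe:
                raise SimConfigError(f"planted LR genes {lig}/{rec} not in gene universe")
            if src not in clusters or tgt not in clusters:
                raise SimConfigError(f"planted LR clusters {src}/{tgt} unknown")

    def gene_names(self) -> list[str]:
        """Mitochondrial genes first (``MT-``), then hemoglobin (``HB``), then generic."""
        names = [f"MT-SIM{i + 1}" for i in range(self.mito_gene_count)]
        names += [f"HB{i + 1}" for i in range(self.hemo_gene_count)]
        n_rest = self.n_genes - len(names)
        names += [f"G{i + 1:04d}" for i in range(n_rest)]
        return names

    def cluster_names(self) -> list[str]:
        return [f"C{i}" for i in range(self.n_clusters)]


def _composition_probs(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Group-specific cluster proportions; ``composition_shift=0`` is uniform."""
    w = (1.0 + cfg.composition_shift) ** np.arange(cfg.n_clusters, dtype=float)
    pt = w / w.sum()
    bm = w[::-1] / w.sum()
    return {"PT": pt, "BM": bm}


def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, dict]:
    """Draw a multi-sample count matrix plus annotation and its truth record.

    Returns an :class:`anndata.AnnData` with sparse integer counts in ``X``
    and per-cell ``sample``, ``group`` and ``cluster`` columns in ``obs``,
    together with a JSON-serializable truth dict.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    clusters = config.cluster_names()

    # Gene baseline means: lognormal across genes; mito elevated, hemo low,
    # mirroring the typical share of mitochondrial vs hemoglobin reads.
    base = rng.lognormal(mean=np.log(config.base_mean), sigma=1.0, size=config.n_genes)
    base[: config.mito_gene_count] *= 5.0
    base[config.mito_gene_count : config.mito_gene_count + config.hemo_gene_count] *= 0.2

    # Cluster-specific marker blocks among the generic genes.
    n_special = config.mito_gene_count + config.hemo_gene_count
    marker_assign: dict[str, list[str]] = {}
    boost = np.ones((config.n_clusters, config.n_genes))
    pos = n_special
    for c, cname in enumerate(clusters):
        block = genes[pos : pos + config.markers_per_cluster]
        marker_assign[cname] = block
        boost[c, pos : pos + config.markers_per_cluster] = 2.0**config.marker_logfc
        pos += config.markers_per_cluster

    # Planted LR pairs: ligand expressed essentially only in the source
    # cluster, receptor only in the target cluster.
    mean_override = {}  # gene index -> per-cluster mean vector
    for lig, rec, src, tgt in config.lr_pairs_planted:
        for gene, on_cluster in ((lig, src), (rec, tgt)):
            gi = gene_index[gene]
            v = mean_override.get(gi, np.full(config.n_clusters, config.lr_low_mean))
            v = v.copy()
            v[clusters.index(on_cluster)] = config.lr_high_mean
            mean_override[gi] = v

    probs = _composition_probs(config)
    shape = 1.0 / config.nb_dispersion

    blocks, obs_rows = [], []
    for group in GROUPS:
        for s in range(config.n_samples_per_group):
            sample = f"{group}{s + 1:02d}"
            n_cells = config.n_cells_per_sample
            cl = rng.choice(config.n_clusters, size=n_cells, p=probs[group])
            # Per-sample gene-level random effect (shared by the sample's cells).
            sample_eff = rng.lognormal(
                -0.5 * config.sample_sigma**2, config.sample_sigma, config.n_genes
            )
            mu = base[None, :] * boost[cl, :] * sample_eff[None, :]
            for gi, per_cluster in mean_override.items():
                mu[:, gi] = per_cluster[cl] * sample_eff[gi]
            sigma = config.cell_sigma * config.dispersion_by_group.get(group, 1.0)
            # Mean-one lognormal cell noise: its sigma is the within-tumor
            # dispersion the heterogeneity score recovers.
            cell_noise = rng.lognormal(-0.5 * sigma**2, sigma, mu.shape)
            gamma = rng.gamma(shape, 1.0 / shape, mu.shape)
            counts = rng.poisson(mu * cell_noise * gamma)
            blocks.append(sparse.csr_matrix(counts))
            for i in range(n_cells):
                obs_rows.append((f"{sample}_c{i + 1:04d}", sample, group, clusters[cl[i]]))

    X = sparse.vstack(blocks, format="csr")
    obs = pd.DataFrame(
        obs_rows, columns=["cell_id", "sample", "group", "cluster"]
    ).set_index("cell_id")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))

    truth = {
        "seed": config.seed,
        "groups": list(GROUPS),
        "markers_by_cluster": marker_assign,
        "marker_logfc": config.marker_logfc,
        "dispersion_by_group": dict(config.dispersion_by_group),
        "lr_pairs_planted": [list(p) for p in config.lr_pairs_planted],
        "composition_probs": {g: probs[g].tolist() for g in GROUPS},
        "mito_genes": genes[: config.mito_gene_count],
        "hemo_genes": genes[config.mito_gene_count : n_special],
        "config": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in asdict(config).items()
            if not isinstance(v, list)
        },
    }
    return adata, truth


def simulate_response_cohort(
    config: SimConfig, n_samples: int | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Binary-response bulk cohort with a planted predictive gene subset.

    Expression is standard normal per gene; the first
    ``response_informative_genes`` generic genes are shifted upward by
    ``response_effect_sd`` standard deviations in responders.  Returns a
    samples x (genes + ``response``) frame and the truth record.
    """
    config.validate()
    n = config.cohort_samples if n_samples is None else n_samples
    if n <= 0:
        raise SimConfigError("cohort needs at least one sample")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = config.gene_names()
    n_special = config.mito_gene_count + config.hemo_gene_count
    informative = genes[n_special : n_special + config.response_informative_genes]

    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    rng.shuffle(labels)
    X = rng.normal(size=(n, config.n_genes))
    for g in informative:
        X[labels == 1, genes.index(g)] += config.response_effect_sd
    df = pd.DataFrame(X, columns=genes, index=[f"S{i + 1:03d}" for i in range(n)])
    df["response"] = labels
    truth = {
        "informative_genes": informative,
        "effect_sd": config.response_effect_sd,
        "n_samples": n,
    }
    return df, truth


def simulate_cohort_set(
    config: SimConfig, roles: tuple[str, ...] = ("train", "validation", "test1", "test2")
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Independent response cohorts sharing the same planted informative genes."""
    cohorts = {}
    truth = None
    for i, role in enumerate(roles):
        df, t = simulate_response_cohort(config, seed=config.seed + 1000 * (i + 1))
        cohorts[role] = df
        truth = t
    return cohorts, {"roles": list(roles), **(truth or {})}


def simulate_bulk_survival(
    n_samples: int = 200,
    n_genes: int = 100,
    set_size: int = 10,
    hazard_ratio: float = 1.0,
    baseline_hazard: float = 1.0 / 365.0,
    censor_time: float = 1500.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Bulk expression with survival, hazard tied to a planted signature.

    Samples whose mean expression over the planted gene set exceeds the
    cohort median carry ``hazard_ratio`` times the baseline hazard;
    ``hazard_ratio=1`` yields a null cohort.  Censoring is administrative at
    ``censor_time`` days.  Returns (expression, survival, set genes) with
    survival columns ``time`` and ``event``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"BG{i + 1:04d}" for i in range(n_genes)]
    sig = genes[:set_size]
    X = rng.normal(size=(n_samples, n_genes))
    expr = pd.DataFrame(X, columns=genes, index=[f"B{i + 1:03d}" for i in range(n_samples)])
    score = expr[sig].mean(axis=1)
    high = (score > score.median()).to_numpy()
    lam = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    t = rng.exponential(1.0 / lam)
    event = (t <= censor_time).astype(int)
    time = np.minimum(t, censor_time)
    surv = pd.DataFrame({"time": time, "event": event}, index=expr.index)
    return expr, surv, sig


def write_tenx_dir(adata: ad.AnnData, outdir: str | Path, truth: dict | None = None) -> None:
    """Write a 10x-style triplet (matrix.mtx, features.tsv, barcodes.tsv) plus
    annotation CSV and, when given, the truth record JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # 10x convention stores genes x cells.
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(adata.X).T.astype(int))
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.reset_index().to_csv(outdir / "annotation.csv", index=False)
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def read_tenx_dir(indir: str | Path) -> ad.AnnData:
    """Read the triplet written by :func:`write_tenx_dir` back into AnnData."""
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx").T)
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    annot_path = indir / "annotation.csv"
    if annot_path.exists():
        annot = pd.read_csv(annot_path).set_index("cell_id").loc[adata.obs_names]
        adata.obs = annot
    return adata
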