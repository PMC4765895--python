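"""Case/control expression data: loading, normalisation, and differential expression.

A dataset is a genes x samples matrix with a binary phenotype (``normal`` /
``cancer``) attached to each sample.  The processing chain mirrors standard
microarray practice: conditional log2 transformation, removal of genes with too
many missing values, per-class mean imputation, and a moderated two-sample
t-test with empirical-Bayes variance shrinkage followed by Benjamini-Hochberg
adjustment.  A disease signature is the set of genes passing both an FDR and a
fold-change threshold, split by the sign of the cancer-vs-normal change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

NORMAL = "normal"
CANCER = "cancer"

__all__ = [
    "ExpressionDataset",
    "DiseaseSignature",
    "read_expression",
    "normalize",
    "differential_expression",
    "bh_fdr",
    "dataset_correlation",
    "write_signature",
    "read_signature",
]


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with per-sample phenotype labels.

    ``values`` is a float matrix of shape ``(len(genes), len(samples))``;
    missing entries are ``NaN``.  Both phenotype classes must be non-empty and
    gene/sample identifiers must be unique.
    """

    dataset_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    phenotype: list[str]

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.phenotype = list(self.phenotype)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"dataset {self.dataset_id!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples"
            )
        dup = pd.Index(self.genes)[pd.Index(self.genes).duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"dataset {self.dataset_id!r}: duplicated gene ids: {dup}")
        dup_s = pd.Index(self.samples)[pd.Index(self.samples).duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"dataset {self.dataset_id!r}: duplicated sample ids: {dup_s}")
        if len(self.phenotype) != len(self.samples):
            raise ValueError(
                f"dataset {self.dataset_id!r}: {len(self.phenotype)} phenotype labels for "
                f"{len(self.samples)} samples"
            )
        bad = sorted({l for l in self.phenotype if l not in (NORMAL, CANCER)})
        if bad:
            raise ValueError(f"dataset {self.dataset_id!r}: unknown phenotype labels {bad}")
        for cls in (NORMAL, CANCER):
            if cls not in self.phenotype:
                raise ValueError(f"dataset {self.dataset_id!r}: no {cls!r} samples")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def class_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.phenotype) if l == label], dtype=int)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class DiseaseSignature:
    """Up- and down-regulated differentially expressed genes with statistics.

    ``log2fc``, ``pvalue`` and ``fdr`` are gene-indexed series covering every
    tested gene (not just signature members).  ``up`` and ``down`` are disjoint.
    """

    up: frozenset[str]
    down: frozenset[str]
    log2fc: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    pvalue: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    fdr: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"signature up/down sets overlap: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def to_frame(self) -> pd.DataFrame:
        direction = pd.Series("ns", index=self.log2fc.index, dtype=object)
        direction.loc[direction.index.isin(self.up)] = "up"
        direction.loc[direction.index.isin(self.down)] = "down"
        return pd.DataFrame(
            {
                "log2fc": self.log2fc,
                "pvalue": self.pvalue,
                "fdr": self.fdr,
                "direction": direction,
            }
        ).rename_axis("gene")


def read_expression(path, phenotype_path) -> ExpressionDataset:
    """Read a genes x samples TSV plus a two-column sample->label phenotype TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicated gene rows: {dup}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression values ({exc})") from exc

    pheno = pd.read_csv(
        phenotype_path, sep="\t", header=None, names=["sample", "label"], comment="#"
    )
    if len(pheno) and tuple(pheno.iloc[0]) == ("sample", "label"):  # tolerate a header row
        pheno = pheno.iloc[1:]
    mapping = dict(zip(pheno["sample"].astype(str), pheno["label"].astype(str)))
    missing = [s for s in df.columns if s not in mapping]
    if missing:
        raise ValueError(f"{phenotype_path}: no phenotype label for samples {missing}")
    labels = [mapping[s] for s in df.columns]
    return ExpressionDataset(
        dataset_id=str(path),
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=values,
        phenotype=labels,
    )


def normalize(
    ds: ExpressionDataset,
    null_fraction_max: float = 0.2,
    log_median_threshold: float = 16.0,
) -> ExpressionDataset:
    """Conditionally log2-transform, drop high-missingness genes, impute the rest.

    If the overall median (missing entries excluded) exceeds
    ``log_median_threshold`` the data are taken to be on the raw intensity scale
    and every value ``v`` is replaced by ``log2(v + 1)``.  Genes whose missing
    fraction exceeds ``null_fraction_max`` are removed; remaining missing
    entries are imputed with the gene's per-class mean.
    """
    X = ds.values.copy()
    if np.all(np.isnan(X)):
        raise ValueError(f"dataset {ds.dataset_id!r}: all values missing")
    med = np.nanmedian(X)
    if med > log_median_threshold:
        if np.nanmin(X) < 0:
            raise ValueError(
                f"dataset {ds.dataset_id!r}: negative values cannot be log2-transformed"
            )
        X = np.log2(X + 1.0)

    miss_frac = np.isnan(X).mean(axis=1)
    keep = miss_frac <= null_fraction_max
    X = X[keep]
    genes = [g for g, k in zip(ds.genes, keep) if k]

    if np.isnan(X).any():
        overall = np.nanmean(X, axis=1)
        for cls in (NORMAL, CANCER):
            idx = ds.class_indices(cls)
            sub = X[:, idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN class slices
                cls_mean = np.nanmean(sub, axis=1)
            cls_mean = np.where(np.isnan(cls_mean), overall, cls_mean)
            nan_r, nan_c = np.nonzero(np.isnan(sub))
            sub[nan_r, nan_c] = cls_mean[nan_r]
            X[:, idx] = sub
    return ExpressionDataset(ds.dataset_id, genes, ds.samples, X, ds.phenotype)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_fdr expects a 1-d sequence of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    ds: ExpressionDataset,
    alpha: float = 0.01,
    fc_threshold: float = 2.0,
    d0: float = 4.0,
) -> DiseaseSignature:
    """Moderated-t differential expression between cancer and normal samples.

    Per gene, ``log2FC = mean(cancer) - mean(normal)`` and the pooled variance
    is shrunk toward the across-gene mean variance with prior weight ``d0``
    (method-of-moments empirical Bayes); the test statistic is referred to a t
    distribution with ``n1 + n2 - 2 + d0`` degrees of freedom.  With ``d0 = 0``
    this is exactly the ordinary pooled two-sample t-test.  The signature is
    the set of genes with ``fdr < alpha`` and ``|log2FC| > log2(fc_threshold)``.
    """
    if d0 < 0:
        raise ValueError("shrinkage weight d0 must be >= 0")
    ni = ds.class_indices(NORMAL)
    ci = ds.class_indices(CANCER)
    if len(ni) < 2 or len(ci) < 2:
        raise ValueError(
            f"dataset {ds.dataset_id!r}: need >=2 samples per class "
            f"(normal={len(ni)}, cancer={len(ci)})"
        )
    X = ds.values
    if np.isnan(X).any():
        raise ValueError(
            f"dataset {ds.dataset_id!r}: missing values present; run normalize() first"
        )
    xn, xc = X[:, ni], X[:, ci]
    n1, n2 = len(ni), len(ci)
    lfc = xc.mean(axis=1) - xn.mean(axis=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * xn.var(axis=1, ddof=1) + (n2 - 1) * xc.var(axis=1, ddof=1)) / df
    s0 = sp2.mean()
    s2 = (d0 * s0 + df * sp2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df + d0)
    p = np.where(np.isnan(t), 1.0, p)  # zero-variance genes with zero change
    fdr = bh_fdr(p)

    passing = (fdr < alpha) & (np.abs(lfc) > np.log2(fc_threshold))
    up = frozenset(g for g, ok, l in zip(ds.genes, passing, lfc) if ok and l > 0)
    down = frozenset(g for g, ok, l in zip(ds.genes, passing, lfc) if ok and l < 0)
    index = pd.Index(ds.genes, name="gene")
    return DiseaseSignature(
        up=up,
        down=down,
        log2fc=pd.Series(lfc, index=index),
        pvalue=pd.Series(p, index=index),
        fdr=pd.Series(fdr, index=index),
    )


def dataset_correlation(ds1: ExpressionDataset, ds2: ExpressionDataset) -> float:
    """Pearson correlation of per-gene mean expression over the common genes."""
    common = sorted(set(ds1.genes) & set(ds2.genes))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common genes; need at least 3")
    i1 = ds1.gene_index()
    i2 = ds2.gene_index()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(ds1.values[[i1[g] for g in common]], axis=1)
        m2 = np.nanmean(ds2.values[[i2[g] for g in common]], axis=1)
    r, _ = stats.pearsonr(m1, m2)
    return float(r)


def write_signature(sig: DiseaseSignature, path) -> None:
    sig.to_frame().to_csv(path, sep="\t")


def read_signature(path) -> DiseaseSignature:
    df = pd.read_csv(path, sep="\t", index_col=0)
    up = frozenset(df.index[df["direction"] == "up"].astype(str))
    down = frozenset(df.index[df["direction"] == "down"].astype(str))
    return DiseaseSignature(
        up=up,
        down=down,
        log2fc=df["log2fc"],
        pvalue=df["pvalue"],
        fdr=df["fdr"],
    )
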