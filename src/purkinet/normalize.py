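"""Normalization and sample-level quality control.

Size factors use the median-of-ratios convention (per-sample median of
count / per-gene geometric mean, over genes observed and positive in every
sample), rescaled to geometric mean 1. The variance stabilizer is the
monotone log2(normalized + pseudocount); downstream stages consume only
monotone stabilized values. Sample standard deviations use denominator n-1
throughout — with three replicates per time point the convention is
material.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneAnnotation, SampleDesign


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix on a tagged scale."""

    values: pd.DataFrame
    scale: str  # normalized_counts | log_stabilized | rpkm | standardized

    VALID_SCALES = ("normalized_counts", "log_stabilized", "rpkm", "standardized")

    def __post_init__(self):
        if self.scale not in self.VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("expression values must be finite where not missing")

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # genes x components
    variance_fractions: np.ndarray
    n_components: int


class SizeFactorNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios size-factor normalization (sklearn transformer).

    ``fit`` expects X of shape (n_samples, n_genes); fitted attribute
    ``size_factors_`` has geometric mean 1. ``transform`` divides each
    sample's counts by its factor.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.size_factors_ = _size_factors_from_array(X.T)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X / self.size_factors_[:, None]


def _size_factors_from_array(counts: np.ndarray) -> np.ndarray:
    """counts: genes x samples; returns per-sample factors, geometric mean 1."""
    finite = np.isfinite(counts)
    usable = finite.all(axis=1) & (np.nan_to_num(counts) > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene is positive and observed in every sample; supply a "
            "pseudo-reference fallback or filter samples"
        )
    ref = counts[usable]
    log_gm = np.mean(np.log(ref), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_gm, axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Per-sample size factors by median-of-ratios, geometric mean 1."""
    factors = _size_factors_from_array(cm.counts.to_numpy(dtype=float))
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def compute_rpkm(
    cm: CountMatrix, ann: GeneAnnotation, mapped_totals: pd.Series | None = None
) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads.

    ``mapped_totals`` defaults to the column sums of the count matrix (the
    per-library mapped-read totals are not recoverable from a count table).
    """
    counts = cm.counts
    lengths = ann.lengths(cm.gene_ids)
    missing = lengths.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} genes lack lengths and are dropped from RPKM"
        )
        counts = counts.loc[~missing.to_numpy()]
        lengths = lengths[~missing.to_numpy()]
    if mapped_totals is None:
        mapped_totals = cm.counts.sum(axis=0, skipna=True)
    totals = pd.Series(mapped_totals).reindex(cm.sample_ids).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValueError("mapped totals must be positive")
    denom = (lengths.to_numpy(dtype=float)[:, None] / 1e3) * (totals[None, :] / 1e6)
    return ExpressionMatrix(counts / denom, "rpkm")


def variance_stabilize(
    cm: CountMatrix, size_factors: pd.Series, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount); a monotone simplified stabilizer."""
    sf = pd.Series(size_factors).reindex(cm.sample_ids).to_numpy(dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    vals = np.log2(cm.counts.to_numpy(dtype=float) / sf[None, :] + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids),
        "log_stabilized",
    )


def standardize_rows(em: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores (mean 0, sd 1 with ddof=1 over non-missing samples).

    Zero-variance and all-missing rows are dropped with a warning; the
    operation is idempotent on its own output.
    """
    vals = em.values
    means = vals.mean(axis=1, skipna=True)
    sds = vals.std(axis=1, ddof=1, skipna=True)
    keep = sds.notna() & (sds > 0)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} constant or all-missing rows")
    out = vals.loc[keep].sub(means[keep], axis=0).div(sds[keep], axis=0)
    return ExpressionMatrix(out, "standardized")


def pca_qc(
    em: ExpressionMatrix,
    design: SampleDesign,
    n_components: int = 10,
    silhouette_threshold: float = 0.25,
) -> tuple[PCAResult, dict]:
    """PCA of samples and a time-point separation verdict.

    The verdict is the silhouette coefficient of time-point labels in the
    PC1-2 score space: "separated" iff silhouette > threshold.
    """
    X = em.values.to_numpy(dtype=float).T  # samples x genes
    X = np.where(np.isfinite(X), X, np.nanmean(X, axis=0, keepdims=True))
    n_samples, n_genes = X.shape
    k = min(n_components, n_samples - 1, n_genes)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    comp_names = [f"PC{i + 1}" for i in range(k)]
    result = PCAResult(
        scores=pd.DataFrame(scores, index=em.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=em.gene_ids,
                              columns=comp_names),
        variance_fractions=pca.explained_variance_ratio_,
        n_components=k,
    )
    labels = design.table.loc[em.sample_ids, "time_point"].to_numpy()
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("pca_qc needs >= 2 samples per time point")
    sil = float(silhouette_score(scores[:, :2], labels))
    verdict = {
        "silhouette": sil,
        "separated": sil > silhouette_threshold,
        "threshold": silhouette_threshold,
    }
    return result, verdict


def covariate_pc_association(pca: PCAResult, covariate) -> pd.DataFrame:
    """Per-component Pearson test of scores vs a sample covariate, BH-adjusted."""
    cov = np.asarray(pd.Series(covariate).reindex(pca.scores.index)
                     if isinstance(covariate, pd.Series) else covariate,
                     dtype=float)
    if len(cov) != len(pca.scores):
        raise ValueError("covariate length must equal sample count")
    rows = []
    if np.ptp(cov) == 0:
        warnings.warn("constant covariate; all p-values set to 1")
        rows = [(c, 0.0, 1.0) for c in pca.scores.columns]
    else:
        for c in pca.scores.columns:
            r, p = stats.pearsonr(pca.scores[c].to_numpy(), cov)
            rows.append((c, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["component", "r", "pvalue"])
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def marker_report(
    rpkm: ExpressionMatrix,
    panel: pd.DataFrame,
    design: SampleDesign,
    enrichment_ratio: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-marker mean expression per time point plus a capture-purity verdict.

    Verdict is "enriched" when target-population markers' mean RPKM exceeds
    off-target markers' by ``enrichment_ratio``; "indeterminate" when no
    panel gene is present in the matrix.
    """
    tp = design.table.loc[rpkm.sample_ids, "time_point"]
    rows = []
    overall: dict[str, float] = {}
    for _, rec in panel.iterrows():
        g = rec["gene_id"]
        if g in rpkm.values.index:
            prof = rpkm.values.loc[g].groupby(tp).mean()
            prof = prof.reindex(design.time_points)
            mean_all = float(rpkm.values.loc[g].mean())
            present = True
        else:
            prof = pd.Series(np.nan, index=design.time_points)
            mean_all = np.nan
            present = False
        overall[g] = mean_all
        rows.append(
            {"gene_id": g, "cell_type": rec["cell_type"],
             "expected_profile": rec.get("expected_profile", ""),
             "present": present, "mean_rpkm": mean_all,
             **{f"mean_{t}": prof[t] for t in design.time_points}}
        )
    report = pd.DataFrame(rows)
    is_target = report["cell_type"] == "target_population"
    target_mean = report.loc[is_target & report["present"], "mean_rpkm"].mean()
    off_mean = report.loc[~is_target & report["present"], "mean_rpkm"].mean()
    if report["present"].sum() == 0 or np.isnan(target_mean) or np.isnan(off_mean):
        verdict = {"purity": "indeterminate", "ratio": np.nan}
    else:
        ratio = target_mean / max(off_mean, 1e-12)
        verdict = {
            "purity": "enriched" if ratio >= enrichment_ratio else "not_enriched",
            "ratio": float(ratio),
        }
    verdict["required_ratio"] = enrichment_ratio
    return report, verdict
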