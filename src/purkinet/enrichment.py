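"""Gene-set over-representation with gene-length-bias correction.

The central test is Fisher's exact upper tail (central hypergeometric).
Length bias is corrected goseq-style: an isotonic probability weighting
function (PWF) — monotone non-decreasing regression of cluster membership
on gene length — is reduced to a single odds parameter (mean weight inside
the tested set vs outside the set, within the background), and the overlap
count is referred to the Wallenius noncentral hypergeometric law with that
odds. With equal weights the odds is exactly 1 and the Wallenius law
reduces to the central hypergeometric, so the corrected test then matches
Fisher's exactly. Q-values are Benjamini-Hochberg adjusted within one
family per calling context (e.g., all disease lists tested against one
cluster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneAnnotation, GeneSet

_CLIP = 1e-6


@dataclass
class PWF:
    """Probability weighting function: per-gene fitted membership probability,
    monotone non-decreasing in gene length."""

    weights: pd.Series  # index gene_id, values in (0, 1)

    def mean_weight(self, genes) -> float:
        return float(self.weights.reindex(list(genes)).mean())


@dataclass
class EnrichmentResult:
    set_name: str
    cluster_name: str
    overlap: int
    expected: float
    fold: float
    pvalue: float
    qvalue: float | None = None
    method: str = "fisher"
    flagged: bool = False

    def as_dict(self) -> dict:
        return {
            "cluster": self.cluster_name, "set": self.set_name,
            "overlap": self.overlap, "expected": self.expected,
            "fold": self.fold, "pvalue": self.pvalue, "qvalue": self.qvalue,
            "method": self.method,
        }


def build_background(
    cm: CountMatrix, ann: GeneAnnotation, mode: str = "expressed_nonzero_variance"
) -> GeneSet:
    """Background gene set for enrichment testing.

    ``expressed_nonzero_variance``: genes with non-zero total count and
    non-zero variance across samples. ``expressed_one_to_one`` additionally
    requires a 1:1 ortholog. Both modes restrict to protein-coding genes.
    """
    counts = cm.counts
    total = counts.sum(axis=1, skipna=True)
    var = counts.var(axis=1, ddof=1, skipna=True)
    expressed = set(counts.index[(total > 0) & var.notna() & (var > 0)])
    coding = ann.protein_coding()
    members = expressed & coding
    if mode == "expressed_one_to_one":
        t = ann.table
        one = set(t.index[t["ortholog_id"].notna()
                          & (t["ortholog_multiplicity"] == 1)])
        members &= one
    elif mode != "expressed_nonzero_variance":
        raise ValueError(f"unknown background mode {mode!r}")
    if not members:
        raise ValueError("empty background")
    return GeneSet(f"background[{mode}]", frozenset(members))


def fit_pwf(membership: pd.Series, lengths: pd.Series,
            genes_per_bin: int = 50) -> PWF:
    """Isotonic regression of a boolean membership indicator on gene length.

    Genes are first pooled into equal-occupancy length bins (about
    ``genes_per_bin`` genes each) and the monotone non-decreasing fit is done
    on the per-bin membership fractions, weighted by bin size; this keeps the
    boundary estimates stable (a raw per-gene isotonic fit collapses to the
    extreme gene's 0/1 value at the ends). Fitted values are clipped to
    [1e-6, 1 - 1e-6]. A background where every gene (or no gene) is a member
    yields a flat PWF at the clipped bound.
    """
    common = membership.index.intersection(lengths.index)
    if len(common) < 50:
        raise ValueError("PWF fitting needs a background of >= 50 genes")
    y = membership.reindex(common).astype(float).to_numpy()
    x = lengths.reindex(common).to_numpy(dtype=float)
    if y.min() == y.max():
        warnings.warn("membership is constant; PWF is flat at the clipped bound")
        fitted = np.full_like(x, float(np.clip(y[0], _CLIP, 1 - _CLIP)))
        return PWF(pd.Series(fitted, index=common, name="pwf"))
    order = np.argsort(x, kind="stable")
    n_bins = max(3, len(common) // genes_per_bin)
    bin_ids = np.minimum(
        np.arange(len(common)) * n_bins // len(common), n_bins - 1)
    bx = np.bincount(bin_ids, weights=x[order]) / np.bincount(bin_ids)
    by = np.bincount(bin_ids, weights=y[order]) / np.bincount(bin_ids)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(bx, by, sample_weight=np.bincount(bin_ids))
    fitted = np.clip(iso.predict(x), _CLIP, 1 - _CLIP)
    return PWF(pd.Series(fitted, index=common, name="pwf"))


def _table_counts(cluster: GeneSet, set_: GeneSet, background: GeneSet):
    bg = background.members
    s = set_.members & bg
    c = cluster.members & bg
    return len(s & c), len(s), len(c), len(bg)


def fisher_test(
    cluster: GeneSet, set_: GeneSet, background: GeneSet
) -> EnrichmentResult:
    """Central hypergeometric upper-tail over-representation test."""
    x, K, n, N = _table_counts(cluster, set_, background)
    if K == 0:
        warnings.warn(f"set {set_.name!r} empty after background intersection")
        return EnrichmentResult(set_.name, cluster.name, 0, 0.0, 0.0, 1.0,
                                method="fisher", flagged=True)
    expected = K * n / N
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    return EnrichmentResult(
        set_.name, cluster.name, x, expected,
        x / expected if expected > 0 else np.nan, p, method="fisher",
    )


def wallenius_test(
    cluster: GeneSet, set_: GeneSet, background: GeneSet, pwf: PWF
) -> EnrichmentResult:
    """Length-bias-corrected over-representation test.

    The PWF is reduced to odds = mean weight inside the set / mean weight
    outside; the overlap is referred to Wallenius' noncentral hypergeometric
    distribution with that odds (upper tail, observed included).
    """
    x, K, n, N = _table_counts(cluster, set_, background)
    if K == 0:
        warnings.warn(f"set {set_.name!r} empty after background intersection")
        return EnrichmentResult(set_.name, cluster.name, 0, 0.0, 0.0, 1.0,
                                method="wallenius", flagged=True)
    bg = background.members
    inside = set_.members & bg
    outside = bg - set_.members
    w_in = pwf.mean_weight(inside)
    w_out = pwf.mean_weight(outside) if outside else w_in
    odds = w_in / w_out
    if abs(odds - 1.0) < 1e-12 or K == N:
        # Wallenius with unit odds IS the central hypergeometric
        dist = stats.hypergeom(N, K, n)
    else:
        dist = stats.nchypergeom_wallenius(N, K, n, odds)
    expected = float(dist.mean())
    p = float(dist.sf(x - 1))
    return EnrichmentResult(
        set_.name, cluster.name, x, expected,
        x / expected if expected > 0 else np.nan, min(p, 1.0),
        method="wallenius",
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def test_sets_against_cluster(
    cluster: GeneSet,
    sets: list[GeneSet],
    background: GeneSet,
    pwf: PWF | None = None,
) -> pd.DataFrame:
    """Test a family of gene sets against one cluster; BH within the family.

    Uses the length-corrected Wallenius test when a PWF is supplied,
    otherwise Fisher's exact test.
    """
    results = []
    for s in sets:
        if pwf is not None:
            results.append(wallenius_test(cluster, s, background, pwf))
        else:
            results.append(fisher_test(cluster, s, background))
    q = bh_adjust([r.pvalue for r in results])
    for r, qi in zip(results, q):
        r.qvalue = float(qi)
    return pd.DataFrame([r.as_dict() for r in results])
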