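"""Cross-tissue comorbidity stratification: the ratio-of-odds-ratios test.

Two disease-gene strata (intellectual-disability co-morbid vs ID-free) are
crossed with two tissue clusters, giving four 2x2 contingency tables. Per
tissue, ROR = OR(ID table) / OR(ID-free table); the statistic is
Delta = |log10 ROR_A - log10 ROR_B|. Significance is assessed by a
margin-conditioned permutation: each of the four tables is redrawn
independently from the distribution of tables with its observed margins
fixed (Patefield-style sequential conditional hypergeometric sampling; a
single hypergeometric draw in the 2x2 case), Haldane's correction (+0.5 to
every cell) is applied to any drawn table containing a zero, and the
empirical p-value uses the add-one convention p = (#{Delta* >= Delta_obs}
+ 1) / (B + 1), which can never return zero. P-values from stratified runs
are Benjamini-Hochberg adjusted across strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet
from .enrichment import bh_adjust

TISSUES = ("A", "B")
LISTS = ("ID", "ID_free")


@dataclass
class ContingencyTable:
    """2x2 (or r x c) table with margins and label metadata."""

    cells: np.ndarray
    tissue: str | None = None
    stratum: str | None = None
    list_name: str | None = None
    corrected: bool = False

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=float)
        if (self.cells < 0).any():
            raise ValueError("cells must be non-negative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.cells.sum())

    def label(self) -> str:
        return f"{self.tissue or '?'}/{self.list_name or '?'}"


@dataclass
class RORTestResult:
    odds_ratios: dict          # (tissue, list) -> OR (Haldane-corrected)
    ror: dict                  # tissue -> ROR
    delta: float               # |log10 ROR_A - log10 ROR_B|
    n_permutations: int
    exceedances: int
    pvalue: float
    seed: int
    stratum: str | None = None
    qvalue: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# table construction and odds ratios
# ---------------------------------------------------------------------------

def build_two_by_two(
    set_: GeneSet, cluster: GeneSet, universe: GeneSet, **labels
) -> ContingencyTable:
    """Rows: in/out of the gene set; columns: in/out of the cluster."""
    u = universe.members
    if not u:
        raise ValueError("empty universe")
    s = set_.members & u
    c = cluster.members & u
    cells = np.array(
        [
            [len(s & c), len(s - c)],
            [len(c - s), len(u - (s | c))],
        ],
        dtype=float,
    )
    return ContingencyTable(cells, **labels)


def haldane_correct(t: ContingencyTable) -> ContingencyTable:
    """Add 0.5 to every cell iff the table contains a zero; idempotent."""
    if t.corrected or not (t.cells == 0).any():
        return t
    return replace(t, cells=t.cells + 0.5, corrected=True)


def odds_ratio(t: ContingencyTable) -> float:
    """(a*d)/(b*c) of a 2x2 table; zero off-diagonal requires prior Haldane."""
    if t.cells.shape != (2, 2):
        raise ValueError("odds ratio requires a 2x2 table")
    a, b = t.cells[0]
    c, d = t.cells[1]
    if (b == 0 or c == 0) and not t.corrected:
        raise ValueError(
            f"table {t.label()} has an uncorrected zero in b or c; "
            "apply haldane_correct first"
        )
    return float((a * d) / (b * c))


def ror_statistic(
    or_id_a: float, or_idfree_a: float, or_id_b: float, or_idfree_b: float
) -> float:
    """Delta = |log10(OR_ID,A / OR_IDfree,A) - log10(OR_ID,B / OR_IDfree,B)|."""
    for v in (or_id_a, or_idfree_a, or_id_b, or_idfree_b):
        if not v > 0:
            raise ValueError("odds ratios must be positive")
    ror_a = or_id_a / or_idfree_a
    ror_b = or_id_b / or_idfree_b
    return float(abs(np.log10(ror_a) - np.log10(ror_b)))


# ---------------------------------------------------------------------------
# margin-conditioned table sampling
# ---------------------------------------------------------------------------

def patefield_sample(
    row_margins, col_margins, n_tables: int, seed=None, rng=None
) -> np.ndarray:
    """Sample r x c tables uniformly from the margin-conditioned law.

    Tables are filled row by row; each row is a multivariate hypergeometric
    draw of its row total from the still-unallocated column margins, which
    realises the sequential conditional decomposition of the fixed-margins
    distribution (for 2x2 this is a single hypergeometric draw). Returns an
    array of shape (n_tables, r, c); deterministic given the seed.
    """
    rows = np.asarray(row_margins, dtype=np.int64)
    cols = np.asarray(col_margins, dtype=np.int64)
    if (rows < 0).any() or (cols < 0).any():
        raise ValueError("margins must be non-negative integers")
    if rows.sum() != cols.sum():
        raise ValueError(
            f"margin mismatch: rows sum to {rows.sum()}, columns to {cols.sum()}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    r, c = len(rows), len(cols)
    if r == 2 and c == 2:
        a = rng.hypergeometric(rows[0], rows[1], cols[0], size=n_tables)
        out = np.empty((n_tables, 2, 2), dtype=np.int64)
        out[:, 0, 0] = a
        out[:, 0, 1] = rows[0] - a
        out[:, 1, 0] = cols[0] - a
        out[:, 1, 1] = rows[1] - (cols[0] - a)
        return out
    out = np.empty((n_tables, r, c), dtype=np.int64)
    for t in range(n_tables):
        remaining = cols.copy()
        for i in range(r - 1):
            draw = rng.multivariate_hypergeometric(remaining, rows[i])
            out[t, i] = draw
            remaining = remaining - draw
        out[t, r - 1] = remaining
    return out


def _vector_odds_ratios(tables: np.ndarray) -> np.ndarray:
    """Haldane-corrected odds ratios for a stack of 2x2 tables."""
    cells = tables.astype(float)
    has_zero = (cells == 0).any(axis=(1, 2))
    cells = cells + 0.5 * has_zero[:, None, None]
    return (cells[:, 0, 0] * cells[:, 1, 1]) / (cells[:, 0, 1] * cells[:, 1, 0])


# ---------------------------------------------------------------------------
# the permutation test
# ---------------------------------------------------------------------------

def ror_permutation_test(
    tables: dict,
    n_permutations: int = 100_000,
    seed: int = 0,
    stratum: str | None = None,
) -> RORTestResult:
    """Margin-conditioned permutation test of the cross-tissue ROR difference.

    ``tables`` maps (tissue, list) for tissue in {"A", "B"} and list in
    {"ID", "ID_free"} to 2x2 ContingencyTables. The observed Delta comes
    from the Haldane-corrected observed tables; each permutation redraws
    all four tables independently conditional on their own margins, with
    Haldane applied per draw only when that draw contains a zero.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    for key in [(t, l) for t in TISSUES for l in LISTS]:
        if key not in tables:
            raise KeyError(f"missing table for {key}")
        t = tables[key]
        if (t.row_margins == 0).any() or (t.col_margins == 0).any():
            raise ValueError(
                f"table {key} has a zero margin; the permutation law is degenerate"
            )

    observed_or = {
        key: odds_ratio(haldane_correct(tables[key])) for key in tables
    }
    delta_obs = ror_statistic(
        observed_or[("A", "ID")], observed_or[("A", "ID_free")],
        observed_or[("B", "ID")], observed_or[("B", "ID_free")],
    )

    rng = np.random.default_rng(seed)
    log_ror = {}
    for tissue in TISSUES:
        ors = {}
        for lst in LISTS:
            t = tables[(tissue, lst)]
            draws = patefield_sample(
                t.row_margins.astype(int), t.col_margins.astype(int),
                n_permutations, rng=rng,
            )
            ors[lst] = _vector_odds_ratios(draws)
        log_ror[tissue] = np.log10(ors["ID"] / ors["ID_free"])
    delta_perm = np.abs(log_ror["A"] - log_ror["B"])

    exceed = int(np.sum(delta_perm >= delta_obs))
    pvalue = (exceed + 1) / (n_permutations + 1)
    return RORTestResult(
        odds_ratios=observed_or,
        ror={
            "A": observed_or[("A", "ID")] / observed_or[("A", "ID_free")],
            "B": observed_or[("B", "ID")] / observed_or[("B", "ID_free")],
        },
        delta=delta_obs,
        n_permutations=n_permutations,
        exceedances=exceed,
        pvalue=pvalue,
        seed=seed,
        stratum=stratum,
    )


def stratified_fdr(results: list[RORTestResult]) -> list[RORTestResult]:
    """BH adjustment across stratified permutation runs (in place and returned)."""
    if not results:
        raise ValueError("no results to adjust")
    q = bh_adjust([r.pvalue for r in results])
    for r, qi in zip(results, q):
        r.qvalue = float(qi)
    return results


def overlap_depletion_test(
    set_a: GeneSet, set_b: GeneSet, universe: GeneSet, tail: str = "less"
) -> tuple[list, float]:
    """Hypergeometric tail probability of the overlap of two sets in a universe.

    ``tail``: "less" for depletion, "greater" for excess, "two_sided" for the
    Fisher-style sum of all tables at most as probable as the observed one.
    Returns the overlapping gene list and the p-value.
    """
    u = universe.members
    if not u:
        raise ValueError("empty universe")
    a = set_a.members & u
    b = set_b.members & u
    k = len(a & b)
    N, K, n = len(u), len(a), len(b)
    dist = stats.hypergeom(N, K, n)
    if tail == "less":
        p = float(dist.cdf(k))
    elif tail == "greater":
        p = float(dist.sf(k - 1))
    elif tail == "two_sided":
        support = np.arange(max(0, K + n - N), min(K, n) + 1)
        pmf = dist.pmf(support)
        p = float(pmf[pmf <= dist.pmf(k) * (1 + 1e-7)].sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return sorted(a & b), min(p, 1.0)


def tables_from_gene_sets(
    id_yes: GeneSet,
    id_no: GeneSet,
    cluster_a: GeneSet,
    cluster_b: GeneSet,
    universe: GeneSet,
    stratum: str | None = None,
) -> dict:
    """Build the four (tissue x list) tables the ROR test consumes."""
    return {
        ("A", "ID"): build_two_by_two(
            id_yes, cluster_a, universe, tissue="A", list_name="ID",
            stratum=stratum),
        ("A", "ID_free"): build_two_by_two(
            id_no, cluster_a, universe, tissue="A", list_name="ID_free",
            stratum=stratum),
        ("B", "ID"): build_two_by_two(
            id_yes, cluster_b, universe, tissue="B", list_name="ID",
            stratum=stratum),
        ("B", "ID_free"): build_two_by_two(
            id_no, cluster_b, universe, tissue="B", list_name="ID_free",
            stratum=stratum),
    }
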