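"""Domain types and tabular I/O.

All tables are tab-separated UTF-8 with a mandatory header row; the missing
token is ``NA``. Gene matching everywhere is exact string match after
whitespace trimming — no case folding; cross-species translation must go
through the ortholog columns of the annotation table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"
VALID_CATEGORIES = frozenset({"1", "2", "3", "4", "5", "6", "S"})
ID_STATUS_VALUES = frozenset({"yes", "no", "unknown"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts.

    Counts are stored as float64 so that missing cells can be carried as NaN;
    every non-missing cell must be a non-negative integer value.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        values = counts.to_numpy(dtype=float)
        bad = np.zeros(values.shape, dtype=bool)
        with np.errstate(invalid="ignore"):
            bad |= values < 0
            bad |= np.isfinite(values) & (values != np.floor(values))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "counts must be non-negative integers; offending cell at "
                f"gene {counts.index[i]!r}, sample {counts.columns[j]!r} "
                f"(value {values[i, j]!r})"
            )
        self.counts = counts.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def missing(self) -> pd.DataFrame:
        """Boolean mask of missing cells."""
        return self.counts.isna()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class SampleDesign:
    """Per-sample design: ordinal time point, replicate, optional covariates."""

    table: pd.DataFrame  # index sample_id; columns time_point, time_rank, replicate, ...

    def __post_init__(self) -> None:
        t = self.table
        required = {"time_point", "time_rank", "replicate"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"design table lacks columns: {sorted(missing)}")
        if t.index.has_duplicates:
            raise ValueError("duplicate sample IDs in design")
        if t["time_point"].nunique() < 2:
            raise ValueError("design needs at least two time points")
        # every time point must map to exactly one rank
        ranks = t.groupby("time_point")["time_rank"].nunique()
        if (ranks != 1).any():
            raise ValueError("time_point/time_rank mapping is not one-to-one")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def time_points(self) -> list:
        """Time point labels in rank order."""
        order = self.table[["time_point", "time_rank"]].drop_duplicates()
        return list(order.sort_values("time_rank")["time_point"])

    def time_ranks(self, sample_ids=None) -> np.ndarray:
        t = self.table if sample_ids is None else self.table.loc[list(sample_ids)]
        return t["time_rank"].to_numpy(dtype=float)

    def check_against(self, cm: CountMatrix) -> None:
        missing = set(cm.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"samples without design rows: {sorted(missing)}")


@dataclass
class GeneAnnotation:
    """Per-gene annotation: length (bp), biotype, ortholog mapping."""

    table: pd.DataFrame  # index gene_id; length_bp, biotype, ortholog_id, ortholog_multiplicity

    def __post_init__(self) -> None:
        t = self.table
        required = {"length_bp", "biotype"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"annotation lacks columns: {sorted(missing)}")
        if t.index.has_duplicates:
            raise ValueError("duplicate gene IDs in annotation")
        if (t["length_bp"] <= 0).any():
            bad = t.index[t["length_bp"] <= 0].tolist()
            raise ValueError(f"non-positive gene length for: {bad}")
        if "ortholog_id" not in t.columns:
            t["ortholog_id"] = pd.Series([None] * len(t), index=t.index, dtype=object)
        if "ortholog_multiplicity" not in t.columns:
            t["ortholog_multiplicity"] = np.where(t["ortholog_id"].notna(), 1, np.nan)
        has_orth = t["ortholog_id"].notna()
        mult = t.loc[has_orth, "ortholog_multiplicity"]
        if (mult.fillna(0) < 1).any():
            raise ValueError("ortholog_multiplicity must be >= 1 where ortholog present")

    def lengths(self, gene_ids) -> pd.Series:
        return self.table["length_bp"].reindex(list(gene_ids))

    def protein_coding(self) -> set[str]:
        t = self.table
        return set(t.index[t["biotype"] == "protein_coding"])


@dataclass
class DiseaseGeneList:
    """Annotated disease gene list (SFARI-like)."""

    list_name: str
    entries: pd.DataFrame  # columns gene_id, category, syndromic, id_comorbid

    def __post_init__(self) -> None:
        e = self.entries
        required = {"gene_id", "category", "syndromic", "id_comorbid"}
        missing = required - set(e.columns)
        if missing:
            raise ValueError(f"disease list lacks columns: {sorted(missing)}")
        if e["gene_id"].duplicated().any():
            dups = e.loc[e["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate genes in list {self.list_name!r}: {dups}")
        bad = set(e["category"].astype(str)) - VALID_CATEGORIES
        if bad:
            raise ValueError(
                f"invalid categories {sorted(bad)} in list {self.list_name!r}; "
                f"allowed: 1-6 and S"
            )
        e["category"] = e["category"].astype(str)
        bad_id = set(e["id_comorbid"]) - ID_STATUS_VALUES
        if bad_id:
            raise ValueError(f"invalid id_comorbid values: {sorted(bad_id)}")
        syn_mismatch = (e["category"] == "S") & (~e["syndromic"].astype(bool))
        if syn_mismatch.any():
            raise ValueError("category S entries must carry syndromic=true")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries["gene_id"])


@dataclass
class GeneSet:
    """Named set of gene identifiers."""

    name: str
    members: frozenset = field(default_factory=frozenset)
    universe_hint: str | None = None

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(f"{self.name}&{other.name}", self.members & other.members)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[MISSING_TOKEN], keep_default_na=False, **kw
    )


def read_count_matrix(path) -> CountMatrix:
    """Read a gene x sample count table (first column gene IDs, header samples).

    Cells equal to ``NA`` are parsed as missing, not zero. Duplicate IDs,
    negative or non-integer counts are hard errors.
    """
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return CountMatrix(df)


def write_count_matrix(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    # write non-missing cells as integers
    out = out.map(lambda v: MISSING_TOKEN if pd.isna(v) else str(int(v)))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_design(path) -> SampleDesign:
    df = _read_tsv(path)
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    return SampleDesign(df.set_index("sample_id"))


def write_sample_design(design: SampleDesign, path) -> None:
    out = design.table.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_gene_annotation(path) -> GeneAnnotation:
    df = _read_tsv(path)
    df["gene_id"] = df["gene_id"].astype(str).str.strip()
    return GeneAnnotation(df.set_index("gene_id"))


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    out = ann.table.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_disease_gene_list(path, list_name: str | None = None) -> DiseaseGeneList:
    """Read a disease gene list; blank ``id_comorbid`` defaults to "unknown"."""
    df = _read_tsv(path, dtype={"category": str})
    df["gene_id"] = df["gene_id"].astype(str).str.strip()
    df["id_comorbid"] = df["id_comorbid"].fillna("unknown")
    if df["syndromic"].dtype == object:
        df["syndromic"] = df["syndromic"].map(
            {"true": True, "false": False, "True": True, "False": False,
             True: True, False: False}
        )
    name = list_name if list_name is not None else str(path)
    return DiseaseGeneList(name, df)


def write_disease_gene_list(lst: DiseaseGeneList, path) -> None:
    out = lst.entries.copy()
    out["syndromic"] = out["syndromic"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_gene_set_gmt(path) -> list[GeneSet]:
    """Read gene sets in GMT format (name <tab> description <tab> genes...)."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g)))
    return sets


# ---------------------------------------------------------------------------
# list filtering
# ---------------------------------------------------------------------------

def filter_sfari_categories(
    lst: DiseaseGeneList, categories, include_syndromic: bool
) -> GeneSet:
    """Retain genes whose confidence category is in ``categories``; syndromic
    genes are added iff ``include_syndromic``."""
    cats = {str(c) for c in categories}
    bad = cats - VALID_CATEGORIES
    if bad:
        raise ValueError(f"invalid categories requested: {sorted(bad)}")
    e = lst.entries
    keep = e["category"].isin(cats)
    if include_syndromic:
        keep |= e["syndromic"].astype(bool)
    members = frozenset(e.loc[keep, "gene_id"])
    tag = "".join(sorted(cats)) + ("+S" if include_syndromic else "")
    if not members:
        warnings.warn(f"category filter {tag} on {lst.list_name!r} left no genes")
    return GeneSet(f"{lst.list_name}[cat{tag}]", members)


def restrict_to_one_to_one_orthologs(
    gene_set: GeneSet, ann: GeneAnnotation
) -> tuple[GeneSet, dict]:
    """Translate a gene set into 1:1-ortholog space.

    Members found in the annotation are mapped to their ``ortholog_id`` when
    ``ortholog_multiplicity == 1``; genes with no ortholog or a many-to-one
    mapping are dropped. Two genes colliding on one ortholog are both dropped
    (the mapping must stay injective). Members that are already ortholog IDs
    (they appear as a 1:1 ``ortholog_id`` in the table) pass through unchanged,
    which makes the operation idempotent. Returns the mapped set and a report
    of drop counts.
    """
    t = ann.table
    one_to_one = t["ortholog_id"].notna() & (t["ortholog_multiplicity"] == 1)
    mapping = t.loc[one_to_one, "ortholog_id"].astype(str).to_dict()
    ortholog_space = set(mapping.values())

    mapped: dict[str, str] = {}
    report = {"absent": 0, "no_one_to_one": 0, "collision": 0, "passthrough": 0}
    targets: dict[str, list[str]] = {}
    for g in gene_set.members:
        if g in mapping:
            targets.setdefault(mapping[g], []).append(g)
        elif g in t.index:
            report["no_one_to_one"] += 1
        elif g in ortholog_space:
            targets.setdefault(g, []).append(g)
            report["passthrough"] += 1
        else:
            report["absent"] += 1
    for target, sources in targets.items():
        if len(sources) == 1:
            mapped[sources[0]] = target
        else:
            report["collision"] += len(sources)
            warnings.warn(
                f"genes {sorted(sources)} collide on ortholog {target!r}; all dropped"
            )
    out = GeneSet(f"{gene_set.name}|1to1", frozenset(mapped.values()))
    return out, report


def partition_by_id_status(
    lst: DiseaseGeneList, stratum: str = "all"
) -> tuple[GeneSet, GeneSet]:
    """Split a disease list by intellectual-disability co-morbidity.

    ``stratum`` selects the genes considered first: ``syndromic_only`` keeps
    syndromic entries, ``categories_1_4`` keeps category 1-4 non-syndromic
    entries, ``all`` keeps their union. Genes flagged "yes" go to the first
    set, "no" to the second; "unknown" is excluded from both (absence of
    annotation is not evidence of absence).
    """
    e = lst.entries
    syndromic = e["syndromic"].astype(bool)
    cat14 = e["category"].isin({"1", "2", "3", "4"})
    if stratum == "syndromic_only":
        keep = syndromic
    elif stratum == "categories_1_4":
        keep = cat14 & ~syndromic
    elif stratum == "all":
        keep = syndromic | cat14
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    sub = e.loc[keep]
    id_yes = frozenset(sub.loc[sub["id_comorbid"] == "yes", "gene_id"])
    id_no = frozenset(sub.loc[sub["id_comorbid"] == "no", "gene_id"])
    base = f"{lst.list_name}[{stratum}]"
    return GeneSet(f"{base}|ID", id_yes), GeneSet(f"{base}|ID-free", id_no)
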