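"""Config-driven orchestration: simulate -> qc -> de -> network -> enrich -> ror.

The run configuration is YAML (JSON accepted) with strict key validation —
unknown keys are an error, because silent typo-tolerance is how thresholds
drift. Every stochastic stage has an explicit seed, results are written as
TSV, and a JSON run report records parameters, per-stage gene counts and
warnings. Logging goes to standard error; result files never interleave
with logs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, enrichment, io, network, normalize, ror, simulate

log = logging.getLogger("purkinet")

_DEFAULTS = {
    "seed": 0,
    "out_dir": "purkinet_run",
    "counts": None,
    "design": None,
    "annotation": None,
    "genelists": [],
    "markers": None,
    "stages": ["simulate", "qc", "de", "network", "enrich", "ror"],
    "n_genes": 1000,
    "power": None,
    "min_module_size": 30,
    "merge_height": 0.5,
    "cut_quantile": 0.15,
    "kme_threshold": 0.8,
    "q_threshold": 0.05,
    "background_mode": "expressed_nonzero_variance",
    "permutations": 100_000,
    "strata": ["syndromic_only", "categories_1_4"],
}

_RANGES = {
    "merge_height": (0.0, 1.0),
    "cut_quantile": (0.0, 1.0),
    "kme_threshold": (-1.0, 1.0),
    "q_threshold": (0.0, 1.0),
}


@dataclass
class RunConfig:
    values: dict

    def __getattr__(self, key):
        try:
            return self.values[key]
        except KeyError as e:  # pragma: no cover
            raise AttributeError(key) from e


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    digests: dict = field(default_factory=dict)

    def record(self, stage_name: str, **info):
        self.stages[stage_name] = info

    def digest(self, name: str, path: Path):
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        self.digests[name] = h

    def write(self, path: Path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"config": self.config, "stages": self.stages,
                 "warnings": self.warnings, "digests": self.digests},
                fh, indent=1, default=str,
            )


def validate_config(path_or_dict) -> RunConfig:
    """Load and strictly validate a YAML/JSON run configuration."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    values = {**_DEFAULTS, **raw}
    if values["seed"] is None:
        raise ValueError("an explicit seed is required")
    for key, (lo, hi) in _RANGES.items():
        v = values[key]
        if v is not None and not (lo <= v <= hi):
            raise ValueError(f"{key}={v} outside [{lo}, {hi}]")
    if values["permutations"] < 1:
        raise ValueError("permutations must be >= 1")
    bad_strata = set(values["strata"]) - {"syndromic_only", "categories_1_4", "all"}
    if bad_strata:
        raise ValueError(f"unknown strata: {sorted(bad_strata)}")
    return RunConfig(values)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    A stage failure aborts downstream stages; the report records partial
    completion. Input files are used where provided, otherwise the simulate
    stage must be enabled to produce them.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dict(config.values))
    stages = list(config.stages)

    state: dict = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            for stage in ["simulate", "qc", "de", "network", "enrich", "ror"]:
                if stage not in stages:
                    continue
                t0 = time.time()
                ok, info = _STAGE_FUNCS[stage](config, state, out, report)
                info["wall_time_s"] = round(time.time() - t0, 3)
                info["status"] = "ok" if ok else "skipped"
                report.record(stage, **info)
                if not ok:
                    log.warning("stage %s skipped: %s", stage, info.get("reason"))
        except Exception as e:
            report.record("error", stage=stage, message=str(e), status="failed")
            report.warnings.extend(str(w.message) for w in caught)
            report.write(out / "run_report.json")
            raise
        report.warnings.extend(str(w.message) for w in caught)
    report.write(out / "run_report.json")
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_inputs(config, state, out):
    if "cm" in state:
        return
    if config.counts is None:
        raise FileNotFoundError(
            "no count matrix: provide 'counts' or enable the simulate stage"
        )
    state["cm"] = io.read_count_matrix(config.counts)
    state["design"] = io.read_sample_design(config.design)
    if config.annotation:
        state["ann"] = io.read_gene_annotation(config.annotation)
    state["lists"] = {}
    for p in config.genelists or []:
        lst = io.read_disease_gene_list(p, list_name=Path(p).stem)
        state["lists"][lst.list_name] = lst
    if config.markers:
        state["markers"] = pd.read_csv(config.markers, sep="\t")


def _stage_simulate(config, state, out, report):
    sim = simulate.SimConfig(n_genes=config.n_genes, seed=config.seed)
    truth = simulate.generate_truth(sim)
    cm, design = simulate.generate_counts(truth)
    ann = simulate.generate_annotation(truth)
    lists = simulate.generate_disease_lists(truth, sim)
    io.write_count_matrix(cm, out / "counts.tsv")
    io.write_sample_design(design, out / "design.tsv")
    io.write_gene_annotation(ann, out / "annotation.tsv")
    for name, lst in lists.items():
        io.write_disease_gene_list(lst, out / f"genelist_{name}.tsv")
    truth.marker_panel.to_csv(out / "markers.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
    state.update(cm=cm, design=design, ann=ann, lists=lists, truth=truth,
                 markers=truth.marker_panel)
    report.digest("counts", out / "counts.tsv")
    return True, {"n_genes": cm.n_genes, "n_samples": cm.n_samples}


def _stage_qc(config, state, out, report):
    _load_inputs(config, state, out)
    cm, design = state["cm"], state["design"]
    design.check_against(cm)
    sf = normalize.estimate_size_factors(cm)
    state["size_factors"] = sf
    vst = normalize.variance_stabilize(cm, sf)
    state["vst"] = vst
    pca, verdict = normalize.pca_qc(vst, design)
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    info = {"n_genes": cm.n_genes, "pca_silhouette": verdict["silhouette"],
            "separated": bool(verdict["separated"])}
    if state.get("markers") is not None and "ann" in state:
        rpkm = normalize.compute_rpkm(cm, state["ann"])
        mrep, purity = normalize.marker_report(rpkm, state["markers"], design)
        mrep.to_csv(out / "marker_report.tsv", sep="\t", index=False)
        info["marker_purity"] = purity["purity"]
    with open(out / "qc_report.json", "w", encoding="utf-8") as fh:
        json.dump(info, fh, indent=1)
    return True, info


def _stage_de(config, state, out, report):
    _load_inputs(config, state, out)
    cm, design = state["cm"], state["design"]
    sf = state.get("size_factors")
    if sf is None:
        sf = normalize.estimate_size_factors(cm)
        state["size_factors"] = sf
    disp = diffexpr.estimate_dispersions(cm, sf, design)
    de = diffexpr.lrt_time_course(cm, design, disp, sf)
    pos, neg = diffexpr.split_by_trend(de, design, q_threshold=config.q_threshold)
    state["de"], state["de_pos"], state["de_neg"] = de, pos, neg
    de.table.to_csv(out / "de_results.tsv", sep="\t")
    report.digest("de_results", out / "de_results.tsv")
    return True, {"n_tested": len(de.table), "n_pos": len(pos), "n_neg": len(neg)}


def _stage_network(config, state, out, report):
    _load_inputs(config, state, out)
    if "vst" not in state:
        sf = state.setdefault(
            "size_factors", normalize.estimate_size_factors(state["cm"]))
        state["vst"] = normalize.variance_stabilize(state["cm"], sf)
    em = normalize.standardize_rows(network.prefilter_genes(state["vst"]))
    scan = network.scan_soft_threshold(em, pinned_power=config.power)
    tom = network.compute_tom(em, scan.chosen_power)
    pre = network.detect_modules(
        1.0 - tom, min_size=config.min_module_size,
        cut_quantile=config.cut_quantile)
    assignment, eigengenes = network.merge_modules(
        em, pre, height=config.merge_height)
    kme = network.module_membership(em, eigengenes)
    tcor = network.module_time_correlation(eigengenes, state["design"])
    state.update(em=em, assignment=assignment, eigengenes=eigengenes, kme=kme,
                 module_time=tcor)
    scan.table.to_csv(out / "softscan.tsv", sep="\t", index=False)
    mods = pd.DataFrame({"module": assignment.labels})
    mods["kME"] = [
        kme.loc[g, m] if m != network.UNASSIGNED else float("nan")
        for g, m in assignment.labels.items()
    ]
    mods.to_csv(out / "modules.tsv", sep="\t", index_label="gene_id")
    eigengenes.profiles.to_csv(out / "eigengenes.tsv", sep="\t")
    report.digest("modules", out / "modules.tsv")
    return True, {"power": scan.chosen_power,
                  "n_modules": len(assignment.module_names()),
                  "module_sizes": assignment.module_sizes.to_dict()}


def _stage_enrich(config, state, out, report):
    if "assignment" not in state:
        return False, {"reason": "network stage did not run; no cluster input"}
    cm, ann = state["cm"], state.get("ann")
    if ann is None:
        return False, {"reason": "enrichment needs a gene annotation"}
    background = enrichment.build_background(cm, ann, mode=config.background_mode)
    lengths = ann.lengths(sorted(background.members))
    rows = []
    for mod in state["assignment"].module_names():
        cluster = network.core_members(
            state["kme"], state["assignment"], mod,
            threshold=config.kme_threshold)
        cluster = io.GeneSet(cluster.name, cluster.members & background.members)
        membership = pd.Series(
            [g in cluster.members for g in lengths.index], index=lengths.index)
        pwf = enrichment.fit_pwf(membership, lengths)
        sets = [
            io.filter_sfari_categories(lst, {"1", "2", "3", "4"}, True)
            for lst in state["lists"].values()
        ]
        fam = enrichment.test_sets_against_cluster(cluster, sets, background, pwf)
        rows.append(fam)
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    state["enrichment"] = table
    return True, {"n_tests": len(table), "background_size": len(background)}


def _stage_ror(config, state, out, report):
    if "assignment" not in state:
        return False, {"reason": "network stage did not run; no cluster input"}
    lists = state.get("lists", {})
    target = None
    for lst in lists.values():
        yes, no = io.partition_by_id_status(lst, "all")
        if len(yes) and len(no):
            target = lst
            break
    if target is None:
        return False, {"reason": "no disease list with ID annotations"}
    tcor = state["module_time"]
    pos_mods = list(tcor.index[tcor["direction"] == "pos"])
    mods = state["assignment"].module_names()
    if len(mods) < 2:
        return False, {"reason": "fewer than two modules for cross-cluster test"}
    # tissue A analogue: the development-correlated cluster; tissue B
    # analogue: the module least correlated with time (the other-tissue
    # cluster shows no positive developmental regulation)
    cluster_a_name = pos_mods[0] if pos_mods else mods[0]
    rest = [m for m in mods if m != cluster_a_name]
    cluster_b_name = min(rest, key=lambda m: abs(tcor.loc[m, "r"]))
    cluster_a = io.GeneSet(cluster_a_name,
                           state["assignment"].members(cluster_a_name))
    cluster_b = io.GeneSet(cluster_b_name,
                           state["assignment"].members(cluster_b_name))
    universe = io.GeneSet("universe", frozenset(state["cm"].gene_ids))
    results = []
    for i, stratum in enumerate(config.strata):
        id_yes, id_no = io.partition_by_id_status(target, stratum)
        if not id_yes.members or not id_no.members:
            continue
        tables = ror.tables_from_gene_sets(
            id_yes, id_no, cluster_a, cluster_b, universe, stratum=stratum)
        results.append(ror.ror_permutation_test(
            tables, n_permutations=config.permutations,
            seed=config.seed + 17 + i, stratum=stratum))
    if not results:
        return False, {"reason": "no stratum had both ID-yes and ID-no genes"}
    ror.stratified_fdr(results)
    payload = [
        {"stratum": r.stratum, "delta": r.delta, "pvalue": r.pvalue,
         "qvalue": r.qvalue, "exceedances": r.exceedances,
         "n_permutations": r.n_permutations, "seed": r.seed,
         "odds_ratios": {f"{k[0]}/{k[1]}": v for k, v in r.odds_ratios.items()},
         "ror": r.ror}
        for r in results
    ]
    with open(out / "ror.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
    state["ror_results"] = results
    return True, {"strata": [r.stratum for r in results],
                  "pvalues": [r.pvalue for r in results]}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "de": _stage_de,
    "network": _stage_network,
    "enrich": _stage_enrich,
    "ror": _stage_ror,
}
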