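"""End-to-end orchestration: load -> eligibility -> genotype QC -> PRS ->
METs -> subgroup statistics -> interaction fit -> optional prediction
harness.  Every stage is an importable library function; the pipeline is
their composition with no hidden state, and every threshold is a config
default rather than a constant buried in logic.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .activity import DEFAULT_METS_THRESHOLD, read_activity_csv, total_mets
from .cohort import Cohort, apply_eligibility, read_phenotypes, write_exclusion_report
from .genetics import (compute_prs, qc_filter_samples, qc_filter_variants,
                       filter_imputed, quartile_bins, read_dosage_tsv,
                       read_vcf, read_weights, write_scores)
from .interaction import fit_interaction
from .subgroup_stats import (DEFAULT_N_BOOT, DEFAULT_SEED, OrResult, TwoByTwo,
                             bootstrap_lr, from_counts, load_table_counts,
                             make_table, odds_ratio, standard_subgroup,
                             subgroup_report)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class Thresholds:
    max_missing: float = 0.02
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    min_call_rate: float = 0.98
    max_fhet: float = 0.2
    min_genotype_prob: float = 0.80
    min_info: float = 0.1
    min_imputed_maf: float = 0.005
    mets_threshold: float = DEFAULT_METS_THRESHOLD


@dataclass
class RunConfig:
    out_dir: str = "results"
    vcf: Optional[str] = None
    dosage_tsv: Optional[str] = None
    weights: Optional[str] = None
    phenotypes: Optional[str] = None
    activity: Optional[str] = None
    counts: Optional[str] = None          # None -> packaged transcription
    run_counts_analysis: bool = True
    run_prediction: bool = False
    seed: int = DEFAULT_SEED
    n_boot: int = DEFAULT_N_BOOT
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self):
        for name in ("vcf", "dosage_tsv", "weights", "phenotypes", "activity", "counts"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


# ---------------------------------------------------------------------------
# counts-driven analysis (the stratified-table layout)

#: (block, parent subgroup, child subgroups) layout of the two published
#: stratified tables
TABLE_LAYOUT = [
    ("family_history", "family_history", ["prs_bottom25", "prs_top25", "mets_ge450", "mets_lt450"]),
    ("age_ge35", "age_ge35", ["prs_bottom25", "prs_top25", "mets_ge450", "mets_lt450"]),
    ("bmi_ge25", "bmi_ge25", ["prs_bottom25", "prs_top25", "mets_ge450", "mets_lt450"]),
    ("prs_mets", "prs_bottom25", ["mets_lt450", "mets_ge450"]),
    ("prs_mets", "prs_top25", ["mets_lt450", "mets_ge450"]),
    ("prs_mets", "mets_ge450", ["prs_bottom25", "prs_top25"]),
    ("prs_mets", "mets_lt450", ["prs_bottom25", "prs_top25"]),
]


def analyze_tables(counts: Optional[dict] = None,
                   n_boot: int = DEFAULT_N_BOOT,
                   seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Recompute the full OR / positive-LR table family from subgroup
    counts: every parent subgroup against the rest of the cohort, every
    nested child with bootstrap p-values against the whole cohort and
    against its parent."""
    counts = counts if counts is not None else load_table_counts()
    frames = []
    for block, parent_name, child_names in TABLE_LAYOUT:
        cohort = from_counts(counts, block=block)
        parent = standard_subgroup(parent_name)
        specs = [parent] + [standard_subgroup(c, parent=parent) for c in child_names]
        rep = subgroup_report(cohort, specs, n_boot=n_boot, seed=seed)
        rep.insert(0, "block", block)
        frames.append(rep)
    return pd.concat(frames, ignore_index=True)


def quartile_figure_or(counts: Optional[dict] = None) -> OrResult:
    """Top-vs-bottom PRS-quartile OR (reference group: the lowest
    quartile, not the rest of the cohort)."""
    counts = counts if counts is not None else load_table_counts()
    top = counts["prs_mets"]["prs_top25"]
    bot = counts["prs_mets"]["prs_bottom25"]
    t = TwoByTwo(cases_in=top["cases"], controls_in=top["controls"],
                 cases_out=bot["cases"], controls_out=bot["controls"])
    return odds_ratio(t)


def interaction_from_counts(counts: Optional[dict] = None) -> "InteractionFit":
    """Unadjusted interaction fit on the cohort expanded from the
    PRS-quartile x METs cells."""
    counts = counts if counts is not None else load_table_counts()
    cohort = from_counts(counts, block="prs_mets")
    return fit_interaction(cohort, adjust_confounders=False)


# ---------------------------------------------------------------------------
# full pipeline

def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write TSV/JSON results plus a run
    log (versions, seed, thresholds) under ``config.out_dir``.  Returns the
    result bundle as a dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    log = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "thresholds": dataclasses.asdict(config.thresholds),
        "stages": [],
    }

    cohort: Optional[Cohort] = None
    if config.phenotypes:
        cohort = _stage("load_phenotypes")(read_phenotypes)(config.phenotypes)
        if config.activity:
            records = _stage("load_activity")(read_activity_csv)(config.activity)
            for p in cohort.participants:
                if p.id in records and p.mets is None:
                    p.mets = total_mets(records[p.id])
        log["stages"].append("load")

    genotypes = None
    if config.vcf or config.dosage_tsv:
        reader = read_vcf if config.vcf else read_dosage_tsv
        genotypes = _stage("load_genotypes")(reader)(config.vcf or config.dosage_tsv)
        th = config.thresholds
        genotypes, variant_fate = _stage("qc_variants")(qc_filter_variants)(
            genotypes, th.max_missing, th.min_maf, th.min_hwe_p)
        genotypes, sample_fate = _stage("qc_samples")(qc_filter_samples)(
            genotypes, th.min_call_rate, th.max_fhet)
        if not genotypes.variants["typed"].all():
            genotypes, imputed_fate = _stage("filter_imputed")(filter_imputed)(
                genotypes, th.min_genotype_prob, th.min_info, th.min_imputed_maf)
            imputed_fate.to_csv(out / "imputed_fate.tsv", sep="\t", index=False)
        variant_fate.to_csv(out / "variant_qc.tsv", sep="\t", index=False)
        sample_fate.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
        log["stages"].append("qc")

    if genotypes is not None and config.weights:
        weights = _stage("load_weights")(read_weights)(config.weights)
        scores, match_report = _stage("prs")(compute_prs)(genotypes, weights)
        bins = quartile_bins(scores)
        write_scores(bins, out / "prs_scores.tsv")
        bundle["prs_match_report"] = match_report
        if cohort is not None:
            # genotype-derived scores supersede any phenotype-file PRS;
            # samples dropped by QC lose their score and fall to the
            # missing-PRS eligibility step
            lookup = dict(zip(bins.index, bins.itertuples()))
            for p in cohort.participants:
                row = lookup.get(p.id)
                if row is not None:
                    p.prs = row.prs
                    p.prs_top25 = bool(row.top25)
                    p.prs_bottom25 = bool(row.bottom25)
                else:
                    p.prs = None
                    p.prs_top25 = None
                    p.prs_bottom25 = None
        log["stages"].append("prs")

    if cohort is not None:
        for p in cohort.participants:
            if p.mets is not None:
                p.mets_low = p.mets < config.thresholds.mets_threshold
            if p.age is not None:
                p.age_ge35 = p.age >= 35
            if p.bmi is not None:
                p.bmi_ge25 = p.bmi >= 25
        cohort, report = _stage("eligibility")(apply_eligibility)(cohort)
        write_exclusion_report(report, out / "exclusion_report.json")
        bundle["exclusion_report"] = report
        log["stages"].append("eligibility")

    if cohort is not None and len(cohort) > 0:
        parent_names = ["prs_top25", "prs_bottom25", "mets_lt450", "mets_ge450"]
        specs = []
        for name in parent_names:
            parent = standard_subgroup(name)
            specs.append(parent)
            others = (["mets_lt450", "mets_ge450"] if name.startswith("prs")
                      else ["prs_bottom25", "prs_top25"])
            specs.extend(standard_subgroup(c, parent=parent) for c in others)
        rep = _stage("subgroup_stats")(subgroup_report)(
            cohort, specs, n_boot=config.n_boot, seed=config.seed)
        rep.to_csv(out / "subgroups.tsv", sep="\t", index=False)
        bundle["subgroups"] = rep
        fit = _stage("interaction")(fit_interaction)(cohort, adjust_confounders=False)
        fit.to_json(out / "interaction.json")
        bundle["interaction"] = fit
        log["stages"].append("analysis")
        if config.run_prediction:
            from .prediction import baseline_features, evaluate_model, with_mets, with_prs
            base = baseline_features()
            results = {}
            for name, feats in [("baseline", base), ("baseline+prs", with_prs(base)),
                                ("baseline+mets", with_mets(base)),
                                ("baseline+prs+mets", with_mets(with_prs(base)))]:
                results[name] = _stage("prediction")(evaluate_model)(
                    cohort, feats, seed=config.seed, model_name=name)
            pd.DataFrame(
                [dataclasses.asdict(r) for r in results.values()]
            ).drop(columns=["fold_aucs"]).to_csv(out / "prediction_auc.tsv",
                                                 sep="\t", index=False)
            bundle["prediction"] = results
            log["stages"].append("prediction")

    if config.run_counts_analysis:
        counts = load_table_counts(config.counts)
        tables = _stage("counts_analysis")(analyze_tables)(
            counts, n_boot=config.n_boot, seed=config.seed)
        tables.to_csv(out / "tables_or_lr.tsv", sep="\t", index=False)
        bundle["tables"] = tables
        fit = _stage("counts_interaction")(interaction_from_counts)(counts)
        fit.to_json(out / "counts_interaction.json")
        bundle["counts_interaction"] = fit
        log["stages"].append("counts_analysis")

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    bundle["log"] = log
    return bundle
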