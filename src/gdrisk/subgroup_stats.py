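"""Subgroup contingency statistics: 2x2 tables, odds ratios with Woolf CIs
and Fisher exact tests, positive likelihood ratios, and bootstrap p-values
for nested subgroups.

All subgroup effect measures reduce to a 2x2 table of (cases, controls)
inside vs outside the subgroup.  The odds ratio compares the subgroup with
the rest of the cohort; the positive likelihood ratio (LR) is the ratio of
posterior odds (odds of disease inside the subgroup) to prior odds (odds in
a reference group: the whole cohort, or the subgroup's parent).  Bootstrap
p-values resample whole participants with replacement and compare the
child subgroup's LR against the parent's in each replicate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, Participant

DEFAULT_SEED = 20220830
DEFAULT_N_BOOT = 10_000


@dataclass(frozen=True)
class TwoByTwo:
    """Subgroup-membership x disease-status counts."""

    cases_in: int
    controls_in: int
    cases_out: int
    controls_out: int

    def __post_init__(self):
        counts = (self.cases_in, self.controls_in, self.cases_out, self.controls_out)
        if any(c < 0 for c in counts):
            raise ValueError(f"counts must be non-negative, got {counts}")
        if sum(counts) == 0:
            raise ValueError("empty table")

    @property
    def n_in(self) -> int:
        return self.cases_in + self.controls_in

    @property
    def total_cases(self) -> int:
        return self.cases_in + self.cases_out

    @property
    def total_controls(self) -> int:
        return self.controls_in + self.controls_out

    def as_array(self) -> np.ndarray:
        return np.array([[self.cases_in, self.controls_in],
                         [self.cases_out, self.controls_out]], dtype=float)


@dataclass
class SubgroupSpec:
    """A named predicate over participants, optionally nested in a parent
    subgroup (child membership must be a subset of the parent's)."""

    name: str
    predicate: Callable[[Participant], Optional[bool]]
    parent: Optional["SubgroupSpec"] = None

    def membership(self, cohort: Cohort) -> np.ndarray:
        out = np.empty(len(cohort), dtype=bool)
        for i, p in enumerate(cohort):
            v = self.predicate(p)
            if v is None:
                raise ValueError(
                    f"subgroup {self.name!r}: predicate unevaluable for participant {p.id}"
                )
            out[i] = bool(v)
        if self.parent is not None:
            par = self.parent.membership(cohort)
            if np.any(out & ~par):
                raise ValueError(
                    f"subgroup {self.name!r} is not nested in parent {self.parent.name!r}"
                )
        return out


@dataclass
class OrResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    fisher_p: float
    table: TwoByTwo
    continuity_corrected: bool = False


@dataclass
class LrResult:
    lr_estimate: float
    ci_low: float
    ci_high: float
    p_vs_all: float
    p_vs_parent: Optional[float]
    n_boot: int
    seed: int
    direction_vs_all: str = "auto"
    direction_vs_parent: Optional[str] = None
    n_dropped_replicates: int = 0


def make_table(cohort: Cohort, subgroup: SubgroupSpec) -> TwoByTwo:
    """Count GD cases/controls inside the subgroup and in the rest of the
    cohort."""
    member = subgroup.membership(cohort)
    gd = np.empty(len(cohort), dtype=bool)
    for i, p in enumerate(cohort):
        if p.gd is None:
            raise ValueError(f"participant {p.id} has no GD outcome")
        gd[i] = p.gd
    return TwoByTwo(
        cases_in=int(np.sum(member & gd)),
        controls_in=int(np.sum(member & ~gd)),
        cases_out=int(np.sum(~member & gd)),
        controls_out=int(np.sum(~member & ~gd)),
    )


def odds_ratio(t: TwoByTwo, alpha: float = 0.05) -> OrResult:
    """OR of the subgroup vs the rest of the cohort with a Woolf
    (log-normal) confidence interval and a two-sided Fisher exact p.

    A zero cell triggers the Haldane-Anscombe +0.5 correction for the
    OR/CI (flagged in the result); the Fisher p always uses the raw counts.
    """
    cells = [t.cases_in, t.controls_in, t.cases_out, t.controls_out]
    if (t.cases_in + t.cases_out == 0) or (t.controls_in + t.controls_out == 0) \
            or (t.n_in == 0) or (t.cases_out + t.controls_out == 0):
        raise ValueError(f"a table margin is zero; OR undefined: {cells}")
    corrected = any(c == 0 for c in cells)
    a, b, c, d = [x + 0.5 for x in cells] if corrected else [float(x) for x in cells]
    or_est = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = math.exp(math.log(or_est) - z * se), math.exp(math.log(or_est) + z * se)
    _, p = stats.fisher_exact(
        [[t.cases_in, t.controls_in], [t.cases_out, t.controls_out]],
        alternative="two-sided",
    )
    return OrResult(or_est, lo, hi, float(p), t, corrected)


def positive_lr(
    t: TwoByTwo,
    reference: Literal["whole_cohort", "parent"] = "whole_cohort",
    parent_table: Optional[TwoByTwo] = None,
) -> float:
    """Positive likelihood ratio: posterior odds (cases_in/controls_in)
    over prior odds of the reference group (whole cohort, or the parent
    subgroup's own counts)."""
    if reference == "whole_cohort":
        ref_cases, ref_controls = t.total_cases, t.total_controls
    elif reference == "parent":
        if parent_table is None:
            raise ValueError("parent reference requires parent_table")
        ref_cases, ref_controls = parent_table.cases_in, parent_table.controls_in
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if ref_cases == 0 or ref_controls == 0:
        raise ValueError("reference odds undefined (zero cases or controls)")
    if t.controls_in == 0:
        warnings.warn("subgroup has no controls; positive LR is infinite", stacklevel=2)
        return math.inf
    prior = ref_cases / ref_controls
    posterior = t.cases_in / t.controls_in
    return posterior / prior


def _one_sided_p(child_lr: np.ndarray, null_value: np.ndarray | float,
                 direction: str, observed: float, observed_null: float
                 ) -> tuple[float, str]:
    """Proportion of replicates on the null side; ties count 0.5."""
    if direction == "auto":
        direction = "greater" if observed >= observed_null else "less"
    if direction == "greater":  # alternative: child LR > null -> null side is <=
        p = np.mean(child_lr < null_value) + 0.5 * np.mean(child_lr == null_value)
    elif direction == "less":
        p = np.mean(child_lr > null_value) + 0.5 * np.mean(child_lr == null_value)
    else:
        raise ValueError(f"direction must be auto/greater/less, got {direction!r}")
    return float(p), direction


def bootstrap_lr(
    cohort: Cohort,
    subgroup: SubgroupSpec,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    direction: str = "auto",
) -> LrResult:
    """Bootstrap the subgroup's positive LR (reference: whole cohort).

    Participants are resampled with replacement ``n_boot`` times; because
    every statistic depends on the data only through the joint counts of
    (outcome, child membership, parent membership), the row resampling is
    carried out exactly as a single multinomial draw over those (at most 6)
    categories per replicate.  Per replicate the child LR (vs the whole
    replicate cohort) and the parent LR are recomputed; ``p_vs_parent`` is
    the proportion of replicates in which the child LR falls on the null
    side of the parent LR (side chosen from the observed comparison when
    ``direction="auto"``; ties count 0.5), and ``p_vs_all`` is the analogue
    against the whole-cohort LR null value of 1.  The percentile 2.5/97.5
    bounds of the child-LR replicates give the 95% CI.  Deterministic under
    a fixed seed; the point estimate is computed on the original cohort.
    """
    child = subgroup.membership(cohort)
    parent = (subgroup.parent.membership(cohort)
              if subgroup.parent is not None else np.ones(len(cohort), dtype=bool))
    gd = np.array([bool(p.gd) for p in cohort])

    # joint categories: 0=out, 1=parent-only, 2=child; x case/control
    stratum = np.where(child, 2, np.where(parent, 1, 0))
    counts = np.zeros(6, dtype=np.int64)
    for s in range(3):
        counts[2 * s] = int(np.sum((stratum == s) & gd))        # cases
        counts[2 * s + 1] = int(np.sum((stratum == s) & ~gd))   # controls
    n = int(counts.sum())

    t_child = TwoByTwo(counts[4], counts[5], counts[0] + counts[2], counts[1] + counts[3])
    obs_child_lr = positive_lr(t_child)
    has_parent = subgroup.parent is not None
    if has_parent:
        t_parent = TwoByTwo(counts[2] + counts[4], counts[3] + counts[5],
                            counts[0], counts[1])
        obs_parent_lr = positive_lr(t_parent)
    else:
        obs_parent_lr = None

    rng = np.random.default_rng(seed)
    reps = rng.multinomial(n, counts / n, size=n_boot).astype(float)
    case_out, ctrl_out = reps[:, 0], reps[:, 1]
    case_po, ctrl_po = reps[:, 2], reps[:, 3]
    case_ch, ctrl_ch = reps[:, 4], reps[:, 5]
    tot_cases = case_out + case_po + case_ch
    tot_ctrls = ctrl_out + ctrl_po + ctrl_ch
    valid = (case_ch + ctrl_ch > 0) & (ctrl_ch > 0) & (tot_cases > 0) & (tot_ctrls > 0)
    parent_cases = case_po + case_ch
    parent_ctrls = ctrl_po + ctrl_ch
    if has_parent:
        valid &= parent_ctrls > 0
    n_dropped = int(n_boot - valid.sum())
    if n_dropped > 0.1 * n_boot:
        warnings.warn(
            f"{n_dropped}/{n_boot} bootstrap replicates dropped (empty subgroup "
            "or undefined odds)", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        child_lr = (case_ch / ctrl_ch) / (tot_cases / tot_ctrls)
        parent_lr = (parent_cases / parent_ctrls) / (tot_cases / tot_ctrls)
    child_lr = child_lr[valid]
    parent_lr = parent_lr[valid]

    ci_low, ci_high = np.percentile(child_lr, [2.5, 97.5])
    p_all, dir_all = _one_sided_p(child_lr, 1.0, direction, obs_child_lr, 1.0)
    if has_parent:
        p_par, dir_par = _one_sided_p(child_lr, parent_lr, direction,
                                      obs_child_lr, obs_parent_lr)
    else:
        p_par, dir_par = None, None
    return LrResult(
        lr_estimate=obs_child_lr, ci_low=float(ci_low), ci_high=float(ci_high),
        p_vs_all=p_all, p_vs_parent=p_par, n_boot=n_boot, seed=seed,
        direction_vs_all=dir_all, direction_vs_parent=dir_par,
        n_dropped_replicates=n_dropped,
    )


# ---------------------------------------------------------------------------
# Expansion of published contingency counts into individual-level cohorts


def load_table_counts(path=None) -> dict:
    """Load the packaged transcription of the published subgroup counts
    (or a user-supplied JSON with the same schema)."""
    if path is not None:
        with open(path) as fh:
            return json.load(fh)
    with resources.files("gdrisk.data").joinpath("tables_counts.json").open() as fh:
        return json.load(fh)


def _check_nested(parent_name, parent_cc, child_name, child_cc):
    if child_cc[0] > parent_cc[0] or child_cc[1] > parent_cc[1]:
        raise ValueError(
            f"inconsistent nesting: {child_name} ({child_cc}) exceeds "
            f"{parent_name} ({parent_cc})"
        )


def _participants(prefix: str, n_cases: int, n_controls: int, start: int,
                  **flags) -> tuple[list[Participant], int]:
    out = []
    k = start
    for gd, count in ((True, n_cases), (False, n_controls)):
        for _ in range(count):
            out.append(Participant(id=f"{prefix}{k:05d}", gd=gd, **flags))
            k += 1
    return out, k


def from_counts(counts: dict, block: str = "prs_mets") -> Cohort:
    """Expand published subgroup counts into an individual-level cohort.

    ``block`` selects the cross-classification to expand:

    * ``"prs_mets"`` — the PRS-quartile x METs table, whose six joint design
      cells (PRS bottom/middle/top quartile group x METs </>= 450) are fully
      recoverable by subtraction; every participant carries consistent
      ``prs_top25``/``prs_bottom25``/``mets_low`` flags.
    * ``"family_history"`` / ``"age_ge35"`` / ``"bmi_ge25"`` — one clinical
      covariate block: the parent flag everywhere, and within the parent the
      nested PRS and METs flags with the published margins (sibling overlap
      within a parent is not identified by the counts and is assigned
      arbitrarily; no computed statistic depends on it).

    Re-deriving any published table from the output via ``make_table``
    returns the input counts exactly.
    """
    total = (counts["cohort"]["cases"], counts["cohort"]["controls"])
    if block == "prs_mets":
        return _expand_prs_mets(counts, total)
    if block in counts.get("covariate_blocks", {}):
        return _expand_covariate_block(counts, block, total)
    raise ValueError(f"unknown block {block!r}")


def _cc(rec) -> tuple[int, int]:
    return int(rec["cases"]), int(rec["controls"])


def _expand_prs_mets(counts: dict, total) -> Cohort:
    pm = counts["prs_mets"]
    bot = _cc(pm["prs_bottom25"])
    top = _cc(pm["prs_top25"])
    low = _cc(pm["mets_lt450"])
    bot_low = _cc(pm["prs_bottom25"]["children"]["mets_lt450"])
    bot_high = _cc(pm["prs_bottom25"]["children"]["mets_ge450"])
    top_low = _cc(pm["prs_top25"]["children"]["mets_lt450"])
    top_high = _cc(pm["prs_top25"]["children"]["mets_ge450"])
    for name, parent_cc, child_name, child_cc in [
        ("prs_bottom25", bot, "prs_bottom25&mets_lt450", bot_low),
        ("prs_bottom25", bot, "prs_bottom25&mets_ge450", bot_high),
        ("prs_top25", top, "prs_top25&mets_lt450", top_low),
        ("prs_top25", top, "prs_top25&mets_ge450", top_high),
    ]:
        _check_nested(name, parent_cc, child_name, child_cc)
    if (bot_low[0] + bot_high[0], bot_low[1] + bot_high[1]) != bot:
        raise ValueError("inconsistent nesting: prs_bottom25 children do not sum to parent")
    if (top_low[0] + top_high[0], top_low[1] + top_high[1]) != top:
        raise ValueError("inconsistent nesting: prs_top25 children do not sum to parent")
    mid_low = (low[0] - bot_low[0] - top_low[0], low[1] - bot_low[1] - top_low[1])
    mid = (total[0] - bot[0] - top[0], total[1] - bot[1] - top[1])
    mid_high = (mid[0] - mid_low[0], mid[1] - mid_low[1])
    for name, cc in [("middle&mets_lt450", mid_low), ("middle&mets_ge450", mid_high)]:
        if cc[0] < 0 or cc[1] < 0:
            raise ValueError(f"inconsistent counts: derived cell {name} negative: {cc}")
    cells = [
        (bot_low, dict(prs_bottom25=True, prs_top25=False, mets_low=True)),
        (bot_high, dict(prs_bottom25=True, prs_top25=False, mets_low=False)),
        (mid_low, dict(prs_bottom25=False, prs_top25=False, mets_low=True)),
        (mid_high, dict(prs_bottom25=False, prs_top25=False, mets_low=False)),
        (top_low, dict(prs_bottom25=False, prs_top25=True, mets_low=True)),
        (top_high, dict(prs_bottom25=False, prs_top25=True, mets_low=False)),
    ]
    participants: list[Participant] = []
    k = 0
    for (nc, nk), flags in cells:
        ps, k = _participants("pm", nc, nk, k, **flags)
        participants.extend(ps)
    return Cohort(participants, provenance=["expanded from prs_mets counts"])


def _expand_covariate_block(counts: dict, block: str, total) -> Cohort:
    rec = counts["covariate_blocks"][block]
    parent = _cc(rec["parent"])
    kids = rec["children"]
    prs_bot = _cc(kids["prs_bottom25"])
    prs_top = _cc(kids["prs_top25"])
    mets_low = _cc(kids["mets_lt450"])
    mets_high = _cc(kids["mets_ge450"])
    for name, cc in kids.items():
        _check_nested(block, parent, f"{block}&{name}", _cc(cc))
    if (prs_bot[0] + prs_top[0] > parent[0]) or (prs_bot[1] + prs_top[1] > parent[1]):
        raise ValueError(f"inconsistent nesting: PRS children exceed parent {block}")
    if (mets_low[0] + mets_high[0], mets_low[1] + mets_high[1]) != parent:
        raise ValueError(f"inconsistent nesting: METs children do not partition parent {block}")
    flag_field = {"family_history": "family_history_diabetes",
                  "age_ge35": "age_ge35", "bmi_ge25": "bmi_ge25"}[block]

    participants: list[Participant] = []
    k = 0
    # inside the parent: PRS assignment (bottom, top, middle) and the METs
    # partition are laid out independently over a shared ordering
    for gd, n_par in ((True, parent[0]), (False, parent[1])):
        j = 0 if gd else 1
        n_bot, n_top, n_low = prs_bot[j], prs_top[j], mets_low[j]
        for i in range(n_par):
            flags = {
                flag_field: True,
                "prs_bottom25": i < n_bot,
                "prs_top25": n_bot <= i < n_bot + n_top,
                "mets_low": i < n_low,
            }
            participants.append(Participant(id=f"{block[:2]}{k:05d}", gd=gd, **flags))
            k += 1
    # the rest of the cohort: parent flag False, nested flags unknown
    rest = (total[0] - parent[0], total[1] - parent[1])
    if rest[0] < 0 or rest[1] < 0:
        raise ValueError(f"inconsistent counts: {block} parent exceeds cohort totals")
    ps, k = _participants(block[:2], rest[0], rest[1], k, **{flag_field: False})
    participants.extend(ps)
    return Cohort(participants, provenance=[f"expanded from {block} counts"])


# ---------------------------------------------------------------------------
# Predicate helpers for the standard subgroups

_FLAG_PREDICATES: dict[str, Callable[[Participant], Optional[bool]]] = {
    "family_history": lambda p: p.family_history_diabetes,
    "age_ge35": lambda p: p.age_ge35 if p.age_ge35 is not None
    else (p.age >= 35 if p.age is not None else None),
    "bmi_ge25": lambda p: p.bmi_ge25 if p.bmi_ge25 is not None
    else (p.bmi >= 25 if p.bmi is not None else None),
    "prs_top25": lambda p: p.prs_top25,
    "prs_bottom25": lambda p: p.prs_bottom25,
    "mets_lt450": lambda p: p.mets_low,
    "mets_ge450": lambda p: (None if p.mets_low is None else not p.mets_low),
}


def standard_subgroup(name: str, parent: Optional[SubgroupSpec] = None) -> SubgroupSpec:
    """Build a SubgroupSpec for one of the named standard flags, optionally
    nested in a parent (the predicate is then the conjunction)."""
    base = _FLAG_PREDICATES[name]
    if parent is None:
        return SubgroupSpec(name, base)

    def pred(p: Participant, _base=base, _parent=parent):
        pv = _parent.predicate(p)
        if pv is False:
            return False
        bv = _base(p)
        if pv is None or bv is None:
            return None
        return bool(pv) and bool(bv)

    return SubgroupSpec(f"{parent.name}&{name}", pred, parent=parent)


REPORT_COLUMNS = [
    "subgroup", "parent", "cases_in", "controls_in", "or", "or_ci_low", "or_ci_high",
    "fisher_p", "lr", "lr_ci_low", "lr_ci_high", "p_vs_all", "p_vs_parent",
    "n_boot", "seed",
]


def subgroup_report(
    cohort: Cohort,
    specs: Sequence[SubgroupSpec],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """One row per subgroup with OR, Woolf CI, Fisher p, positive LR,
    bootstrap CI, and bootstrap p-values; column order is stable."""
    rows = []
    for spec in specs:
        t = make_table(cohort, spec)
        orr = odds_ratio(t)
        lrr = bootstrap_lr(cohort, spec, n_boot=n_boot, seed=seed)
        rows.append({
            "subgroup": spec.name,
            "parent": spec.parent.name if spec.parent else "",
            "cases_in": t.cases_in, "controls_in": t.controls_in,
            "or": orr.or_estimate, "or_ci_low": orr.ci_low, "or_ci_high": orr.ci_high,
            "fisher_p": orr.fisher_p,
            "lr": lrr.lr_estimate, "lr_ci_low": lrr.ci_low, "lr_ci_high": lrr.ci_high,
            "p_vs_all": lrr.p_vs_all, "p_vs_parent": lrr.p_vs_parent,
            "n_boot": n_boot, "seed": seed,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
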