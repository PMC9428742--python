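"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: a nulliparous
cohort with roughly 3.7% GD prevalence, a raw-scale T2D polygenic score
with mean about 8.3 and SD about 0.55 built from 84 independent biallelic
variants, right-skewed weekly METs (lognormal, mean about 900, SD about
950), and a logistic outcome model with a positive PRS x inactivity
interaction.  It does not model linkage disequilibrium, ancestry structure,
or longitudinal visits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import Cohort, Participant
from .genetics import (MISSING_CALL, GenotypeMatrix, VariantWeight,
                       compute_prs, quartile_bins)

# fixed per-component offsets for the seed fan-out, so adding a component
# never perturbs earlier draws
_STREAMS = {
    "panel": 0, "genotypes": 1, "age": 2, "bmi": 3, "mets": 4,
    "family_history": 5, "outcome": 6, "missingness": 7, "waist": 8, "race": 9,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[component],))
    )


@dataclass
class ModelCoeffs:
    """Outcome-logit coefficients; ``a`` (intercept) is solved numerically
    for the prevalence target when None."""

    a: Optional[float] = None
    b: float = 0.10   # per year of age
    c: float = 0.08   # per kg/m^2 of BMI
    d: float = 0.41   # high PRS (top quartile)
    e: float = 0.10   # low METs (< 450)
    f: float = 0.78   # interaction


@dataclass
class SyntheticConfig:
    n: int = 3533
    seed: int = 20220830
    prevalence_target: float = 0.037
    age_mean: float = 28.6
    age_sd: float = 4.9
    bmi_mean: float = 26.5
    bmi_sd: float = 5.5
    mets_mean: float = 900.0
    mets_sd: float = 950.0
    fam_hist_prob: float = 0.18
    n_variants: int = 84
    allele_freqs: Optional[np.ndarray] = None   # drawn U(0.1, 0.9) when None
    betas: Optional[np.ndarray] = None          # positive, scaled to PRS mean target
    prs_mean_target: float = 8.3
    mets_threshold: float = 450.0
    model_coeffs: ModelCoeffs = field(default_factory=ModelCoeffs)

    def __post_init__(self):
        if self.n < 100:
            raise ValueError("n must be >= 100")
        for name in ("prevalence_target", "fam_hist_prob"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @property
    def mets_lognorm_params(self) -> tuple[float, float]:
        """(mu, sigma) of the lognormal matching the METs mean/SD."""
        cv2 = (self.mets_sd / self.mets_mean) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(self.mets_mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)


def _panel(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, list[VariantWeight]]:
    rng = _rng(config.seed, "panel")
    m = config.n_variants
    freqs = (np.asarray(config.allele_freqs, dtype=float)
             if config.allele_freqs is not None else rng.uniform(0.1, 0.9, size=m))
    if config.betas is not None:
        betas = np.asarray(config.betas, dtype=float)
    else:
        raw = np.abs(rng.normal(1.0, 0.5, size=m)) + 0.05
        betas = raw * config.prs_mean_target / float(np.sum(2.0 * freqs * raw))
    bases = np.array(["A", "C", "G", "T"])
    weights = []
    for i in range(m):
        ref, alt = rng.choice(bases, size=2, replace=False)
        # avoid strand-ambiguous pairs in the synthetic panel
        while {ref, alt} in ({"A", "T"}, {"C", "G"}):
            ref, alt = rng.choice(bases, size=2, replace=False)
        weights.append(VariantWeight(f"rs{100000 + i}", alt, ref, float(betas[i])))
    return freqs, betas, weights


def simulate_cohort(config: SyntheticConfig
                    ) -> tuple[Cohort, GenotypeMatrix, dict]:
    """Draw a full synthetic cohort.

    Genotypes are variant-wise binomial(2, freq); the PRS is computed with
    the production scorer; covariates follow the configured marginals; the
    GD outcome is Bernoulli under the logit model with the intercept solved
    so the expected prevalence hits the target.  Returns (cohort, genotype
    matrix, truth record with every generating parameter).
    """
    n, m = config.n, config.n_variants
    freqs, betas, weights = _panel(config)

    g_rng = _rng(config.seed, "genotypes")
    hard = g_rng.binomial(2, freqs[:, None], size=(m, n)).astype(np.int8)
    variants = pd.DataFrame({
        "rsid": [w.rsid for w in weights],
        "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1) * 1000,
        "ref": [w.other_allele for w in weights],
        "alt": [w.effect_allele for w in weights],
        "typed": True,
        "info": np.nan,
    })
    samples = [f"s{i:05d}" for i in range(n)]
    genotypes = GenotypeMatrix(samples=samples, variants=variants,
                               dosages=hard.astype(float), hard_calls=hard)
    prs, _ = compute_prs(genotypes, weights)
    bins = quartile_bins(prs)

    age = np.clip(_rng(config.seed, "age").normal(config.age_mean, config.age_sd, n), 16, 50)
    bmi = np.clip(_rng(config.seed, "bmi").normal(config.bmi_mean, config.bmi_sd, n), 15, 60)
    mu, sigma = config.mets_lognorm_params
    mets = _rng(config.seed, "mets").lognormal(mu, sigma, n)
    fam = _rng(config.seed, "family_history").random(n) < config.fam_hist_prob
    waist = np.clip(_rng(config.seed, "waist").normal(85.0, 12.0, n), 50, 180)
    race = _rng(config.seed, "race").choice(["groupA", "groupB"], p=[0.85, 0.15], size=n)

    prs_arr = prs.to_numpy()
    bottom25 = bins["bottom25"].to_numpy()
    x3 = bins["top25"].to_numpy()
    x4 = mets < config.mets_threshold
    co = config.model_coeffs
    eta = co.b * age + co.c * bmi + co.d * x3 + co.e * x4 + co.f * (x3 & x4)

    if co.a is None:
        def gap(a):
            return float(np.mean(expit(a + eta))) - config.prevalence_target
        try:
            a = brentq(gap, -50.0, 50.0)
        except ValueError as exc:
            raise ValueError(
                "prevalence target unreachable: intercept solve failed "
                f"(target {config.prevalence_target})"
            ) from exc
    else:
        a = co.a
    p_gd = expit(a + eta)
    gd = _rng(config.seed, "outcome").random(n) < p_gd

    participants = [
        Participant(
            id=samples[i], age=float(age[i]), bmi=float(bmi[i]), waist=float(waist[i]),
            family_history_diabetes=bool(fam[i]), pcos=False, hypertension=False,
            mets=float(mets[i]), prs=float(prs_arr[i]), gd=bool(gd[i]),
            race_ethnicity=str(race[i]),
            prs_top25=bool(x3[i]), prs_bottom25=bool(bottom25[i]),
            mets_low=bool(x4[i]),
            age_ge35=bool(age[i] >= 35), bmi_ge25=bool(bmi[i] >= 25),
        )
        for i in range(n)
    ]
    cohort = Cohort(participants, provenance=[f"simulated (seed={config.seed}, n={n})"])
    truth = {
        "seed": config.seed, "n": n,
        "allele_freqs": freqs.tolist(), "betas": betas.tolist(),
        "coeffs": {"a": float(a), "b": co.b, "c": co.c, "d": co.d, "e": co.e, "f": co.f},
        "prevalence_target": config.prevalence_target,
        "realized_prevalence": float(np.mean(gd)),
        "prs_mean": float(prs.mean()), "prs_sd": float(prs.std()),
        "mets_mean": float(np.mean(mets)), "mets_sd": float(np.std(mets)),
    }
    return cohort, genotypes, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def inject_missingness(
    cohort: Optional[Cohort] = None,
    genotypes: Optional[GenotypeMatrix] = None,
    rates: Optional[dict] = None,
    seed: int = 0,
):
    """Mask entries completely at random, returning corrupted copies and the
    truth masks.

    ``rates`` maps targets to missingness probabilities in [0, 1):
    ``"genotypes"`` masks genotype calls; any Participant field name (e.g.
    ``"mets"``, ``"prs"``) masks that field.  Returns
    ``(cohort_copy, genotypes_copy, masks)`` where masks hold boolean arrays
    of what was removed.
    """
    rates = rates or {}
    for k, r in rates.items():
        if not 0.0 <= r < 1.0:
            raise ValueError(f"rate for {k!r} must lie in [0, 1), got {r}")
    rng = _rng(seed, "missingness")
    masks: dict[str, np.ndarray] = {}

    new_geno = genotypes
    if genotypes is not None and rates.get("genotypes", 0) > 0:
        mask = rng.random(genotypes.dosages.shape) < rates["genotypes"]
        dos = genotypes.dosages.copy()
        dos[mask] = np.nan
        hard = None
        if genotypes.hard_calls is not None:
            hard = genotypes.hard_calls.copy()
            hard[mask] = MISSING_CALL
        new_geno = replace(genotypes, dosages=dos, hard_calls=hard)
        masks["genotypes"] = mask

    new_cohort = cohort
    if cohort is not None:
        field_rates = {k: r for k, r in rates.items() if k != "genotypes" and r > 0}
        ps = list(cohort.participants)
        for fname, r in field_rates.items():
            mask = rng.random(len(ps)) < r
            ps = [replace(p, **{fname: None}) if hit else p for p, hit in zip(ps, mask)]
            masks[fname] = mask
        new_cohort = Cohort(ps, cohort.provenance + [f"missingness injected: {field_rates}"])
    return new_cohort, new_geno, masks
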