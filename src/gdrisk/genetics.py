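"""Genotype container, QC filters, and weighted-allele polygenic risk
scoring.

The polygenic risk score (PRS) of a sample is the sum over matched variants
of the effect-allele dosage weighted by the per-variant effect size beta
(a log-odds weight from a prior association study):

    score_i = sum_v beta_v * dosage_i(effect allele at v)

QC recomputes per-variant missingness, minor-allele frequency (MAF) and the
Hardy-Weinberg equilibrium (HWE) exact-test p-value from the calls rather
than trusting input metadata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MISSING_CALL = -1
_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}
_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class VariantWeight:
    """One PRS locus: effect/other alleles and the per-allele weight beta."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    info: Optional[float] = None

    def __post_init__(self):
        ea, oa = self.effect_allele.upper(), self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in _BASES or oa not in _BASES:
            raise ValueError(f"{self.rsid}: alleles must be A/C/G/T, got {ea}/{oa}")
        if ea == oa:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: beta must be finite")
        if self.info is not None and not (0.0 <= self.info <= 1.0):
            raise ValueError(f"{self.rsid}: info must lie in [0, 1]")

    @property
    def palindromic(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in _PALINDROMIC


def read_weights(path) -> list[VariantWeight]:
    """TSV with header rsid/effect_allele/other_allele/beta[/info]."""
    df = pd.read_csv(path, sep="\t")
    has_info = "info" in df.columns
    return [
        VariantWeight(
            str(r.rsid), str(r.effect_allele), str(r.other_allele), float(r.beta),
            float(r.info) if has_info and pd.notna(r.info) else None,
        )
        for r in df.itertuples()
    ]


def write_weights(weights: Sequence[VariantWeight], path) -> None:
    pd.DataFrame(
        [(w.rsid, w.effect_allele, w.other_allele, w.beta, w.info) for w in weights],
        columns=["rsid", "effect_allele", "other_allele", "beta", "info"],
    ).to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Variants x samples genotypes.

    ``dosages`` holds alt-allele dosages in [0, 2] with NaN for missing;
    ``hard_calls`` the corresponding {0,1,2} calls with -1 for missing;
    ``genotype_probs`` the per-call maximum genotype probability (imputed
    data only).  ``variants`` is a DataFrame with columns rsid, chrom, pos,
    ref, alt, typed (directly genotyped vs imputed) and info (imputation
    quality, NaN when not applicable).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    hard_calls: Optional[np.ndarray] = None
    genotype_probs: Optional[np.ndarray] = None

    def __post_init__(self):
        n_v, n_s = len(self.variants), len(self.samples)
        if self.dosages.shape != (n_v, n_s):
            raise ValueError(
                f"dosages shape {self.dosages.shape} != ({n_v} variants, {n_s} samples)"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 2] where present")
        for name in ("hard_calls", "genotype_probs"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (n_v, n_s):
                raise ValueError(f"{name} shape mismatch")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def _calls(self) -> np.ndarray:
        if self.hard_calls is not None:
            return self.hard_calls
        hc = np.where(np.isnan(self.dosages), MISSING_CALL, np.rint(self.dosages))
        return hc.astype(np.int8)

    # per-variant statistics, always recomputed from the calls --------------
    def variant_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=1)

    def alt_allele_freq(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            return np.nanmean(self.dosages, axis=1) / 2.0

    def variant_maf(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    def variant_hwe_p(self) -> np.ndarray:
        hc = self._calls()
        out = np.empty(self.n_variants)
        for i in range(self.n_variants):
            row = hc[i]
            n_het = int(np.sum(row == 1))
            n_hom_ref = int(np.sum(row == 0))
            n_hom_alt = int(np.sum(row == 2))
            out[i] = hwe_exact_p(n_het, n_hom_ref, n_hom_alt)
        return out

    # per-sample statistics -------------------------------------------------
    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def sample_fhet(self) -> np.ndarray:
        """Heterozygosity-based inbreeding-style coefficient per sample:
        F = 1 - observed het / expected het, with the expectation
        2p(1-p) summed over the variants the sample is typed at."""
        hc = self._calls()
        p = self.alt_allele_freq()
        exp_het_v = 2.0 * p * (1.0 - p)
        present = hc != MISSING_CALL
        obs = np.sum((hc == 1) & present, axis=0).astype(float)
        exp = np.where(present, exp_het_v[:, None], 0.0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = 1.0 - obs / exp
        return np.where(exp > 0, f, 0.0)

    def subset(self, variant_idx=None, sample_idx=None) -> "GenotypeMatrix":
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in s],
            variants=self.variants.iloc[v].reset_index(drop=True),
            dosages=self.dosages[np.ix_(v, s)].copy(),
            hard_calls=None if self.hard_calls is None else self.hard_calls[np.ix_(v, s)].copy(),
            genotype_probs=None if self.genotype_probs is None
            else self.genotype_probs[np.ix_(v, s)].copy(),
        )


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Hardy-Weinberg equilibrium exact-test p-value (plain, not mid-p).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one, using
    the standard recurrence over the conditional distribution.
    Monomorphic variants return p = 1.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # probabilities over het counts with the parity of n_rare
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    h = mid
    while h >= 2:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        h -= 2
    h = mid
    while h <= n_rare - 2:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# QC filters


def qc_filter_variants(
    g: GenotypeMatrix,
    max_missing: float = 0.02,
    min_maf: float = 0.01,
    min_hwe_p: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants with missingness > max_missing, MAF < min_maf, or HWE
    exact p < min_hwe_p.  Returns the filtered matrix and a per-variant
    fate log (rsid, missingness, maf, hwe_p, kept, reason)."""
    miss = g.variant_missingness()
    maf = g.variant_maf()
    hwe = g.variant_hwe_p()
    reasons = []
    for i in range(g.n_variants):
        r = []
        if miss[i] > max_missing:
            r.append("missingness")
        if not (maf[i] >= min_maf):  # NaN MAF (all missing) also fails
            r.append("maf")
        if hwe[i] < min_hwe_p:
            r.append("hwe")
        reasons.append(",".join(r))
    fate = pd.DataFrame({
        "rsid": g.variants["rsid"],
        "missingness": miss,
        "maf": maf,
        "hwe_p": hwe,
        "kept": [r == "" for r in reasons],
        "reason": reasons,
    })
    keep = np.flatnonzero(fate["kept"].to_numpy())
    if keep.size == 0:
        warnings.warn("variant QC removed every variant", stacklevel=2)
    return g.subset(variant_idx=keep), fate


def qc_filter_samples(
    g: GenotypeMatrix,
    min_call_rate: float = 0.98,
    max_fhet: float = 0.2,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples with call rate < min_call_rate or |F_het| > max_fhet."""
    cr = g.sample_call_rate()
    fhet = g.sample_fhet()
    kept = (cr >= min_call_rate) & (np.abs(fhet) <= max_fhet)
    fate = pd.DataFrame({
        "sample": g.samples, "call_rate": cr, "fhet": fhet, "kept": kept,
    })
    keep = np.flatnonzero(kept)
    if keep.size < 2:
        warnings.warn("fewer than 2 samples survive sample QC", stacklevel=2)
    return g.subset(sample_idx=keep), fate


def filter_imputed(
    g: GenotypeMatrix,
    min_genotype_prob: float = 0.80,
    min_info: float = 0.1,
    min_maf: float = 0.005,
    per_variant: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Imputed-variant retention filter; directly genotyped variants are
    untouched.

    Hard calls whose maximum genotype probability is <= ``min_genotype_prob``
    are set to missing (per-genotype semantics; with ``per_variant=True``
    the mean probability is used to drop whole variants instead).  Imputed
    variants with INFO <= min_info or MAF <= min_maf are dropped.
    """
    typed = g.variants["typed"].to_numpy(dtype=bool)
    imputed = ~typed
    if imputed.any():
        if g.genotype_probs is None:
            raise ValueError("genotype probabilities required for imputed variants")
        if g.variants["info"].isna()[imputed].any():
            bad = g.variants.loc[imputed & g.variants["info"].isna().to_numpy(), "rsid"]
            raise ValueError(f"INFO score missing for imputed variants: {list(bad)}")
    dosages = g.dosages.copy()
    hard = None if g.hard_calls is None else g.hard_calls.copy()
    dropped_low_prob = np.zeros(g.n_variants, dtype=bool)
    if imputed.any():
        if per_variant:
            mean_prob = np.nanmean(np.where(np.isnan(g.dosages), np.nan, g.genotype_probs), axis=1)
            dropped_low_prob = imputed & (mean_prob <= min_genotype_prob)
        else:
            low = (g.genotype_probs <= min_genotype_prob) & imputed[:, None]
            dosages[low] = np.nan
            if hard is not None:
                hard[low] = MISSING_CALL
    work = replace(g, dosages=dosages, hard_calls=hard)
    maf = work.variant_maf()
    info = g.variants["info"].to_numpy(dtype=float)
    reasons = []
    for i in range(g.n_variants):
        r = []
        if imputed[i]:
            if dropped_low_prob[i]:
                r.append("genotype_prob")
            if info[i] <= min_info:
                r.append("info")
            if not (maf[i] > min_maf):
                r.append("maf")
        reasons.append(",".join(r))
    fate = pd.DataFrame({
        "rsid": g.variants["rsid"], "typed": typed, "info": info, "maf": maf,
        "kept": [r == "" for r in reasons], "reason": reasons,
    })
    keep = np.flatnonzero(fate["kept"].to_numpy())
    return work.subset(variant_idx=keep), fate


# ---------------------------------------------------------------------------
# PRS


def compute_prs(
    g: GenotypeMatrix,
    weights: Sequence[VariantWeight],
    min_match_frac: float = 0.5,
) -> tuple[pd.Series, dict]:
    """Weighted-allele PRS per sample, plus a variant-match report.

    Allele orientation per locus: the weight's effect allele may match the
    matrix alt allele (dosage used as-is) or the ref allele (dosage flipped
    via dosage(effect) = 2 - dosage(alt)).  Strand-ambiguous A/T and C/G
    loci are matched by allele identity with a warning.  Missing dosages are
    imputed as 2 x cohort effect-allele frequency at that locus.
    """
    rsid_to_idx = {r: i for i, r in enumerate(g.variants["rsid"])}
    ref = g.variants["ref"].to_numpy()
    alt = g.variants["alt"].to_numpy()
    scores = np.zeros(g.n_samples)
    n_matched = n_flipped = n_palindromic = 0
    dropped: list[str] = []
    mean_imputed_per_sample = np.zeros(g.n_samples, dtype=int)
    for w in weights:
        i = rsid_to_idx.get(w.rsid)
        if i is None:
            dropped.append(w.rsid)
            continue
        pair = {ref[i], alt[i]}
        if {w.effect_allele, w.other_allele} != pair:
            dropped.append(w.rsid)
            continue
        if w.palindromic:
            n_palindromic += 1
        if w.effect_allele == alt[i]:
            dose = g.dosages[i].copy()
        else:
            dose = 2.0 - g.dosages[i]
            n_flipped += 1
        missing = np.isnan(dose)
        if missing.any():
            eaf = np.nanmean(dose) / 2.0
            if np.isnan(eaf):
                dropped.append(w.rsid)
                continue
            dose[missing] = 2.0 * eaf
            mean_imputed_per_sample += missing.astype(int)
        scores += w.beta * dose
        n_matched += 1
    if n_palindromic:
        warnings.warn(
            f"{n_palindromic} strand-ambiguous (A/T or C/G) weight variants matched "
            "by allele identity; verify strand alignment upstream",
            stacklevel=2,
        )
    if weights and n_matched / len(weights) < min_match_frac:
        raise ValueError(
            f"only {n_matched}/{len(weights)} weight variants matched the genotype "
            "matrix; refusing to score (possible genome-build or naming mismatch)"
        )
    report = {
        "n_weights": len(weights),
        "n_matched": n_matched,
        "n_flipped": n_flipped,
        "n_palindromic": n_palindromic,
        "n_dropped": len(dropped),
        "dropped_rsids": dropped,
        "n_missing_imputed_per_sample": dict(zip(g.samples, mean_imputed_per_sample.tolist())),
    }
    return pd.Series(scores, index=pd.Index(g.samples, name="sample_id"), name="prs"), report


def quartile_bins(scores: pd.Series | np.ndarray) -> pd.DataFrame:
    """Assign PRS quartiles Q1 (lowest) .. Q4 plus top25/bottom25 flags.

    Cut points sit at the 25th/50th/75th percentiles; a score exactly at a
    cut point goes to the lower bin.  Degenerate (constant) scores all land
    in Q1 with a warning.
    """
    s = pd.Series(scores)
    if len(s) < 4:
        raise ValueError(f"need at least 4 samples to form quartiles, got {len(s)}")
    cuts = np.quantile(s.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    if cuts[0] == cuts[2]:
        warnings.warn("scores are constant across cut points; all samples in Q1",
                      stacklevel=2)
    q = 1 + np.sum(s.to_numpy(dtype=float)[:, None] > cuts[None, :], axis=1)
    out = pd.DataFrame({
        "prs": s.to_numpy(dtype=float),
        "quartile": [f"Q{i}" for i in q],
        "top25": q == 4,
        "bottom25": q == 1,
    }, index=s.index)
    return out


def write_scores(bins: pd.DataFrame, path) -> None:
    out = bins.reset_index().rename(columns={"index": "sample_id"})
    out[["sample_id", "prs", "quartile"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O: VCF (via cyvcf2) and a plain TSV dosage-matrix dialect


def read_vcf(path, info_key: str = "INFO", typed_flag: str = "TYPED") -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix.

    Dosages come from the DS FORMAT field when present, else from GT hard
    calls.  The imputation-quality score is read from the INFO column under
    ``info_key`` (commonly "INFO" or "R2"); a variant is considered directly
    genotyped when the flag ``typed_flag`` is present in its INFO column.
    Per-call maximum genotype probabilities are read from the GP field.
    """
    from cyvcf2 import VCF  # deferred: only needed on the VCF path

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dos, hard, probs = [], [], [], []
    any_gp = False
    for v in vcf:
        alt = v.ALT[0] if v.ALT else "."
        info_val = v.INFO.get(info_key)
        rows.append({
            "rsid": v.ID or f"{v.CHROM}:{v.POS}",
            "chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": alt,
            "typed": v.INFO.get(typed_flag) is not None,
            "info": float(info_val) if info_val is not None else np.nan,
        })
        gts = np.array([sum(a for a in g[:2] if a >= 0) if g[0] >= 0 else MISSING_CALL
                        for g in v.genotypes], dtype=np.int8)
        hard.append(gts)
        try:
            ds = v.format("DS")
        except Exception:
            ds = None
        if ds is not None:
            d = ds.astype(float).reshape(-1)
            d[np.isnan(d)] = np.nan
        else:
            d = np.where(gts == MISSING_CALL, np.nan, gts.astype(float))
        dos.append(d)
        try:
            gp = v.format("GP")
        except Exception:
            gp = None
        if gp is not None:
            any_gp = True
            probs.append(np.nanmax(gp.astype(float), axis=1))
        else:
            probs.append(np.full(len(samples), np.nan))
    variants = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "ref", "alt", "typed", "info"])
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosages=np.asarray(dos, dtype=float).reshape(len(rows), len(samples)),
        hard_calls=np.asarray(hard, dtype=np.int8).reshape(len(rows), len(samples)),
        genotype_probs=np.asarray(probs, dtype=float) if any_gp else None,
    )


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Plain dosage matrix: columns rsid, chrom, pos, ref, alt, typed, info,
    then one column per sample holding the alt-allele dosage (blank =
    missing)."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["rsid", "chrom", "pos", "ref", "alt", "typed", "info"]
    samples = [c for c in df.columns if c not in meta_cols]
    variants = df[meta_cols].copy()
    variants["typed"] = variants["typed"].astype(bool)
    dos = df[samples].to_numpy(dtype=float)
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dos)


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    dose_cols = pd.DataFrame(g.dosages, columns=g.samples)
    out = pd.concat([g.variants.reset_index(drop=True), dose_cols], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Emit a minimal uncompressed VCF (GT from hard calls, DS dosages)."""
    hc = g._calls()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_CALL: "./."}
        for i, v in g.variants.iterrows():
            info_parts = []
            if not (isinstance(v["info"], float) and math.isnan(v["info"])):
                info_parts.append(f"INFO={v['info']:g}")
            if v["typed"]:
                info_parts.append("TYPED")
            info_str = ";".join(info_parts) or "."
            calls = []
            for j in range(g.n_samples):
                d = g.dosages[i, j]
                ds = "." if math.isnan(d) else f"{d:g}"
                calls.append(f"{gt_map[int(hc[i, j])]}:{ds}")
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['rsid']}\t{v['ref']}\t{v['alt']}"
                     f"\t.\t.\t{info_str}\tGT:DS\t" + "\t".join(calls) + "\n")
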