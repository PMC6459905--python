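"""Sample and variant quality control for exome-array case-control data.

The cascade mirrors standard PLINK-era practice: sample-level filters
(missingness, sex discordance, heterozygosity outliers, relatedness by
method-of-moments IBD on a pruned SNP subset), then variant-level
filters (autosomes only, call rate, Hardy-Weinberg in controls,
differential case/control missingness). Every removal is recorded in an
ordered :class:`QCReport`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeStudy

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class QCStep:
    name: str
    threshold: str
    n_samples_removed: int
    n_variants_removed: int
    ids_removed: list


@dataclass
class QCReport:
    """Ordered record of a QC cascade with before/after dimensions."""

    steps: list[QCStep] = field(default_factory=list)
    dims_before: tuple[int, int] | None = None
    dims_after: tuple[int, int] | None = None

    def add(self, name, threshold, sample_ids=(), variant_ids=()):
        self.steps.append(
            QCStep(
                name,
                str(threshold),
                len(sample_ids),
                len(variant_ids),
                list(sample_ids) + list(variant_ids),
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "threshold": s.threshold,
                    "n_samples_removed": s.n_samples_removed,
                    "n_variants_removed": s.n_variants_removed,
                }
                for s in self.steps
            ]
        )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose conditional probability does not
    exceed that of the observed count (Wigginton-style exact test).
    Monomorphic tables give p = 1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # fold to the rarer allele
    if n_minor == 0:
        return 1.0

    # log-probability of each attainable heterozygote count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    lg = math.lgamma
    logp = np.array(
        [
            lg(n + 1)
            - lg((n_minor - h) // 2 + 1)
            - lg(h + 1)
            - lg(n - (n_minor + h) // 2 + 1)
            + h * math.log(2.0)
            for h in hets
        ]
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == min(n_het, n_minor)][0] if (n_het in hets) else None
    if obs is None:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_p_vector(genotypes: np.ndarray) -> np.ndarray:
    """Exact HWE p per variant column of a 0/1/2/-1 matrix."""
    out = np.ones(genotypes.shape[1])
    for j in range(genotypes.shape[1]):
        g = genotypes[:, j]
        g = g[g >= 0]
        if g.size == 0:
            continue
        out[j] = hwe_exact_p(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
    return out


# ---------------------------------------------------------------------------
# Relatedness (method-of-moments IBD)
# ---------------------------------------------------------------------------

def ibd_pihat(g_a: np.ndarray, g_b: np.ndarray, allele_freqs: np.ndarray,
              min_overlap: int = 100) -> float:
    """Method-of-moments pi-hat for one sample pair.

    pi-hat = P(IBD=2) + P(IBD=1)/2, with the IBD-state probabilities
    solved from observed identity-by-state counts against their
    expectations under the given allele frequencies. Components are
    clamped to [0,1]. Returns NaN (flagged unreliable) when fewer than
    ``min_overlap`` SNPs are jointly non-missing.
    """
    ok = (g_a >= 0) & (g_b >= 0)
    if int(ok.sum()) < min_overlap:
        return float("nan")
    a, b, p = g_a[ok].astype(int), g_b[ok].astype(int), allele_freqs[ok]
    ibs = 2 - np.abs(a - b)
    n0 = int((ibs == 0).sum())
    n1 = int((ibs == 1).sum())
    n2 = int((ibs == 2).sum())
    q = 1.0 - p
    e00 = float(np.sum(2 * p**2 * q**2))
    e10 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e20 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e11 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e21 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))
    m = len(a)
    z0 = n0 / e00 if e00 > 0 else 0.0
    z1 = (n1 - z0 * e10) / e11 if e11 > 0 else 0.0
    z2 = (n2 - z0 * e20 - z1 * e21) / m
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    if z.sum() <= 0:
        return 0.0
    z = z / z.sum()
    return float(z[2] + 0.5 * z[1])


def pihat_matrix(genotypes: np.ndarray, allele_freqs: np.ndarray,
                 min_overlap: int = 100) -> np.ndarray:
    """Pairwise pi-hat for all samples (vectorized over SNPs)."""
    n = genotypes.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = ibd_pihat(
                genotypes[i], genotypes[j], allele_freqs, min_overlap
            )
    return out


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(study: GenotypeStudy, maf_min: float = 0.05,
             call_rate_min: float = 0.99, r2_max: float = 0.05,
             hwe_p_min: float = 1e-3,
             high_ld_regions: pd.DataFrame | None = None,
             window: int = 50, step: int = 5) -> np.ndarray:
    """Select an independent high-quality SNP subset.

    Marginal filters: non-AT/CG alleles, autosomal, outside supplied
    high-LD regions, MAF > ``maf_min``, call rate > ``call_rate_min``,
    HWE p > ``hwe_p_min``. Then greedy windowed pruning (window of
    ``window`` variants, step ``step``, ascending position) removes one
    of every pair with genotype r-squared >= ``r2_max``.

    Returns the integer indices of retained variants.
    """
    v = study.variants
    keep = np.ones(study.n_variants, dtype=bool)
    a1 = v["a1"].astype(str).str.upper() if "a1" in v else pd.Series(["A"] * len(v))
    a2 = v["a2"].astype(str).str.upper() if "a2" in v else pd.Series(["G"] * len(v))
    ambiguous = [
        (x, y) in AMBIGUOUS_PAIRS for x, y in zip(a1, a2)
    ]
    keep &= ~np.asarray(ambiguous)
    chrom = pd.to_numeric(v["chrom"], errors="coerce")
    keep &= ((chrom >= 1) & (chrom <= 22)).to_numpy()
    if high_ld_regions is not None and len(high_ld_regions):
        for _, row in high_ld_regions.iterrows():
            inside = (
                (chrom == row["chrom"])
                & (v["pos"] >= row["start"])
                & (v["pos"] <= row["end"])
            )
            keep &= ~inside.to_numpy()
    keep &= study.maf() > maf_min
    keep &= study.variant_call_rate() > call_rate_min
    cand = np.flatnonzero(keep)
    if cand.size == 0:
        logger.warning("ld_prune: no variants pass marginal filters")
        return cand
    hwe = hwe_p_vector(study.genotypes[:, cand])
    cand = cand[hwe > hwe_p_min]
    if cand.size == 0:
        logger.warning("ld_prune: no variants pass HWE filter")
        return cand

    # greedy windowed pruning, per chromosome, ascending position
    order = np.lexsort(
        (v["pos"].to_numpy()[cand], chrom.to_numpy()[cand])
    )
    cand = cand[order]
    g = study.genotypes[:, cand].astype(float)
    g[g < 0] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    g -= g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    g /= sd

    alive = np.ones(cand.size, dtype=bool)
    n = g.shape[0]
    start = 0
    while start < cand.size:
        idx = np.flatnonzero(alive[start : start + window]) + start
        if idx.size > 1:
            sub = g[:, idx]
            corr = (sub.T @ sub) / n
            r2 = corr**2
            for ii in range(len(idx)):
                if not alive[idx[ii]]:
                    continue
                for jj in range(ii + 1, len(idx)):
                    if alive[idx[jj]] and r2[ii, jj] >= r2_max:
                        alive[idx[jj]] = False
        start += step
    return np.sort(cand[alive])


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

def heterozygosity_rate(genotypes: np.ndarray) -> np.ndarray:
    """Per-sample fraction of heterozygous calls among non-missing calls."""
    called = genotypes >= 0
    het = genotypes == 1
    denom = called.sum(axis=1)
    return np.where(denom > 0, het.sum(axis=1) / np.maximum(denom, 1), np.nan)


def sample_qc(study: GenotypeStudy, missing_rate_max: float = 0.05,
              het_sd: float = 4.0, pihat_max: float = 0.2,
              pruned_variants: np.ndarray | None = None,
              genotypic_sex: pd.Series | None = None,
              min_overlap: int = 100) -> tuple[GenotypeStudy, QCReport]:
    """Sample-level QC cascade.

    Steps, in order: (1) missing call rate > ``missing_rate_max``;
    (2) sex discordance (reported vs genotypic sex, skipped with a
    warning if genotypic sex is not supplied); (3) heterozygosity-rate
    outliers beyond ``het_sd`` SDs of the mean, computed on the pruned
    subset; (4) one member of each pair with pi-hat > ``pihat_max`` —
    the member with the higher missing rate (ties by sample-id order).
    """
    report = QCReport(dims_before=(study.n_samples, study.n_variants))
    if pruned_variants is None:
        pruned_variants = ld_prune(study)
    if len(pruned_variants) == 0:
        raise ValueError(
            "pruned SNP subset is empty; relax ld_prune thresholds"
        )

    # 1. missingness
    miss = study.sample_missing_rate()
    drop = miss > missing_rate_max
    ids = study.samples.loc[drop, "sample_id"].tolist()
    report.add("sample_missingness", f">{missing_rate_max}", sample_ids=ids)
    study = study.take_samples(~drop)
    if genotypic_sex is not None:
        genotypic_sex = genotypic_sex.loc[~drop].reset_index(drop=True)

    # 2. sex discordance
    if genotypic_sex is not None:
        disc = (
            (study.samples["sex"].to_numpy() != genotypic_sex.to_numpy())
            & (study.samples["sex"].to_numpy() != 0)
            & (genotypic_sex.to_numpy() != 0)
        )
        ids = study.samples.loc[disc, "sample_id"].tolist()
        report.add("sex_discordance", "reported != genotypic", sample_ids=ids)
        study = study.take_samples(~disc)
    else:
        logger.warning("sample_qc: no genotypic sex supplied; step skipped")
        report.add("sex_discordance", "skipped (no genotypic sex)", sample_ids=[])

    gp = study.genotypes[:, pruned_variants]

    # 3. heterozygosity outliers
    het = heterozygosity_rate(gp)
    mu, sd = np.nanmean(het), np.nanstd(het)
    out = np.abs(het - mu) > het_sd * sd if sd > 0 else np.zeros(len(het), bool)
    ids = study.samples.loc[out, "sample_id"].tolist()
    report.add("heterozygosity", f">{het_sd} SD", sample_ids=ids)
    study = study.take_samples(~out)
    gp = gp[~out]

    # 4. relatedness
    freqs = np.where(gp >= 0, gp, 0).sum(axis=0) / np.maximum(
        2 * (gp >= 0).sum(axis=0), 1
    )
    pm = pihat_matrix(gp, freqs, min_overlap)
    miss_now = study.sample_missing_rate()
    to_drop: set[int] = set()
    pairs = np.argwhere(np.triu(pm > pihat_max, k=1))
    # resolve greedily, highest pi-hat first
    for i, j in sorted(pairs, key=lambda ij: -pm[ij[0], ij[1]]):
        if i in to_drop or j in to_drop:
            continue
        if miss_now[i] > miss_now[j]:
            to_drop.add(int(i))
        elif miss_now[j] > miss_now[i]:
            to_drop.add(int(j))
        else:
            sid_i = study.samples["sample_id"].iloc[i]
            sid_j = study.samples["sample_id"].iloc[j]
            to_drop.add(int(i) if sid_i > sid_j else int(j))
    drop_mask = np.zeros(study.n_samples, dtype=bool)
    drop_mask[list(to_drop)] = True
    ids = study.samples.loc[drop_mask, "sample_id"].tolist()
    report.add("relatedness", f"pi-hat>{pihat_max}", sample_ids=ids)
    study = study.take_samples(~drop_mask)

    report.dims_after = (study.n_samples, study.n_variants)
    return study, report


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def variant_qc(study: GenotypeStudy, call_rate_min: float = 0.98,
               hwe_controls_p_min: float = 1e-6,
               diff_missing_p_min: float = 5e-3) -> tuple[GenotypeStudy, QCReport]:
    """Variant-level QC cascade.

    Removals in order: non-autosomal variants (which also covers
    haploid-heterozygous calls in an autosome-only pipeline); call rate
    < ``call_rate_min``; Hardy-Weinberg deviation in controls
    (p < ``hwe_controls_p_min``); differential case/control missingness
    (Fisher exact p < ``diff_missing_p_min`` on the 2x2
    missing/observed x case/control table).
    """
    report = QCReport(dims_before=(study.n_samples, study.n_variants))

    chrom = pd.to_numeric(study.variants["chrom"], errors="coerce")
    drop = ~((chrom >= 1) & (chrom <= 22)).to_numpy()
    report.add("non_autosomal", "chrom not in 1..22",
               variant_ids=study.variants.loc[drop, "variant_id"].tolist())
    study = study.take_variants(~drop)

    drop = study.variant_call_rate() < call_rate_min
    report.add("call_rate", f"<{call_rate_min}",
               variant_ids=study.variants.loc[drop, "variant_id"].tolist())
    study = study.take_variants(~drop)

    controls = study.is_control
    if controls.sum() == 0:
        logger.warning("variant_qc: no controls; HWE-in-controls step skipped")
        report.add("hwe_controls", "skipped (no controls)", variant_ids=[])
    else:
        hwe = hwe_p_vector(study.genotypes[controls])
        drop = hwe < hwe_controls_p_min
        report.add("hwe_controls", f"p<{hwe_controls_p_min}",
                   variant_ids=study.variants.loc[drop, "variant_id"].tolist())
        study = study.take_variants(~drop)

    cases = study.is_case
    controls = study.is_control
    if cases.sum() and controls.sum():
        miss = study.genotypes < 0
        p = np.ones(study.n_variants)
        mc = miss[cases].sum(axis=0)
        mk = miss[controls].sum(axis=0)
        nc, nk = int(cases.sum()), int(controls.sum())
        for j in np.flatnonzero((mc + mk) > 0):
            _, p[j] = stats.fisher_exact(
                [[mc[j], nc - mc[j]], [mk[j], nk - mk[j]]]
            )
        drop = p < diff_missing_p_min
        report.add("differential_missingness", f"p<{diff_missing_p_min}",
                   variant_ids=study.variants.loc[drop, "variant_id"].tolist())
        study = study.take_variants(~drop)
    else:
        report.add("differential_missingness", "skipped (one group empty)",
                   variant_ids=[])

    report.dims_after = (study.n_samples, study.n_variants)
    return study, report


def nonmonomorphic_filter(study: GenotypeStudy,
                          per_group: bool = False) -> np.ndarray:
    """Indices of variants polymorphic in the analyzed sample.

    Default: minor-allele count >= 1 in the pooled case+control sample.
    ``per_group=True`` applies the stricter reading requiring
    polymorphism within cases and within controls separately.
    """
    if per_group:
        mac_ca, _ = study.allele_counts(study.is_case)
        mac_co, _ = study.allele_counts(study.is_control)
        keep = (mac_ca >= 1) & (mac_co >= 1)
    else:
        mac, _ = study.allele_counts()
        keep = mac >= 1
    return np.flatnonzero(keep)
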