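"""Synthetic exome-array case-control study generator.

Emulates the statistical structure of an exome-chip study of a
late-onset disease: a mostly-rare variant spectrum in which the majority
of assayed sites are monomorphic in the sample, gene-structured
functional annotations, consensus deleteriousness scores in [0,1] with
neutral/deleterious labels, reference-panel allele frequencies that are
noisy versions of the generating frequencies, multi-country cohorts with
configurable case:control ratios, and configurable per-gene
causal/protective effect architectures.

Sampling is retrospective: a population is simulated forward from a
logistic disease model on causal-variant dosages plus covariate offsets,
and the requested numbers of cases and controls are then drawn from it
per country. This ascertainment is what induces the set-unique count
imbalance between unequal groups that the ISUB control analysis probes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import GenotypeStudy, MISSING

SPECTRUM_CLASSES = ("monomorphic", "singleton", "rare", "low_frequency", "common")
FUNCTIONAL_CLASSES = ("synonymous", "missense", "LoF")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic exome-array study.

    Defaults describe a full-scale study of 4,244 cases and 3,106
    controls from 6 countries on an array of ~233k sites of which ~43%
    are polymorphic; tests and examples pass scaled-down values.
    """

    n_cases: int = 4244
    n_controls: int = 3106
    n_countries: int = 6
    #: case:control ratio per country; None = the overall ratio everywhere
    case_control_ratio_per_country: list[float] | None = None
    n_genes: int = 14488
    #: mean of the (shifted-Poisson) variants-per-gene distribution
    variants_per_gene: float = 16.1
    #: mixture weights over the site-frequency classes, in the order
    #: (monomorphic, singleton, rare MAF<0.005, low-frequency 0.005-0.05,
    #: common >0.05); chosen so ~57% of sites are monomorphic as on a
    #: typical exome chip
    maf_spectrum: tuple[float, ...] = (0.57, 0.13, 0.17, 0.08, 0.05)
    #: probabilities over (synonymous, missense, LoF)
    functional_class_probs: tuple[float, ...] = (0.30, 0.65, 0.05)
    #: Beta(a, b) shape of the deleteriousness score + label threshold
    deleterious_score_params: tuple[float, float, float] = (2.0, 2.0, 0.5)
    #: probability a LoF variant carries no score (only LoF may be unscored)
    score_missing_prob: float = 0.10
    #: sd of logit-scale noise linking sample-generating MAF to reference MAF
    reference_maf_noise: float = 0.30
    #: cohort size at which the singleton class has expected MAC 1; the
    #: array content is fixed, so a scaled-down sample of the same sites
    #: sees proportionally lower allele counts
    singleton_reference_n: int = 7350
    causal_fraction: float = 0.0
    protective_fraction: float = 0.0
    #: |beta| = effect_size_c * |log10 MAF| for causal variants
    effect_size_c: float = 0.4
    #: (sex log-odds offset, per-country log-odds offsets or scalar)
    sex_effect: float = 0.0
    country_effects: tuple[float, ...] | float = 0.0
    missing_genotype_rate: float = 0.002
    #: optional (case_rate, control_rate) overriding the flat rate
    missing_rate_by_phenotype: tuple[float, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.n_genes < 1 or self.variants_per_gene < 1:
            raise ValueError("need at least one gene with one variant")
        for name, probs in (
            ("maf_spectrum", self.maf_spectrum),
            ("functional_class_probs", self.functional_class_probs),
        ):
            p = np.asarray(probs, dtype=float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be probabilities summing to 1")
        for name, v in (
            ("causal_fraction", self.causal_fraction),
            ("protective_fraction", self.protective_fraction),
            ("score_missing_prob", self.score_missing_prob),
            ("missing_genotype_rate", self.missing_genotype_rate),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.case_control_ratio_per_country is not None and len(
            self.case_control_ratio_per_country
        ) != self.n_countries:
            raise ValueError("one case:control ratio per country required")

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_site_frequencies(cfg: SimulationConfig, n_sites: int,
                           rng: np.random.Generator,
                           n_total_alleles: int) -> np.ndarray:
    """Generating minor-allele frequency per site from the spectrum mixture."""
    cls = rng.choice(len(SPECTRUM_CLASSES), size=n_sites, p=cfg.maf_spectrum)
    maf = np.zeros(n_sites)
    # singleton class: expected minor-allele count ~1 at the reference
    # cohort scale (so smaller simulated samples see mostly MAC 0-1)
    maf[cls == 1] = 1.0 / (2 * cfg.singleton_reference_n)
    n_rare = int((cls == 2).sum())
    maf[cls == 2] = 10 ** rng.uniform(np.log10(5e-4), np.log10(5e-3), n_rare)
    n_low = int((cls == 3).sum())
    maf[cls == 3] = 10 ** rng.uniform(np.log10(5e-3), np.log10(5e-2), n_low)
    n_common = int((cls == 4).sum())
    maf[cls == 4] = rng.uniform(0.05, 0.5, n_common)
    return maf


def _build_variant_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_gene = 1 + rng.poisson(cfg.variants_per_gene - 1.0, size=cfg.n_genes)
    n_sites = int(per_gene.sum())
    gene_ids = np.repeat(
        [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)], per_gene
    )
    chroms = np.repeat(
        1 + (np.arange(cfg.n_genes) % 22), per_gene
    )
    pos = np.zeros(n_sites, dtype=np.int64)
    # genes laid consecutively; variants spaced 100bp-10kb apart
    offset_within = rng.integers(100, 10_000, size=n_sites).cumsum()
    pos = 1_000_000 + offset_within

    maf = _draw_site_frequencies(
        cfg, n_sites, rng, 2 * (cfg.n_cases + cfg.n_controls)
    )
    fclass = rng.choice(
        FUNCTIONAL_CLASSES, size=n_sites, p=cfg.functional_class_probs
    )
    a, b, thr = cfg.deleterious_score_params
    score = rng.beta(a, b, size=n_sites)
    unscored = (fclass == "LoF") & (rng.random(n_sites) < cfg.score_missing_prob)
    score[unscored] = np.nan
    label = np.where(score >= thr, "deleterious", "neutral").astype(object)
    label[unscored] = None
    label[np.isnan(score) & ~unscored] = None

    # reference MAF: generating MAF perturbed on the logit scale
    with np.errstate(divide="ignore"):
        logit = np.log(np.maximum(maf, 1e-8) / (1 - np.maximum(maf, 1e-8)))
    ref = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0, cfg.reference_maf_noise, n_sites))))
    ref[maf == 0] = 0.0

    alleles = rng.choice(["A", "C", "G", "T"], size=(n_sites, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")

    return pd.DataFrame(
        {
            "variant_id": [f"var{i + 1}" for i in range(n_sites)],
            "chrom": chroms,
            "pos": pos,
            "a1": alleles[:, 0],
            "a2": alleles[:, 1],
            "gene": gene_ids,
            "functional_class": fclass,
            "score": score,
            "label": label,
            "ref_maf": ref,
            "gen_maf": maf,
        }
    )


def simulate_gene_effects(cfg: SimulationConfig, variant_table: pd.DataFrame,
                          gene_id: str, rng: np.random.Generator) -> np.ndarray:
    """Per-variant log-odds effects for one gene.

    Exactly ``round(causal_fraction * n_variants)`` variants (preferring
    polymorphic rare sites, MAF < 0.01) receive nonzero coefficients; of
    these, ``round(protective_fraction * n_causal)`` are risk-decreasing.
    Magnitudes follow |beta| = c * |log10 MAF|.
    """
    mask = variant_table["gene"].to_numpy() == gene_id
    if not mask.any():
        raise ValueError(f"unknown gene {gene_id!r}")
    maf = variant_table.loc[mask, "gen_maf"].to_numpy()
    m = int(mask.sum())
    beta = np.zeros(m)
    n_causal = int(round(cfg.causal_fraction * m))
    if n_causal == 0:
        return beta
    eligible = np.flatnonzero((maf > 0) & (maf < 0.01))
    if len(eligible) < n_causal:
        extra = np.flatnonzero(maf > 0)
        extra = np.setdiff1d(extra, eligible)
        eligible = np.concatenate([eligible, extra])
    n_causal = min(n_causal, len(eligible))
    idx = rng.choice(eligible, size=n_causal, replace=False)
    mags = cfg.effect_size_c * np.abs(np.log10(maf[idx]))
    n_prot = int(round(cfg.protective_fraction * n_causal))
    signs = np.ones(n_causal)
    if n_prot:
        signs[rng.choice(n_causal, size=n_prot, replace=False)] = -1.0
    beta[idx] = signs * mags
    return beta


def _country_targets(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cases/controls to draw per country, honoring per-country ratios."""
    k = cfg.n_countries
    cases = np.full(k, cfg.n_cases // k)
    cases[: cfg.n_cases % k] += 1
    if cfg.case_control_ratio_per_country is None:
        controls = np.full(k, cfg.n_controls // k)
        controls[: cfg.n_controls % k] += 1
    else:
        ratios = np.asarray(cfg.case_control_ratio_per_country, dtype=float)
        raw = cases / ratios
        controls = np.floor(raw * cfg.n_controls / raw.sum()).astype(int)
        deficit = cfg.n_controls - controls.sum()
        controls[np.argsort(-(raw * cfg.n_controls / raw.sum() - controls))[:deficit]] += 1
    return cases, controls


def simulate_study(cfg: SimulationConfig) -> GenotypeStudy:
    """Generate a full :class:`~exoburden.io.GenotypeStudy`.

    Deterministic given ``cfg.seed``; identical configs yield
    byte-identical studies.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    variants = _build_variant_table(cfg, rng)
    n_sites = len(variants)
    maf = variants["gen_maf"].to_numpy()

    # per-gene causal architecture
    beta = np.zeros(n_sites)
    if cfg.causal_fraction > 0:
        for gene_id, grp in variants.groupby("gene", sort=False):
            beta[grp.index] = simulate_gene_effects(cfg, variants, gene_id, rng)
    causal_idx = np.flatnonzero(beta != 0.0)

    cases_per, controls_per = _country_targets(cfg)
    country_names = [f"C{j + 1}" for j in range(cfg.n_countries)]
    ceff = cfg.country_effects
    country_offsets = (
        np.full(cfg.n_countries, float(ceff))
        if np.isscalar(ceff)
        else np.asarray(ceff, dtype=float)
    )

    geno_blocks, sample_rows = [], []
    sid = 0
    for j in range(cfg.n_countries):
        need_cases, need_controls = int(cases_per[j]), int(controls_per[j])
        got_cases = got_controls = 0
        g_keep = []
        rows = []
        poly = np.flatnonzero(maf > 0)
        # ultra-rare sites: draw the site's allele count, then place the
        # alleles on random chromosome slots — distribution-identical to
        # per-individual Binomial(2, maf) draws but far cheaper
        batch0 = max(256, 2 * (need_cases + need_controls))
        sparse = poly[2 * batch0 * maf[poly] < 30]
        dense = np.setdiff1d(poly, sparse)
        while got_cases < need_cases or got_controls < need_controls:
            remaining = need_cases - got_cases + need_controls - got_controls
            batch = max(256, remaining + remaining // 3 + 64)
            g = np.zeros((batch, n_sites), dtype=np.int8)
            if dense.size:
                g[:, dense] = rng.binomial(2, maf[dense], size=(batch, dense.size))
            if sparse.size:
                counts = rng.binomial(2 * batch, maf[sparse])
                cols = np.repeat(sparse, counts)
                if cols.size:
                    slots = rng.integers(0, 2 * batch, size=cols.size)
                    # alleles occupy distinct chromosome slots within a
                    # site; collisions are rare — redraw until none
                    for _ in range(64):
                        key = cols.astype(np.int64) * (2 * batch) + slots
                        order = np.argsort(key, kind="stable")
                        dup = np.zeros(cols.size, dtype=bool)
                        dup[order[1:]] = key[order[1:]] == key[order[:-1]]
                        if not dup.any():
                            break
                        slots[dup] = rng.integers(0, 2 * batch, size=int(dup.sum()))
                    np.add.at(g, (slots // 2, cols), 1)
            sex = rng.integers(1, 3, size=batch)  # 1 male, 2 female
            eta = country_offsets[j] + cfg.sex_effect * (sex == 1)
            if causal_idx.size:
                eta = eta + g[:, causal_idx].astype(float) @ beta[causal_idx]
            p_case = 1.0 / (1.0 + np.exp(-eta))
            is_case = rng.random(batch) < p_case
            take_ca = np.flatnonzero(is_case)[: need_cases - got_cases]
            take_co = np.flatnonzero(~is_case)[: need_controls - got_controls]
            got_cases += take_ca.size
            got_controls += take_co.size
            for pheno, take in ((1, take_ca), (0, take_co)):
                if take.size:
                    g_keep.append(g[take])
                    rows.extend(
                        (pheno, int(sx), country_names[j]) for sx in sex[take]
                    )
        geno_blocks.append(np.vstack(g_keep))
        sample_rows.extend(rows)
        sid += len(rows)

    genotypes = np.vstack(geno_blocks)
    n = genotypes.shape[0]
    samples = pd.DataFrame(sample_rows, columns=["phenotype", "sex", "country"])
    samples.insert(0, "sample_id", [f"S{i + 1:06d}" for i in range(n)])

    # missingness, optionally phenotype-dependent
    if cfg.missing_rate_by_phenotype is not None:
        rc, rk = cfg.missing_rate_by_phenotype
        rate = np.where(samples["phenotype"].to_numpy() == 1, rc, rk)[:, None]
    else:
        rate = cfg.missing_genotype_rate
    if np.any(np.asarray(rate) > 0):
        mask = rng.random(genotypes.shape) < rate
        genotypes[mask] = MISSING

    # orient to the minor allele as observed in the drawn sample
    observed = genotypes >= 0
    ac = np.where(observed, genotypes, 0).sum(axis=0)
    tot = 2 * observed.sum(axis=0)
    flip = ac > tot - ac
    if flip.any():
        cols = genotypes[:, flip]
        cols[cols >= 0] = 2 - cols[cols >= 0]
        genotypes[:, flip] = cols
        a1 = variants.loc[flip, "a1"].copy()
        variants.loc[flip, "a1"] = variants.loc[flip, "a2"].to_numpy()
        variants.loc[flip, "a2"] = a1.to_numpy()
        variants.loc[flip, "ref_maf"] = 1.0 - variants.loc[flip, "ref_maf"]

    variants = variants.copy()
    variants["true_beta"] = beta
    variants["annotated"] = True
    return GenotypeStudy(genotypes, samples, variants)


def write_study(study: GenotypeStudy, prefix) -> None:
    """Write PLINK bed/bim/fam plus annotation and covariate TSVs."""
    from . import io as _io
    from pathlib import Path

    _io.write_plink(study, prefix)
    prefix = Path(prefix)
    ann_cols = ["variant_id", "gene", "functional_class", "score", "label", "ref_maf"]
    study.variants[[c for c in ann_cols if c in study.variants.columns]].to_csv(
        prefix.with_suffix(".annot.tsv"), sep="\t", index=False
    )
    study.samples.to_csv(prefix.with_suffix(".covar.tsv"), sep="\t", index=False)
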