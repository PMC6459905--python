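"""Individual set-unique burden (ISUB) analysis.

A variant is *set-unique* when it is carried by at least one member of
one phenotype group and by no member of the other. Each individual's
ISUB score is the sum of deleteriousness scores over the set-unique
variants they carry, counted once per variant under a dominant model.
Two variant classes are scored: NS (all set-unique missense +
loss-of-function variants) and DEL (the NS members labeled
deleterious). Because larger groups reveal more group-unique variants,
an unequal case:control ratio inflates the larger group's scores under
the null — the artifact the balanced-cohort control analysis removes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import fit_logistic
from .io import GenotypeStudy
from .assoc import build_covariate_matrix

logger = logging.getLogger(__name__)

DEFAULT_ISUB_COVARIATES = ["PC1", "PC2", "PC3", "PC4", "PC5", "country"]
NS_CLASSES = ("missense", "LoF")


@dataclass
class ClassSet:
    """Variant indices of one scored class together with their scores."""

    variant_idx: np.ndarray
    scores: np.ndarray
    case_unique: np.ndarray  # bool per entry; False = control-unique


@dataclass
class ISUBResult:
    variant_class: str
    scores: np.ndarray                  # per-individual S_i
    counts: np.ndarray                  # per-individual set-unique variant count
    group_summary: pd.DataFrame
    comparison_p: float
    count_comparison_p: float = np.nan
    per_variant_score_comparison_p: float = np.nan
    outlier_removed_p: float = np.nan
    log_transformed_p: float = np.nan
    cohorts: tuple = ()
    n_cases: int = 0
    n_controls: int = 0


def set_unique_variants(study: GenotypeStudy) -> tuple[np.ndarray, np.ndarray]:
    """Indices of case-unique and control-unique variants.

    Case-unique: minor-allele count > 0 among cases and 0 among
    controls; symmetrically for control-unique. The two sets are
    disjoint by construction.
    """
    if (study.phenotype >= 0).sum() == 0:
        raise ValueError("no phenotyped samples")
    mac_case, _ = study.allele_counts(study.is_case)
    mac_ctrl, _ = study.allele_counts(study.is_control)
    case_unique = np.flatnonzero((mac_case > 0) & (mac_ctrl == 0))
    ctrl_unique = np.flatnonzero((mac_ctrl > 0) & (mac_case == 0))
    return case_unique, ctrl_unique


def filter_reference_maf(variant_idx: np.ndarray, variants: pd.DataFrame,
                         maf_max: float = 0.005) -> np.ndarray:
    """Drop variants whose reference-panel MAF exceeds ``maf_max``.

    Variants with no reference frequency are retained (absence from the
    reference panel implies rarity) and logged.
    """
    idx = np.asarray(variant_idx, int)
    if "ref_maf" not in variants.columns:
        return idx
    ref = variants["ref_maf"].to_numpy(float)[idx]
    missing = ~np.isfinite(ref)
    if missing.any():
        logger.info("filter_reference_maf: %d variants lack a reference MAF; retained",
                    int(missing.sum()))
    return idx[missing | (ref <= maf_max)]


def build_class_sets(study: GenotypeStudy, case_unique: np.ndarray,
                     ctrl_unique: np.ndarray,
                     pooled_max_for_unscored: bool = False
                     ) -> tuple[ClassSet, ClassSet]:
    """Assemble the NS and DEL variant classes with their scores.

    NS = set-unique missense + LoF variants; DEL = NS members labeled
    deleterious. Loss-of-function variants lacking a score are assigned
    the deleterious label and the maximum score observed in their own
    set-unique group (case-unique max for case-unique variants, and
    symmetrically) — or the pooled maximum with
    ``pooled_max_for_unscored=True``. Variants with a missing functional
    class are excluded with a warning.
    """
    v = study.variants
    fclass = v["functional_class"].astype(object).to_numpy()
    score = v["score"].to_numpy(float) if "score" in v else np.full(len(v), np.nan)
    label = (
        v["label"].astype(object).to_numpy()
        if "label" in v
        else np.array([None] * len(v), dtype=object)
    )

    idx = np.concatenate([case_unique, ctrl_unique]).astype(int)
    is_case_u = np.concatenate(
        [np.ones(len(case_unique), bool), np.zeros(len(ctrl_unique), bool)]
    )
    missing_class = pd.isna(pd.Series(fclass[idx])).to_numpy()
    if missing_class.any():
        logger.warning("build_class_sets: %d variants lack a functional class; excluded",
                       int(missing_class.sum()))
        idx, is_case_u = idx[~missing_class], is_case_u[~missing_class]

    ns_mask = np.isin(fclass[idx], NS_CLASSES)
    ns_idx, ns_case_u = idx[ns_mask], is_case_u[ns_mask]
    ns_scores = score[ns_idx].copy()
    ns_labels = label[ns_idx].copy()

    # unscored-LoF rule: deleterious label + max score of its own dataset
    unscored_lof = (fclass[ns_idx] == "LoF") & ~np.isfinite(ns_scores)
    if unscored_lof.any():
        scored = np.isfinite(ns_scores)
        if pooled_max_for_unscored:
            pool_max = ns_scores[scored].max() if scored.any() else 0.0
            ns_scores[unscored_lof] = pool_max
        else:
            for grp in (True, False):
                sel = unscored_lof & (ns_case_u == grp)
                if not sel.any():
                    continue
                grp_scored = scored & (ns_case_u == grp)
                grp_max = ns_scores[grp_scored].max() if grp_scored.any() else 0.0
                ns_scores[sel] = grp_max
        ns_labels[unscored_lof] = "deleterious"

    # drop NS members that still lack any score (non-LoF unscored)
    has_score = np.isfinite(ns_scores)
    if not has_score.all():
        logger.warning("build_class_sets: %d unscored non-LoF variants dropped from NS",
                       int((~has_score).sum()))
    ns = ClassSet(ns_idx[has_score], ns_scores[has_score], ns_case_u[has_score])
    ns_labels = ns_labels[has_score]

    del_mask = ns_labels == "deleterious"
    del_set = ClassSet(ns.variant_idx[del_mask], ns.scores[del_mask],
                       ns.case_unique[del_mask])
    return ns, del_set


def isub_scores(study: GenotypeStudy, class_set: ClassSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual ISUB score and set-unique variant count.

    Dominant model: a carried variant (genotype 1 or 2) contributes its
    score exactly once; homozygotes are not double-counted.
    """
    if class_set.variant_idx.size == 0:
        n = study.n_samples
        return np.zeros(n), np.zeros(n, dtype=int)
    g = study.genotypes[:, class_set.variant_idx]
    carried = g > 0
    scores = carried @ class_set.scores
    counts = carried.sum(axis=1)
    return scores, counts


def compare_isub(scores: np.ndarray, study: GenotypeStudy,
                 covariates: list[str] | None = None) -> float:
    """Logistic-regression p-value for a case-control ISUB difference.

    Regresses phenotype on the per-individual score plus covariates and
    returns the Wald p of the score coefficient; NaN when the scores
    have no variance.
    """
    use = study.phenotype >= 0
    y = study.phenotype[use].astype(float)
    s = np.asarray(scores, float)[use]
    if s.std() == 0:
        logger.warning("compare_isub: zero score variance; p undefined")
        return np.nan
    C = build_covariate_matrix(study.samples.loc[use].reset_index(drop=True), covariates)
    X = np.hstack([np.ones((len(y), 1)), s[:, None], C])
    fit = fit_logistic(X, y)
    return fit.wald_p(1)


def count_and_score_diagnostics(study: GenotypeStudy, class_set: ClassSet,
                                counts: np.ndarray) -> tuple[float, float]:
    """Disentangle the two mechanisms behind an ISUB difference.

    Returns two-sided Wilcoxon rank-sum p-values for (a) per-individual
    set-unique variant counts between cases and controls and (b)
    per-variant deleteriousness scores between the case-unique and
    control-unique variant sets.
    """
    if class_set.variant_idx.size == 0:
        logger.warning("count_and_score_diagnostics: empty class set; skipped")
        return np.nan, np.nan
    cases, ctrls = study.is_case, study.is_control
    count_p = stats.mannwhitneyu(
        counts[cases], counts[ctrls], alternative="two-sided"
    ).pvalue
    s_case = class_set.scores[class_set.case_unique]
    s_ctrl = class_set.scores[~class_set.case_unique]
    if s_case.size and s_ctrl.size:
        score_p = stats.mannwhitneyu(s_case, s_ctrl, alternative="two-sided").pvalue
    else:
        score_p = np.nan
    return float(count_p), float(score_p)


def _group_summary(scores, counts, study) -> pd.DataFrame:
    rows = []
    for name, mask in (("case", study.is_case), ("control", study.is_control)):
        s = scores[mask]
        rows.append(
            {
                "group": name,
                "n_individuals": int(mask.sum()),
                "n_variants_mean": float(counts[mask].mean()) if mask.sum() else np.nan,
                "score_mean": float(s.mean()) if s.size else np.nan,
                "score_median": float(np.median(s)) if s.size else np.nan,
                "score_sd": float(s.std(ddof=1)) if s.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_analyses(result: ISUBResult, study: GenotypeStudy,
                         covariates: list[str] | None = None,
                         outlier_sd: float = 5.0) -> ISUBResult:
    """Outlier-removed and log-transformed re-analyses.

    (a) Individuals whose score lies more than ``outlier_sd`` SDs from
    the set mean are removed and the comparison rerun; (b) the
    comparison is rerun on log(S_i + 1) (the offset accommodates zero
    scores).
    """
    s = result.scores
    mu, sd = s.mean(), s.std()
    keep = np.abs(s - mu) <= outlier_sd * sd if sd > 0 else np.ones(len(s), bool)
    if not keep.any():
        raise ValueError("all individuals removed as outliers")
    if keep.all():
        result.outlier_removed_p = result.comparison_p
    else:
        sub = study.take_samples(keep)
        result.outlier_removed_p = compare_isub(s[keep], sub, covariates)
    result.log_transformed_p = compare_isub(np.log(s + 1.0), study, covariates)
    return result


def run_isub(study: GenotypeStudy, covariates: list[str] | None = None,
             cohorts: tuple[str, ...] | None = None,
             ref_maf_max: float = 0.005, outlier_sd: float = 5.0,
             pooled_max_for_unscored: bool = False) -> dict[str, ISUBResult]:
    """Full ISUB analysis for the NS and DEL classes.

    With ``cohorts`` given, the study is first restricted to those
    countries and every step — set-uniqueness included — is recomputed
    within the subset (set-uniqueness is subset-relative).
    """
    if cohorts is not None:
        present = set(study.samples["country"])
        missing = [c for c in cohorts if c not in present]
        if missing:
            raise ValueError(f"requested cohorts absent: {missing}")
        study = study.take_samples(
            study.samples["country"].isin(cohorts).to_numpy()
        )

    case_u, ctrl_u = set_unique_variants(study)
    case_u = filter_reference_maf(case_u, study.variants, ref_maf_max)
    ctrl_u = filter_reference_maf(ctrl_u, study.variants, ref_maf_max)
    ns, del_set = build_class_sets(study, case_u, ctrl_u, pooled_max_for_unscored)

    results = {}
    for name, cset in (("NS", ns), ("DEL", del_set)):
        scores, counts = isub_scores(study, cset)
        res = ISUBResult(
            variant_class=name,
            scores=scores,
            counts=counts,
            group_summary=_group_summary(scores, counts, study),
            comparison_p=compare_isub(scores, study, covariates),
            cohorts=tuple(cohorts) if cohorts else (),
            n_cases=int(study.is_case.sum()),
            n_controls=int(study.is_control.sum()),
        )
        res.count_comparison_p, res.per_variant_score_comparison_p = (
            count_and_score_diagnostics(study, cset, counts)
        )
        if np.isfinite(res.comparison_p):
            res = sensitivity_analyses(res, study, covariates, outlier_sd)
        results[name] = res
    return results


def balanced_subset_analysis(study: GenotypeStudy, cohorts: tuple[str, ...],
                             covariates: list[str] | None = None,
                             **kwargs) -> dict[str, ISUBResult]:
    """ISUB recomputed from scratch within the named (balanced) cohorts."""
    return run_isub(study, covariates, cohorts=cohorts, **kwargs)
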