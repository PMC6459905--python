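"""Single-variant association testing under an additive model.

Per-variant logistic regression (Wald p, PLINK convention) and
Firth-penalized logistic regression (penalized-LRT p, logistf
convention) of case/control status on minor-allele dosage plus
covariates, with genomic-inflation and multiple-testing diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import fit_logistic, firth_lrt_p
from .io import GenotypeStudy

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["PC1", "PC2", "PC3", "PC4", "PC5", "sex", "country"]


def build_covariate_matrix(samples: pd.DataFrame,
                           covariates: list[str] | None) -> np.ndarray:
    """Numeric design block for the requested covariate columns.

    ``country`` (or any non-numeric column) is expanded to K-1
    indicators against the largest category; ``sex`` is coded 0/1.
    Columns absent from the table are skipped with a warning.
    """
    blocks = []
    for name in covariates or []:
        if name not in samples.columns:
            logger.warning("covariate %r not in sample table; skipped", name)
            continue
        col = samples[name]
        if name == "sex":
            blocks.append((col.to_numpy(float) == 1).astype(float)[:, None])
        elif pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(float)[:, None])
        else:
            counts = col.value_counts()
            ref = counts.index[0]  # largest category as reference
            for level in counts.index[1:]:
                blocks.append((col == level).to_numpy(float)[:, None])
    if not blocks:
        return np.empty((len(samples), 0))
    return np.hstack(blocks)


@dataclass
class AssociationResult:
    table: pd.DataFrame  # variant_id, maf, mac, beta, se, odds_ratio, p, test, n_used, flag

    def pvalues(self) -> np.ndarray:
        return self.table["p"].to_numpy()


def _assoc(study: GenotypeStudy, covariates, method: str) -> AssociationResult:
    y_all = study.phenotype
    use = y_all >= 0
    samples = study.samples.loc[use].reset_index(drop=True)
    y_full = y_all[use].astype(float)
    C = build_covariate_matrix(samples, covariates)
    G = study.genotypes[use]

    rows = []
    for j in range(study.n_variants):
        g = G[:, j].astype(float)
        ok = g >= 0
        yv, gv, Cv = y_full[ok], g[ok], C[ok]
        n_used = int(ok.sum())
        mac = int(gv.sum())
        mac = min(mac, 2 * n_used - mac)
        maf = mac / (2 * n_used) if n_used else np.nan
        vid = study.variants["variant_id"].iloc[j]
        if n_used == 0 or gv.std() == 0:
            rows.append((vid, maf, mac, np.nan, np.nan, np.nan, np.nan,
                         method, n_used, "monomorphic in analyzed samples"))
            continue
        X = np.hstack([np.ones((n_used, 1)), gv[:, None], Cv])
        if method == "logistic_wald":
            fit = fit_logistic(X, yv)
            if fit.separated:
                rows.append((vid, maf, mac, np.nan, np.nan, np.nan, np.nan,
                             method, n_used, "separation; firth recommended"))
                continue
            beta, se = fit.beta[1], fit.se[1]
            p = fit.wald_p(1)
            flag = "" if fit.converged else "non-converged"
        else:  # firth_lrt
            p, fit = firth_lrt_p(X, yv, 1)
            beta, se = fit.beta[1], fit.se[1]
            flag = "" if fit.converged else "iteration cap exceeded"
        rows.append((vid, maf, mac, beta, se, float(np.exp(beta)), p,
                     method, n_used, flag))
    table = pd.DataFrame(
        rows,
        columns=["variant_id", "maf", "mac", "beta", "se", "odds_ratio",
                 "p", "test", "n_used", "flag"],
    )
    return AssociationResult(table)


def logistic_assoc(study: GenotypeStudy,
                   covariates: list[str] | None = None) -> AssociationResult:
    """Per-variant additive-model logistic regression (Wald p-values).

    Missing genotypes drop the sample for that variant; monomorphic and
    separated variants are flagged rather than reported with a p-value.
    """
    return _assoc(study, covariates, "logistic_wald")


def firth_assoc(study: GenotypeStudy,
                covariates: list[str] | None = None) -> AssociationResult:
    """Per-variant Firth-penalized regression (penalized-LRT p-values)."""
    return _assoc(study, covariates, "firth_lrt")


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor lambda_GC.

    Median of the chi-square(1 df) quantiles of the observed p-values
    divided by the theoretical null median (~0.4549). Values below 1
    arise when the spectrum is dominated by rare, low-power variants.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0,1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def qq_table(p_values: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 p for a QQ plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(p)}
    )
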