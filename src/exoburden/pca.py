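"""Principal components for population-stratification assessment.

Uses the classical genotype normalization of Price et al.'s EIGENSTRAT:
each variant column is mean-imputed, centered by twice the posterior
allele-frequency estimate and scaled by the binomial SD at that
frequency, then decomposed by SVD. Population outliers are flagged
against a labeled reference cluster on the leading components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeStudy

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: np.ndarray          # n_samples x k
    loadings: np.ndarray        # n_variants_used x k
    eigenvalues: np.ndarray
    sample_ids: pd.Series
    is_reference: np.ndarray
    is_outlier: np.ndarray
    variant_index: np.ndarray   # indices of columns actually used


def compute_pcs(study: GenotypeStudy, variant_subset: np.ndarray, k: int = 10,
                is_reference: np.ndarray | None = None) -> PCAResult:
    """EIGENSTRAT-normalized PCA on a pruned variant subset.

    Missing genotypes are mean-imputed; each column is centered by
    ``2*p_hat`` and scaled by ``sqrt(p_hat*(1-p_hat))`` with the
    posterior frequency ``p_hat = (1 + sum g) / (2 + 2n)``. Zero-variance
    columns are dropped. Component signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    g = study.genotypes[:, variant_subset].astype(float)
    n = g.shape[0]
    missing = g < 0
    g[missing] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])

    n_called = (~missing).sum(axis=0)
    p_hat = (1.0 + np.where(missing, 0, study.genotypes[:, variant_subset]).sum(axis=0)) / (
        2.0 + 2.0 * n_called
    )
    keep = g.std(axis=0) > 0
    g = g[:, keep]
    p_hat = p_hat[keep]
    used = np.asarray(variant_subset)[keep]

    X = (g - 2.0 * p_hat) / np.sqrt(p_hat * (1.0 - p_hat))
    X -= X.mean(axis=0)  # scores have zero mean by construction

    max_k = min(n, X.shape[1])
    if k > max_k:
        logger.warning("compute_pcs: k=%d exceeds rank, reduced to %d", k, max_k)
        k = max_k
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]

    # deterministic sign: largest-|loading| entry positive per component
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0

    scores = U * S
    eigenvalues = S**2 / max(n - 1, 1)
    if is_reference is None:
        is_reference = np.zeros(n, dtype=bool)
    return PCAResult(
        scores=scores,
        loadings=Vt.T,
        eigenvalues=eigenvalues,
        sample_ids=study.samples["sample_id"].reset_index(drop=True),
        is_reference=np.asarray(is_reference, dtype=bool),
        is_outlier=np.zeros(n, dtype=bool),
        variant_index=used,
    )


def flag_outliers(pca: PCAResult, sd: float = 10.0, n_pcs: int = 4,
                  use_reference_sd: bool = True) -> set[str]:
    """Flag samples deviating from the reference cluster on leading PCs.

    A sample is an outlier if on any of the first ``n_pcs`` components
    its score lies more than ``sd`` reference-cluster standard
    deviations from the reference-cluster mean. With
    ``use_reference_sd=False`` the whole-sample SD is used instead.
    Updates ``pca.is_outlier`` in place and returns the flagged ids.
    """
    ref = pca.is_reference
    if ref.sum() == 0:
        raise ValueError("no reference samples labeled")
    n_pcs = min(n_pcs, pca.scores.shape[1])
    S = pca.scores[:, :n_pcs]
    mu = S[ref].mean(axis=0)
    sigma = S[ref].std(axis=0) if use_reference_sd else S.std(axis=0)
    sigma = np.where(sigma > 0, sigma, np.inf)
    out = (np.abs(S - mu) > sd * sigma).any(axis=1)
    out &= ~ref  # reference samples are never flagged
    pca.is_outlier = out
    ids = set(pca.sample_ids[out])
    logger.info("flag_outliers: %d outliers at %g SD on PC1..%d", len(ids), sd, n_pcs)
    return ids
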