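"""Analytic single-variant power and simulation-based gene-test power.

The single-variant calculator follows the classical case-control
allelic trend-test derivation: genotype penetrances are additive on the
log-odds scale, the baseline odds is solved so the population risk
matches the disease prevalence, expected risk-allele frequencies in
cases and controls follow, and power is the tail probability of the
1-df non-central chi-square whose non-centrality comes from the
expected allele-frequency difference at the given sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .burden import skat_o
from .simulate import SimulationConfig, simulate_study


@dataclass
class PowerQuery:
    n_cases: int
    n_controls: int
    maf: float
    odds_ratio: float
    alpha: float
    prevalence: float = 1.0 / 350.0  # lifetime risk of the modeled disease

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0,0.5]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0,1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")


def expected_allele_freqs(maf: float, odds_ratio: float,
                          prevalence: float) -> tuple[float, float]:
    """Expected risk-allele frequency in cases and in controls.

    Genotype odds are ``odds0 * OR**g`` (additive log-odds); ``odds0``
    is solved so the HWE-weighted penetrance equals the prevalence.
    """
    g = np.array([0.0, 1.0, 2.0])
    Pg = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])

    def pop_risk(odds0):
        f = odds0 * odds_ratio**g / (1 + odds0 * odds_ratio**g)
        return float((Pg * f).sum()) - prevalence

    odds0 = brentq(pop_risk, 1e-14, 1e6)
    f = odds0 * odds_ratio**g / (1 + odds0 * odds_ratio**g)
    p_case = float((Pg * f * g / 2).sum() / (Pg * f).sum())
    p_ctrl = float((Pg * (1 - f) * g / 2).sum() / (Pg * (1 - f)).sum())
    return p_case, p_ctrl


def single_variant_power(q: PowerQuery,
                         unselected_controls: bool = False) -> float:
    """Analytic power of the allelic trend test at threshold ``alpha``.

    ``unselected_controls=True`` treats controls as population draws
    (allele frequency = MAF) rather than screened disease-free.
    """
    q.validate()
    p_case, p_ctrl = expected_allele_freqs(q.maf, q.odds_ratio, q.prevalence)
    if unselected_controls:
        p_ctrl = q.maf
    n1, n2 = 2 * q.n_cases, 2 * q.n_controls  # allele counts
    p_bar = (n1 * p_case + n2 * p_ctrl) / (n1 + n2)
    ncp = (p_case - p_ctrl) ** 2 / (p_bar * (1 - p_bar) * (1 / n1 + 1 / n2))
    crit = stats.chi2.isf(q.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def simulate_single_variant_power(q: PowerQuery, n_sims: int = 1000,
                                  seed: int = 0) -> float:
    """Empirical rejection rate of the trend test on simulated studies.

    Case/control genotypes are drawn from their exact retrospective
    genotype distributions under the penetrance model; each replicate is
    tested with the Cochran-Armitage trend chi-square.
    """
    q.validate()
    rng = np.random.default_rng(seed)
    g = np.array([0.0, 1.0, 2.0])
    Pg = np.array([(1 - q.maf) ** 2, 2 * q.maf * (1 - q.maf), q.maf**2])
    odds0 = brentq(
        lambda o: float((Pg * (o * q.odds_ratio**g / (1 + o * q.odds_ratio**g))).sum())
        - q.prevalence,
        1e-14, 1e6,
    )
    f = odds0 * q.odds_ratio**g / (1 + odds0 * q.odds_ratio**g)
    P_case = Pg * f / (Pg * f).sum()
    P_ctrl = Pg * (1 - f) / (Pg * (1 - f)).sum()
    crit = stats.chi2.isf(q.alpha, df=1)
    hits = 0
    for _ in range(n_sims):
        cc = rng.multinomial(q.n_cases, P_case)
        kk = rng.multinomial(q.n_controls, P_ctrl)
        a1 = cc @ g  # case risk alleles
        a2 = kk @ g
        n1, n2 = 2 * q.n_cases, 2 * q.n_controls
        p1, p2 = a1 / n1, a2 / n2
        pb = (a1 + a2) / (n1 + n2)
        if pb in (0.0, 1.0):
            continue
        chi = (p1 - p2) ** 2 / (pb * (1 - pb) * (1 / n1 + 1 / n2))
        if chi > crit:
            hits += 1
    return hits / n_sims


def gene_test_power(base_config: SimulationConfig,
                    causal_fractions, protective_fractions,
                    alpha: float = 3.45e-6, n_simulations: int = 200,
                    seed: int = 0):
    """Empirical SKAT-O power over a causal/protective architecture grid.

    For each (causal_fraction, protective_fraction) cell, simulates
    ``n_simulations`` single-gene studies from the generator, runs the
    optimal test at level ``alpha`` and reports the rejection fraction
    with a 95% binomial (Wilson) interval.
    """
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    import pandas as pd

    causal_fractions = list(causal_fractions)
    protective_fractions = list(protective_fractions)
    rows = []
    for ci, cf in enumerate(causal_fractions):
        for pi, pf in enumerate(protective_fractions):
            hits = 0
            cell = ci * len(protective_fractions) + pi
            for s in range(n_simulations):
                cfg = SimulationConfig(
                    **{
                        **base_config.to_dict(),
                        "causal_fraction": cf,
                        "protective_fraction": pf,
                        "seed": (seed + 7919 * s + 104729 * cell) % (2**31 - 1),
                    }
                )
                study = simulate_study(cfg)
                fit = skat_o(study.genotypes, study.phenotype.astype(float))
                if fit.nominal_p < alpha:
                    hits += 1
            p_hat = hits / n_simulations
            z = 1.959963984540054
            denom = 1 + z**2 / n_simulations
            center = (p_hat + z**2 / (2 * n_simulations)) / denom
            half = (
                z
                * np.sqrt(p_hat * (1 - p_hat) / n_simulations + z**2 / (4 * n_simulations**2))
                / denom
            )
            rows.append(
                {
                    "causal_fraction": cf,
                    "protective_fraction": pf,
                    "power": p_hat,
                    "ci_low": max(center - half, 0.0),
                    "ci_high": min(center + half, 1.0),
                    "n_simulations": n_simulations,
                }
            )
    return pd.DataFrame(rows)
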