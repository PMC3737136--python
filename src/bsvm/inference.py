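"""Permutation significance for regions and individual variants, plus the
classical single-variant 2x2 allele-count tests.

The region statistic is the post-selection R^2.  Each permutation shuffles
the case/control labels and re-runs the *entire* pipeline — direction
classification, weighting, collapsing, backward elimination — so that the
selection's optimisation is inside the null distribution; permuting labels
around a fixed selected model would inflate the type I error.  P-values
use the add-one rule (1 + #{null >= observed}) / (B + 1), so they are
never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._core import _compute_weights, _pipeline_r2, _subset_r2
from .backward_selection import _pattern_arrays, backward_select
from .data_model import GenotypeDataset, drop_monomorphic, summarize_variants
from .svm_engine import SvmConfig
from .weighting import RISK, WeightScheme, compute_weights


@dataclass
class PermutationResult:
    """Observed statistic, permutation null draws and the add-one p-value."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    B: int
    seed: int


def _prepare(data, scheme, svm_config):
    if isinstance(scheme, str):
        scheme = WeightScheme(scheme)
    if svm_config is None:
        svm_config = SvmConfig()
    data, _ = drop_monomorphic(data)
    pat, pat_id, n_case_p, n_ctrl_p = _pattern_arrays(data)
    sum_g2 = ((pat ** 2) * (n_case_p + n_ctrl_p)[:, None]).sum(axis=0)
    return data, scheme, svm_config, pat, pat_id, n_case_p, n_ctrl_p, sum_g2


def _core_args(svm_config):
    return (svm_config.C, svm_config.resolved_gamma(2),
            svm_config.standardize, svm_config.tol, svm_config.max_iter,
            svm_config.r2_mode_code)


def _permuted_case_counts(pat_id, n_patterns, case_vec, rng):
    perm = rng.permutation(case_vec)
    n_case_p = np.bincount(pat_id, weights=perm, minlength=n_patterns)
    return n_case_p


def region_test(data: GenotypeDataset, scheme="RM",
                svm_config: SvmConfig | None = None, B: int = 1000,
                seed: int = 0) -> PermutationResult:
    """Permutation test of association between the disease and the
    informative variants retained by backward selection.

    The observed statistic is the final R^2 of the selection on the true
    labels; ``B`` label permutations each re-run the full pipeline.
    Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    (data, scheme, svm_config, pat, pat_id, n_case_p, n_ctrl_p,
     sum_g2) = _prepare(data, scheme, svm_config)
    args = _core_args(svm_config)
    observed = _pipeline_r2(pat, n_case_p, n_ctrl_p, data.n1, data.n2,
                            scheme.code, scheme.erec_delta, sum_g2, *args)
    rng = np.random.default_rng(seed)
    case_vec = (data.labels == 1).astype(np.float64)
    total = n_case_p + n_ctrl_p
    null_stats = np.empty(B)
    for b in range(B):
        ncp = _permuted_case_counts(pat_id, pat.shape[0], case_vec, rng)
        null_stats[b] = _pipeline_r2(pat, ncp, total - ncp, data.n1,
                                     data.n2, scheme.code, scheme.erec_delta,
                                     sum_g2, *args)
    p = (1 + int((null_stats >= observed).sum())) / (B + 1)
    return PermutationResult(float(observed), null_stats, float(p), B, seed)


def region_rejects(data: GenotypeDataset, scheme, svm_config, B, alpha,
                   rng) -> bool:
    """Decide p <= alpha with curtailed permutation sampling.

    Stops as soon as the exceedance count k makes p = (1+k)/(B+1) > alpha
    inevitable; the decision is identical to running all B permutations.
    Used by the power study, where only the rejection indicator matters.
    """
    (data, scheme, svm_config, pat, pat_id, n_case_p, n_ctrl_p,
     sum_g2) = _prepare(data, scheme, svm_config)
    args = _core_args(svm_config)
    observed = _pipeline_r2(pat, n_case_p, n_ctrl_p, data.n1, data.n2,
                            scheme.code, scheme.erec_delta, sum_g2, *args)
    case_vec = (data.labels == 1).astype(np.float64)
    total = n_case_p + n_ctrl_p
    k_stop = int(np.floor(alpha * (B + 1)))  # reject iff k <= k_stop - 1
    k = 0
    for b in range(B):
        ncp = _permuted_case_counts(pat_id, pat.shape[0], case_vec, rng)
        r2 = _pipeline_r2(pat, ncp, total - ncp, data.n1, data.n2,
                          scheme.code, scheme.erec_delta, sum_g2, *args)
        if r2 >= observed:
            k += 1
            if k >= k_stop:
                return False
    return (1 + k) / (B + 1) <= alpha


def variant_test(data: GenotypeDataset, scheme="RM",
                 svm_config: SvmConfig | None = None, retained=None,
                 B: int = 1000, seed: int = 0) -> dict:
    """Per-variant permutation p-values for the retained informative set.

    The statistic for variant i is the drop in R^2 when i is removed from
    the retained model, Delta_i = R^2(retained) - R^2(retained \\ {i}).
    The null permutes labels with the retained set held fixed (weights are
    re-estimated from the permuted labels); re-running the selection per
    variant per permutation would be prohibitively cubic, so the fixed-set
    null is an approximation.
    """
    (data, scheme, svm_config, pat, pat_id, n_case_p, n_ctrl_p,
     sum_g2) = _prepare(data, scheme, svm_config)
    args = _core_args(svm_config)
    if retained is None:
        summaries = compute_weights(data, scheme=scheme)
        retained = backward_select(data, summaries, svm_config).retained
    retained = list(retained)
    if not retained:
        raise ValueError("retained set is empty")
    ridx = [data.variant_ids.index(v) for v in retained]
    keep_full = np.zeros(data.n_variants, dtype=np.bool_)
    keep_full[ridx] = True

    def deltas(ncp, nclp):
        mc = pat.T @ ncp
        mu = pat.T @ nclp
        w, cat = _compute_weights(mc, mu, data.n1, data.n2, scheme.code,
                                  scheme.erec_delta, sum_g2)
        full = _subset_r2(pat, ncp, nclp, w, cat, keep_full, data.n1,
                          data.n2, *args)
        out = np.empty(len(ridx))
        for a, j in enumerate(ridx):
            keep = keep_full.copy()
            keep[j] = False
            if keep.any():
                r2m = _subset_r2(pat, ncp, nclp, w, cat, keep, data.n1,
                                 data.n2, *args)
            else:
                r2m = 0.0
            out[a] = full - r2m
        return out

    obs = deltas(n_case_p, n_ctrl_p)
    rng = np.random.default_rng(seed)
    case_vec = (data.labels == 1).astype(np.float64)
    total = n_case_p + n_ctrl_p
    exceed = np.zeros(len(ridx), dtype=np.int64)
    for b in range(B):
        ncp = _permuted_case_counts(pat_id, pat.shape[0], case_vec, rng)
        exceed += deltas(ncp, total - ncp) >= obs
    p = (1 + exceed) / (B + 1)
    return {vid: float(pv) for vid, pv in zip(retained, p)}


def exact_allele_test(m_case: int, m_ctrl: int, chrom_case: int,
                      chrom_ctrl: int) -> float:
    """Two-sided Fisher exact p-value on the 2x2 minor/major allele-count
    table, summing all tables as or less probable than the observed one."""
    if m_case > chrom_case or m_ctrl > chrom_ctrl:
        raise ValueError("allele counts exceed chromosome totals")
    table = [[m_case, chrom_case - m_case],
             [m_ctrl, chrom_ctrl - m_ctrl]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def chisq_allele_test(m_case: int, m_ctrl: int, chrom_case: int,
                      chrom_ctrl: int) -> float:
    """Pearson chi-squared (1 df, no continuity correction) on the same
    2x2 allele-count table; suitable for common variants."""
    table = np.array([[m_case, chrom_case - m_case],
                      [m_ctrl, chrom_ctrl - m_ctrl]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        raise ValueError("expected cell count < 1: use exact_allele_test")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)
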