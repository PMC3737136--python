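"""Variant direction classification, per-variant weights, and directional
collapsing into the two burden covariates.

Five weighting schemes are supported:

``RM``
    The data-adaptive risk measure: the Poisson likelihood ratio of a
    mutation event in a case versus a control (reversed for nonrisk
    variants), times the (m+2)/(m+1) correction that keeps the denominator
    away from zero.  On balanced designs 1 < RM < inf, RM grows with the
    strength of association in either direction, and RM is close to one
    for variants unrelated to disease.
``WSt``
    Madsen-Browning weighted-sum weight from the estimated control
    frequency: rarer-in-controls variants are up-weighted.
``Fp``
    Pooled-frequency analogue of WSt.
``RBt``
    Replication-based weight: minus the log of the one-sided binomial tail
    probability of the observed case/control split of mutant alleles.
    Approximate re-implementation from a one-line description.
``EREC``
    Estimated-regression-coefficient weight |beta + delta| with a one-step
    logistic score estimate of beta and stabilising offset delta
    (default 1).  Approximate re-implementation; the sign of beta + delta
    overrides the count-based direction category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._core import SCHEME_CODES, _compute_weights
from .data_model import GenotypeDataset, VariantSummary

logger = logging.getLogger(__name__)

RISK = "risk"
NONRISK = "nonrisk"


@dataclass
class WeightScheme:
    """One of the five weighting schemes with its scheme-specific constants."""

    name: str = "RM"
    erec_delta: float = 1.0

    def __post_init__(self):
        if self.name not in SCHEME_CODES:
            raise ValueError(f"unknown weighting scheme {self.name!r}; "
                             f"choose from {sorted(SCHEME_CODES)}")

    @property
    def code(self) -> int:
        return SCHEME_CODES[self.name]


@dataclass
class CollapsedPair:
    """Per-individual cumulative weighted risk / protective burden pair."""

    s_risk: np.ndarray
    s_nonrisk: np.ndarray
    members_risk: set = field(default_factory=set)
    members_nonrisk: set = field(default_factory=set)

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.s_risk, self.s_nonrisk])


def classify_variant(m_case: int, m_ctrl: int) -> str:
    """Risk if the minor allele is more frequent in cases than controls,
    nonrisk otherwise (ties included)."""
    return RISK if m_case > m_ctrl else NONRISK


def rm_weight(m_case: int, m_ctrl: int, n1: int, n2: int,
              category: str) -> float:
    """Poisson likelihood-ratio risk measure.

    Per-chromosome mutation rates are estimated with +1/+2 smoothing,
    lambda_case = (m_case+1)/(2 n1 + 2) and analogously for controls; the
    rate ratio (case/control for risk variants, reversed for nonrisk) is
    multiplied by (m+2)/(m+1) where m is the total mutant-allele count.
    """
    m = m_case + m_ctrl
    if m < 1:
        raise ValueError("RM weight undefined for a monomorphic variant")
    lam_case = (m_case + 1) / (2 * n1 + 2)
    lam_ctrl = (m_ctrl + 1) / (2 * n2 + 2)
    corr = (m + 2) / (m + 1)
    ratio = lam_case / lam_ctrl if category == RISK else lam_ctrl / lam_case
    return ratio * corr


def wst_weight(m_ctrl: int, n2: int, n: int) -> float:
    """Madsen-Browning weight 1/sqrt(n q(1-q)) with the smoothed control
    frequency q = (m_ctrl+1)/(2 n2 + 2)."""
    q = (m_ctrl + 1) / (2 * n2 + 2)
    return 1.0 / np.sqrt(n * q * (1 - q))


def fp_weight(m_case: int, m_ctrl: int, n: int) -> float:
    """Pooled-frequency weight 1/sqrt(p(1-p)),
    p = (m_case+m_ctrl+1)/(2n+2)."""
    p = (m_case + m_ctrl + 1) / (2 * n + 2)
    return 1.0 / np.sqrt(p * (1 - p))


def rbt_weight(m_case: int, m_ctrl: int, n1: int, n2: int,
               category: str) -> float:
    """Replication-based weight: -log of the one-sided binomial tail of the
    mutant-allele split between cases and controls."""
    m = m_case + m_ctrl
    if m < 1:
        raise ValueError("RBt weight undefined for a monomorphic variant")
    n = n1 + n2
    if category == RISK:
        sf = stats.binom.sf(m_case - 1, m, n1 / n)
    else:
        sf = stats.binom.sf(m_ctrl - 1, m, n2 / n)
    if sf <= 0:
        return 745.0
    w = -np.log(sf)
    if not np.isfinite(w) or w <= 0:
        return rm_weight(m_case, m_ctrl, n1, n2, category)
    return float(w)


def erec_weight(m_case: int, m_ctrl: int, n1: int, n2: int,
                genotype_column: np.ndarray, labels: np.ndarray,
                delta: float = 1.0):
    """EREC weight |beta + delta| with a one-step logistic score estimate.

    beta is approximated by U/I from the null-scored logistic model of
    case status on the allele count.  Returns ``(weight, category)``:
    the sign of beta + delta determines the direction category.  When the
    weight degenerates to 0 (delta = 0 and a null coefficient) the
    count-based RM weight and category are the fallback.
    """
    g = np.asarray(genotype_column, dtype=float)
    y = (np.asarray(labels) == 1).astype(float)
    n = n1 + n2
    ybar = n1 / n
    score = float(g @ (y - ybar))
    gbar = g.mean()
    info = ybar * (1 - ybar) * float(((g - gbar) ** 2).sum())
    beta = score / info if info > 1e-12 else 0.0
    v = beta + delta
    w = abs(v)
    cat = RISK if v >= 0 else NONRISK
    if not np.isfinite(w) or w <= 1e-12:
        cat = classify_variant(m_case, m_ctrl)
        w = rm_weight(m_case, m_ctrl, n1, n2, cat)
    return float(w), cat


def compute_weights(data: GenotypeDataset,
                    summaries: list[VariantSummary] | None = None,
                    scheme: WeightScheme | str = "RM"
                    ) -> list[VariantSummary]:
    """Populate category and weight for every variant under one scheme.

    Uses the compiled kernel shared with the permutation pipeline, so the
    interactive path and the simulation path cannot drift apart.
    """
    from .data_model import summarize_variants

    if isinstance(scheme, str):
        scheme = WeightScheme(scheme)
    if summaries is None:
        summaries = summarize_variants(data)
    n1, n2 = data.n1, data.n2
    if scheme.name == "RM" and n1 != n2:
        logger.warning("unbalanced design (n1=%d, n2=%d): RM > 1 is not "
                       "guaranteed", n1, n2)
    m_case = np.array([s.m_case for s in summaries], dtype=float)
    m_ctrl = np.array([s.m_ctrl for s in summaries], dtype=float)
    if (m_case + m_ctrl).min() < 1:
        raise ValueError("monomorphic variant present; drop it first")
    sum_g2 = (data.counts.astype(np.float64) ** 2).sum(axis=0)
    w, cat = _compute_weights(m_case, m_ctrl, n1, n2, scheme.code,
                              scheme.erec_delta, sum_g2)
    out = []
    for s, wi, ci in zip(summaries, w, cat):
        out.append(VariantSummary(s.variant_id, s.m_case, s.m_ctrl,
                                  RISK if ci == 1 else NONRISK, float(wi)))
    return out


def collapse(data: GenotypeDataset, summaries: list[VariantSummary],
             active_set=None) -> CollapsedPair:
    """Collapse weighted minor-allele counts of the active variants into
    the cumulative risk and protective burden covariates.

    ``s_risk[k]`` sums ``weight_i * counts[k, i]`` over active risk
    variants; ``s_nonrisk`` analogously over active nonrisk variants.
    Variants outside ``active_set`` contribute nothing to either.
    """
    by_id = {s.variant_id: s for s in summaries}
    if active_set is None:
        active_set = set(by_id)
    active_set = set(active_set)
    if not active_set:
        raise ValueError("active_set is empty")
    unknown = active_set - set(by_id)
    if unknown:
        raise ValueError(f"active_set contains unknown variants: {unknown}")
    s_risk = np.zeros(data.n)
    s_nonrisk = np.zeros(data.n)
    members_risk, members_nonrisk = set(), set()
    for j, vid in enumerate(data.variant_ids):
        if vid not in active_set:
            continue
        s = by_id[vid]
        if s.weight is None or s.category is None:
            raise ValueError(f"variant {vid} has no weight/category")
        contrib = s.weight * data.counts[:, j]
        if s.category == RISK:
            s_risk += contrib
            members_risk.add(vid)
        else:
            s_nonrisk += contrib
            members_nonrisk.add(vid)
    return CollapsedPair(s_risk, s_nonrisk, members_risk, members_nonrisk)


def weights_table(summaries: list[VariantSummary],
                  scheme: WeightScheme | str = "RM") -> pd.DataFrame:
    name = scheme if isinstance(scheme, str) else scheme.name
    return pd.DataFrame(
        {"variant_id": [s.variant_id for s in summaries],
         "m_case": [s.m_case for s in summaries],
         "m_ctrl": [s.m_ctrl for s in summaries],
         "category": [s.category for s in summaries],
         "scheme": name,
         "weight": [s.weight for s in summaries]})


def export_weights_tsv(summaries, path, scheme="RM") -> None:
    weights_table(summaries, scheme).to_csv(path, sep="\t", index=False)
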