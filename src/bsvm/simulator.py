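"""Case-control rare-variant simulator and power / type-I-error studies.

Control minor-allele frequencies follow Wright's stationary
mutation-selection-drift distribution,

    f(q)  proportional to  q**(beta1 - 1) * (1 - q)**(beta2 - 1)
                           * exp(sigma * (1 - q)),

with scaled mutation rates beta1 = 0.001, beta2 = beta1/3 and selection
rate sigma = 12 by default.  The density is evaluated on a truncated
support [1/(4e4), 0.5] (below the lower bound an allele is effectively
absent from a population of this scale; above 0.5 the allele would no
longer be the minor one) and sampled by inverse CDF on a fine
logarithmically spaced grid.  Under these defaults roughly 77% of draws —
about 141 out of 183 — fall below MAF 0.01.

Effect sizes are specified by per-variant population-attributable risks
(PARs).  A risk variant's odds ratio follows from the attributable-risk
inversion OR = 1 + PAR / (MAF_U * (1 - PAR)); its case frequency from
MAF_A = OR * MAF_U / (1 + MAF_U * (OR - 1)).  Protective variants attach
the same per-variant PAR to the *major* allele, so their minor allele is
depleted in cases (MAF_A < MAF_U).  Genotypes are Hardy-Weinberg
Binomial(2, MAF) draws, independent across variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GenotypeDataset
from .inference import region_rejects, region_test
from .svm_engine import SvmConfig

MAF_FLOOR = 1.0 / 4e4


@dataclass(frozen=True)
class WrightParams:
    beta1: float = 0.001
    beta2: float = 0.001 / 3
    sigma: float = 12.0
    q_min: float = MAF_FLOOR
    q_max: float = 0.5
    grid_size: int = 4096


@dataclass
class Scenario:
    """One simulation condition.

    ``n_risk`` / ``n_protective`` / ``n_neutral`` give the variant mix;
    ``M`` defaults to their sum but may exceed it (as in the 183-variant
    condition), in which case causal roles are assigned to uniformly drawn
    rare variants (MAF_U < 0.01) and the remainder are neutral.
    ``total_par`` is split over the risk variants (equally, or uniformly
    renormalised); protective variants mirror the per-variant PARs in the
    protective direction.

    When ``wright`` is not given, a pure mixture scenario (``M`` equal to
    the risk/protective/neutral sum) draws its control MAFs from the
    Wright density truncated to the rare range (below 0.01): these
    scenarios model a set of rare variants with mixed effects.  A larger
    region (``M`` above the sum) uses the full spectrum up to 0.5, of
    which roughly three quarters come out rare.
    """

    n_risk: int = 10
    n_protective: int = 0
    n_neutral: int = 10
    M: int | None = None
    total_par: float = 0.03
    par_mode: str = "equal"  # or "uniform"
    n1: int = 500
    n2: int = 500
    wright: WrightParams | None = None

    def __post_init__(self):
        mix = self.n_risk + self.n_protective + self.n_neutral
        if self.M is None:
            self.M = mix
        if self.wright is None:
            self.wright = (WrightParams(q_max=0.01) if self.M == mix
                           else WrightParams())
        if self.M < self.n_risk + self.n_protective + self.n_neutral:
            raise ValueError("M smaller than the requested variant mix")
        if not 0 <= self.total_par < 1:
            raise ValueError("total_par must be in [0, 1)")
        if self.par_mode not in ("equal", "uniform"):
            raise ValueError("par_mode must be 'equal' or 'uniform'")
        if self.total_par > 0 and self.n_risk == 0:
            raise ValueError("positive total_par needs risk variants")


_GRID_CACHE: dict = {}


def _wright_grid(params: WrightParams):
    key = params
    if key not in _GRID_CACHE:
        q = np.exp(np.linspace(np.log(params.q_min), np.log(params.q_max),
                               params.grid_size))
        logf = ((params.beta1 - 1) * np.log(q)
                + (params.beta2 - 1) * np.log1p(-q)
                + params.sigma * (1 - q))
        f = np.exp(logf - logf.max())
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (f[1:] + f[:-1]) * np.diff(q))])
        cdf /= cdf[-1]
        # deduplicate flat CDF stretches for a well-posed inverse
        keep = np.concatenate([[True], np.diff(cdf) > 0])
        _GRID_CACHE[key] = (cdf[keep], q[keep])
    return _GRID_CACHE[key]


def wright_cdf(q, params: WrightParams | None = None):
    """Numerically integrated CDF of the truncated Wright density
    (independent of the sampler's inverse-CDF path only up to the shared
    grid; used for reporting, not as a test oracle)."""
    params = params or WrightParams()
    cdf, grid = _wright_grid(params)
    return np.interp(q, grid, cdf)


def sample_maf_wright(M: int, params: WrightParams | None = None,
                      rng=None) -> np.ndarray:
    """Draw M control minor-allele frequencies from the truncated Wright
    distribution by inverse-CDF on the cached grid."""
    params = params or WrightParams()
    rng = np.random.default_rng(rng)
    cdf, grid = _wright_grid(params)
    u = rng.random(M)
    q = np.interp(u, cdf, grid)
    return np.minimum(q, params.q_max)


def par_to_or(par_i: float, maf_u: float) -> float:
    """Attributable-risk inversion: OR = 1 + PAR / (MAF_U * (1 - PAR))."""
    if not 0 <= par_i < 1:
        raise ValueError("PAR must be in [0, 1)")
    if not 0 < maf_u < 1:
        raise ValueError("MAF_U must be in (0, 1)")
    return 1.0 + par_i / (maf_u * (1.0 - par_i))


def case_maf(or_i: float, maf_u: float) -> float:
    """Case-group frequency from the odds scaling
    MAF_A = OR * MAF_U / (1 + MAF_U * (OR - 1))."""
    if or_i <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0 < maf_u < 1:
        raise ValueError("MAF_U must be in (0, 1)")
    return or_i * maf_u / (1.0 + maf_u * (or_i - 1.0))


def _per_variant_pars(scenario: Scenario, rng) -> np.ndarray:
    """PAR for each of the n_risk risk variants (protective mirror these)."""
    k = scenario.n_risk
    if k == 0 or scenario.total_par == 0:
        return np.zeros(k)
    if scenario.par_mode == "equal":
        return np.full(k, scenario.total_par / k)
    raw = rng.random(k)
    return raw / raw.sum() * scenario.total_par


def simulate_truth(scenario: Scenario, rng=None) -> pd.DataFrame:
    """Draw the per-variant ground truth for one replicate: MAF_U, role,
    PAR, OR and MAF_A."""
    rng = np.random.default_rng(rng)
    M = scenario.M
    maf_u = sample_maf_wright(M, scenario.wright, rng)
    roles = np.array(["neutral"] * M, dtype=object)
    n_causal = scenario.n_risk + scenario.n_protective
    if n_causal:
        if M == scenario.n_risk + scenario.n_protective + scenario.n_neutral:
            causal_idx = np.arange(n_causal)
        else:
            rare = np.flatnonzero(maf_u < 0.01)
            if rare.size < n_causal:
                raise ValueError("not enough rare variants to host the "
                                 "causal roles; redraw with another seed")
            causal_idx = rng.choice(rare, size=n_causal, replace=False)
        roles[causal_idx[:scenario.n_risk]] = "risk"
        roles[causal_idx[scenario.n_risk:]] = "protective"
    pars = np.zeros(M)
    risk_pars = _per_variant_pars(scenario, rng)
    pars[roles == "risk"] = risk_pars
    if scenario.n_protective and risk_pars.size:
        # protective variants mirror the risk variants' per-variant PARs
        pars[roles == "protective"] = np.resize(risk_pars,
                                                scenario.n_protective)
    ors = np.ones(M)
    maf_a = maf_u.copy()
    for i in range(M):
        if roles[i] == "risk" and pars[i] > 0:
            ors[i] = par_to_or(pars[i], maf_u[i])
            maf_a[i] = case_maf(ors[i], maf_u[i])
        elif roles[i] == "protective" and pars[i] > 0:
            # PAR attached to the major allele: minor depleted in cases
            f_major = 1.0 - maf_u[i]
            or_major = par_to_or(pars[i], f_major)
            maf_a[i] = 1.0 - case_maf(or_major, f_major)
            ors[i] = (maf_a[i] / (1 - maf_a[i])) / (maf_u[i] / (1 - maf_u[i]))
    return pd.DataFrame({
        "variant_id": [f"V{i + 1:04d}" for i in range(M)],
        "role": roles, "par": pars, "odds_ratio": ors,
        "maf_u": maf_u, "maf_a": maf_a})


def generate_dataset(scenario: Scenario, rng=None, truth=None
                     ) -> GenotypeDataset:
    """Generate one case-control replicate under the scenario.

    Controls draw Binomial(2, MAF_U) genotypes; cases draw
    Binomial(2, MAF_A) per the variant's role.  Pass a ``truth`` frame to
    reuse fixed per-variant parameters across replicates.
    """
    rng = np.random.default_rng(rng)
    if truth is None:
        truth = simulate_truth(scenario, rng)
    maf_u = truth["maf_u"].to_numpy()
    maf_a = truth["maf_a"].to_numpy()
    n1, n2 = scenario.n1, scenario.n2
    cases = rng.binomial(2, maf_a, size=(n1, len(truth)))
    ctrls = rng.binomial(2, maf_u, size=(n2, len(truth)))
    counts = np.vstack([cases, ctrls]).astype(np.int8)
    labels = np.concatenate([np.ones(n1, np.int8), -np.ones(n2, np.int8)])
    return GenotypeDataset(counts, labels, list(truth["variant_id"]))


@dataclass
class PowerResult:
    estimate: float
    rejections: int
    replicates: int
    ci_low: float
    ci_high: float
    alpha: float
    scheme: str


def power_study(scenario: Scenario, scheme="RM",
                svm_config: SvmConfig | None = None, replicates: int = 100,
                B: int = 1000, alpha: float = 0.05, seed: int = 0,
                early_stop: bool = True) -> PowerResult:
    """Empirical rejection rate of the region test over simulated
    replicates, with a 95% Clopper-Pearson interval.

    Under ``total_par = 0`` this estimates the type I error; otherwise the
    power.  ``early_stop`` curtails each replicate's permutations once
    non-rejection is certain (the estimate is unchanged).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if svm_config is None:
        svm_config = SvmConfig()
    scheme_name = scheme if isinstance(scheme, str) else scheme.name
    root = np.random.SeedSequence(seed)
    rej = 0
    for rep_seq in root.spawn(replicates):
        gen_rng, perm_rng = (np.random.default_rng(s)
                             for s in rep_seq.spawn(2))
        data = generate_dataset(scenario, gen_rng)
        if early_stop:
            rejected = region_rejects(data, scheme, svm_config, B, alpha,
                                      perm_rng)
        else:
            res = region_test(data, scheme, svm_config, B,
                              seed=int(perm_rng.integers(2 ** 31)))
            rejected = res.p_value <= alpha
        rej += bool(rejected)
    est = rej / replicates
    lo, hi = _clopper_pearson(rej, replicates)
    return PowerResult(est, rej, replicates, lo, hi, alpha, scheme_name)


def _clopper_pearson(k: int, n: int, level: float = 0.95):
    a = 1 - level
    lo = stats.beta.ppf(a / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)
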