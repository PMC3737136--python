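"""Backward elimination of neutral variants driven by the SVM R^2.

Starting from all (polymorphic, weighted) variants collapsed into the risk
and protective burden covariates, each round refits the SVM with every
remaining variant left out of its covariate in turn.  The removal with the
highest leave-one-out R^2 (ties broken towards the lowest variant index)
is accepted whenever that R^2 is at least the current one; the loop stops
when every removal would lower R^2.  Weights and categories are estimated
once from the full data and never refreshed inside the loop, so a removal
only subtracts the variant's fixed contribution from one covariate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import _backward_select_core
from .data_model import GenotypeDataset, VariantSummary
from .svm_engine import SvmConfig, fit_svm
from .weighting import RISK, collapse


@dataclass
class SelectionTrace:
    """Ordered record of the elimination path."""

    removed: list  # (variant_id, r2 after the removal) in removal order
    retained: list  # variant ids still in the model
    r2_path: list  # initial R^2 followed by each accepted R^2
    r2_final: float
    n_fits: int = 0

    def to_json(self) -> str:
        return json.dumps({"removed": self.removed,
                           "retained": self.retained,
                           "r2_path": self.r2_path,
                           "r2_final": self.r2_final,
                           "n_fits": self.n_fits})

    def to_frame(self) -> pd.DataFrame:
        rows = [(0, None, self.r2_path[0])]
        rows += [(k + 1, vid, r2)
                 for k, (vid, r2) in enumerate(self.removed)]
        return pd.DataFrame(rows, columns=["step", "removed_variant", "r2"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _pattern_arrays(data: GenotypeDataset):
    """Compress individuals into distinct genotype-pattern rows."""
    pat, pat_id = np.unique(data.counts, axis=0, return_inverse=True)
    case = (data.labels == 1).astype(np.float64)
    n_case_p = np.bincount(pat_id, weights=case, minlength=pat.shape[0])
    n_ctrl_p = np.bincount(pat_id, weights=1.0 - case,
                           minlength=pat.shape[0])
    return pat.astype(np.float64), pat_id, n_case_p, n_ctrl_p


def leave_one_out_r2(data: GenotypeDataset, summaries: list[VariantSummary],
                     active_set, variant_i: str,
                     svm_config: SvmConfig | None = None) -> float:
    """R^2 of the model refitted with ``variant_i`` left out of its burden
    covariate (the other covariate is untouched)."""
    if svm_config is None:
        svm_config = SvmConfig()
    active_set = set(active_set)
    if variant_i not in active_set:
        raise ValueError(f"{variant_i!r} is not in the active set")
    reduced = active_set - {variant_i}
    pair = collapse(data, summaries, reduced)  # raises if reduced is empty
    if not pair.s_risk.any() and not pair.s_nonrisk.any():
        raise ValueError("removal leaves both covariates identically zero")
    return fit_svm(pair, data.labels, svm_config).r2


def backward_select(data: GenotypeDataset, summaries: list[VariantSummary],
                    svm_config: SvmConfig | None = None) -> SelectionTrace:
    """Run the full backward elimination and return the trace.

    ``summaries`` must carry weights and categories (see
    :func:`bsvm.weighting.compute_weights`) for exactly the (polymorphic)
    variants of ``data``.  Deterministic: ties go to the lowest variant
    index, and the solver has no random state.
    """
    if svm_config is None:
        svm_config = SvmConfig()
    if data.n_variants < 2:
        raise ValueError("backward selection needs at least 2 variants")
    by_id = {s.variant_id: s for s in summaries}
    if set(by_id) != set(data.variant_ids):
        raise ValueError("summaries do not match the dataset's variants")
    w = np.empty(data.n_variants)
    cat = np.empty(data.n_variants, np.int8)
    for j, vid in enumerate(data.variant_ids):
        s = by_id[vid]
        if s.weight is None or s.category is None:
            raise ValueError(f"variant {vid} has no weight/category")
        w[j] = s.weight
        cat[j] = 1 if s.category == RISK else 0
    pat, _, n_case_p, n_ctrl_p = _pattern_arrays(data)
    r2_final, removed_idx, r2_path, n_fits = _backward_select_core(
        pat, n_case_p, n_ctrl_p, w, cat, data.n1, data.n2,
        svm_config.C, svm_config.resolved_gamma(2), svm_config.standardize,
        svm_config.tol, svm_config.max_iter, svm_config.r2_mode_code)
    removed_ids = [data.variant_ids[i] for i in removed_idx]
    removed = [(vid, float(r2))
               for vid, r2 in zip(removed_ids, r2_path[1:])]
    retained = [v for v in data.variant_ids if v not in set(removed_ids)]
    return SelectionTrace(removed=removed, retained=retained,
                          r2_path=[float(r) for r in r2_path],
                          r2_final=float(r2_final), n_fits=int(n_fits))
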