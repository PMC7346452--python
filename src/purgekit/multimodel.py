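"""AICc multi-model inference: candidate sets, selection, averaging.

Two candidate families are considered, both always containing parity,
season and the polygenic animal effect, and differing in the inbreeding
covariates offered:

* Ballou–Boakes family: subsets of {z.F_D, z.F_L, z.F_A-BL},
* Kalinowski family:    subsets of {z.F_NEWD, z.F_NEWL, z.F_A-KL},

i.e. 2^3 = 8 candidates per family.  Candidates within ΔAICc <= 2 of the
best model are retained, their Akaike weights renormalised, and
coefficients combined with the natural average method: a term is averaged
only over the selected models that contain it, with weights renormalised
among those models; its relative importance (RI) is the summed selected-set
weight of the models containing it, so a term present everywhere has
RI = 1.  Unconditional standard errors follow the standard model-averaging
formula (between-model spread added to within-model variance).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import (
    BALLOU_COVARIATES,
    KALINOWSKI_COVARIATES,
    ModelFit,
    ModelSpec,
    fit_glmm,
)
from .pedigree import Pedigree, a_inverse

__all__ = [
    "CandidateSet",
    "SelectionResult",
    "AveragedEstimate",
    "enumerate_candidates",
    "akaike_weights",
    "select_models",
    "natural_average",
    "average_all_terms",
]

log = logging.getLogger(__name__)

APPROACH_COVARIATES = {
    "ballou_boakes": BALLOU_COVARIATES,
    "kalinowski": KALINOWSKI_COVARIATES,
}


@dataclass(frozen=True)
class CandidateSet:
    """All fitted candidates of one approach (non-convergent ones excluded)."""

    approach: str
    fits: tuple[ModelFit, ...]
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class SelectionResult:
    """Fits within the ΔAICc threshold, with renormalised Akaike weights."""

    fits: tuple[ModelFit, ...]
    delta: np.ndarray
    weights: np.ndarray
    threshold: float = 2.0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [f.label for f in self.fits],
                "AICc": [f.aicc for f in self.fits],
                "weight": self.weights,
                "dAICc": self.delta,
            }
        )


@dataclass(frozen=True)
class AveragedEstimate:
    """Model-averaged coefficient with unconditional CI and importance."""

    term: str
    estimate: float | None
    se: float | None
    ci: tuple[float, float] | None
    ri: float
    n_models: int

    @property
    def significant(self) -> bool:
        """95% CI excludes zero."""
        return self.ci is not None and (self.ci[0] > 0.0 or self.ci[1] < 0.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i ∝ exp(-Δ_i/2) normalised over the supplied set."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one AICc value")
    w = np.exp(-(a - a.min()) / 2.0)
    return w / w.sum()


def enumerate_candidates(
    frame: pd.DataFrame,
    ped: Pedigree,
    approach: str,
    *,
    sigma_a="ml",
    method: str = "laplace",
    response: str = "binomial_counts",
) -> CandidateSet:
    """Fit all 8 covariate subsets of one approach on a prepared frame.

    The inverse-relationship structure over the dams is computed once and
    shared across the candidate fits.  Non-convergent candidates are
    excluded from the returned set (and logged), not penalised.
    """
    covs = APPROACH_COVARIATES[approach]
    dam_structure = a_inverse(ped, sorted(set(frame["dam"])))
    fits, excluded = [], []
    for r in range(len(covs) + 1):
        for subset in itertools.combinations(covs, r):
            spec = ModelSpec(inbreeding_covariates=subset, response=response)
            try:
                f = fit_glmm(frame, ped, spec, sigma_a=sigma_a, method=method,
                             dam_structure=dam_structure)
            except ValueError as err:
                log.warning("candidate %s failed: %s", spec.label, err)
                excluded.append(spec.label)
                continue
            if not f.converged:
                log.warning("candidate %s did not converge; excluded", spec.label)
                excluded.append(spec.label)
                continue
            fits.append(f)
    return CandidateSet(approach=approach, fits=tuple(fits), excluded=tuple(excluded))


def select_models(cands, threshold: float = 2.0) -> SelectionResult:
    """Retain fits with ΔAICc <= threshold; recompute weights over them."""
    fits = list(cands.fits) if isinstance(cands, CandidateSet) else list(cands)
    if not fits:
        raise ValueError("no converged candidate fits to select from")
    aicc = np.array([f.aicc for f in fits])
    delta = aicc - aicc.min()
    keep = delta <= threshold
    fits = [f for f, k in zip(fits, keep) if k]
    delta = delta[keep]
    order = np.argsort(delta, kind="stable")
    fits = [fits[i] for i in order]
    delta = delta[order]
    return SelectionResult(
        fits=tuple(fits), delta=delta, weights=akaike_weights(delta), threshold=threshold
    )


def natural_average(sel: SelectionResult, term: str) -> AveragedEstimate:
    """Natural-average estimate of one term over the selected models.

    RI is computed over the full selected set; the coefficient and its
    unconditional SE are averaged only over models containing the term,
    with weights renormalised among those models.  A term absent from all
    selected models gets RI = 0 and no estimate.
    """
    has = np.array([term in f.coef for f in sel.fits])
    # a term in every selected model has RI exactly 1 by definition
    ri = 1.0 if has.all() else float(sel.weights[has].sum())
    if not has.any():
        return AveragedEstimate(term, None, None, None, ri=0.0, n_models=0)
    w = sel.weights[has] / sel.weights[has].sum()
    beta = np.array([f.coef[term] for f, h in zip(sel.fits, has) if h])
    se = np.array([f.se[term] for f, h in zip(sel.fits, has) if h])
    b_avg = float(w @ beta)
    se_u = float(w @ np.sqrt(se**2 + (beta - b_avg) ** 2))
    ci = (b_avg - 1.96 * se_u, b_avg + 1.96 * se_u)
    return AveragedEstimate(term, b_avg, se_u, ci, ri=ri, n_models=int(has.sum()))


def average_all_terms(sel: SelectionResult) -> pd.DataFrame:
    """Averaged estimates for every term appearing in any selected model."""
    terms: list[str] = []
    for f in sel.fits:
        for t in f.terms:
            if t not in terms:
                terms.append(t)
    rows = []
    for t in terms:
        a = natural_average(sel, t)
        rows.append(
            {
                "term": t,
                "estimate": a.estimate,
                "se": a.se,
                "ci_low": None if a.ci is None else a.ci[0],
                "ci_high": None if a.ci is None else a.ci[1],
                "RI": a.ri,
                "significant": a.significant,
            }
        )
    return pd.DataFrame(rows).set_index("term")
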