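"""Model selection, Akaike weights and natural-average model averaging."""

import numpy as np
import pandas as pd
import pytest

from purgekit import (
    ModelFit,
    SimConfig,
    TrueModel,
    akaike_weights,
    average_all_terms,
    natural_average,
    select_models,
    simulate_study,
)
from purgekit.glmm import prepare_analysis_frame
from purgekit.multimodel import CandidateSet, SelectionResult, enumerate_candidates


def _fake_fit(aicc_val, coef, se=None, label=""):
    se = se or {t: 0.1 for t in coef}
    return ModelFit(
        terms=tuple(coef), coef=dict(coef), se=dict(se), loglik=0.0, k=len(coef),
        n=100, aic=aicc_val, aicc=aicc_val, sigma2_a=0.1, converged=True,
        covariates=(), label=label or "+".join(coef),
    )


# -- Akaike weights ----------------------------------------------------------


def test_akaike_weights_reference_values():
    w = akaike_weights([100.0, 102.0])
    assert np.round(w, 3).tolist() == [0.731, 0.269]
    assert akaike_weights([42.0]).tolist() == [1.0]
    assert akaike_weights([5.0, 5.0]).tolist() == [0.5, 0.5]


def test_akaike_weights_empty_errors():
    with pytest.raises(ValueError):
        akaike_weights([])


# -- selection ---------------------------------------------------------------


def test_select_models_threshold():
    fits = [_fake_fit(a, {"x": 1.0}) for a in (100.0, 101.9, 103.0)]
    sel = select_models(fits)
    assert len(sel.fits) == 2
    assert sel.delta[0] == 0.0
    assert sel.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert sel.weights[0] == sel.weights.max()


def test_select_models_all_tied():
    fits = [_fake_fit(50.0, {"x": float(i)}) for i in range(4)]
    sel = select_models(fits)
    assert len(sel.fits) == 4
    assert np.allclose(sel.weights, 0.25)


# -- natural averaging -------------------------------------------------------


def _selection(weights, fits):
    w = np.asarray(weights, dtype=float)
    return SelectionResult(fits=tuple(fits), delta=np.zeros(len(fits)), weights=w)


def test_natural_average_worked_example():
    """(beta, w) = (0.5, 0.6) and (0.3, 0.2) -> renormalised (0.75, 0.25), 0.45."""
    fits = [
        _fake_fit(0, {"x": 0.5, "base": 1.0}),
        _fake_fit(0, {"base": 1.0}),
        _fake_fit(0, {"x": 0.3, "base": 1.0}),
    ]
    sel = _selection([0.6, 0.2, 0.2], fits)
    a = natural_average(sel, "x")
    assert a.estimate == pytest.approx(0.45)
    assert a.ri == pytest.approx(0.8)
    assert a.n_models == 2


def test_natural_average_single_model_passthrough():
    fits = [_fake_fit(0, {"x": 0.7, "base": 1.0}, se={"x": 0.21, "base": 0.1}),
            _fake_fit(0, {"base": 1.0})]
    sel = _selection([0.4, 0.6], fits)
    a = natural_average(sel, "x")
    assert a.estimate == 0.7
    assert a.se == pytest.approx(0.21)
    assert a.ri == pytest.approx(0.4)


def test_natural_average_absent_term():
    sel = _selection([1.0], [_fake_fit(0, {"base": 1.0})])
    a = natural_average(sel, "ghost")
    assert a.estimate is None and a.ri == 0.0 and a.n_models == 0


def test_natural_average_matches_bruteforce_weighted_sums():
    rng = np.random.default_rng(6)
    for _ in range(20):
        k = rng.integers(2, 6)
        fits, include = [], []
        for i in range(k):
            has = bool(rng.random() < 0.7) or i == 0
            coef = {"base": 1.0}
            if has:
                coef["x"] = float(rng.normal())
            include.append(has)
            fits.append(_fake_fit(0, coef, se={t: float(rng.uniform(0.05, 0.4)) for t in coef}))
        w = rng.dirichlet(np.ones(k))
        sel = _selection(w, fits)
        a = natural_average(sel, "x")
        mask = np.array(include)
        wn = w[mask] / w[mask].sum()
        betas = np.array([f.coef["x"] for f, h in zip(fits, mask) if h])
        ses = np.array([f.se["x"] for f, h in zip(fits, mask) if h])
        bbar = float(wn @ betas)
        assert a.estimate == pytest.approx(bbar, abs=1e-12)
        assert a.se == pytest.approx(float(wn @ np.sqrt(ses**2 + (betas - bbar) ** 2)), abs=1e-12)
        assert a.ri == pytest.approx(float(w[mask].sum()), abs=1e-12)


def test_relative_importance_conventions():
    # a term in every selected model has RI = 1; a term confined to a single
    # model carries exactly that model's weight (0.49/0.31/0.19 pattern)
    w = np.array([0.49, 0.31, 0.19]) / 0.99
    fits = [
        _fake_fit(0, {"Season": -0.2, "z.F_L": 0.1}),
        _fake_fit(0, {"Season": -0.2, "z.F_A-BL": 0.05}),
        _fake_fit(0, {"Season": -0.2}),
    ]
    sel = _selection(w, fits)
    assert natural_average(sel, "Season").ri == pytest.approx(1.0, abs=1e-12)
    assert natural_average(sel, "z.F_A-BL").ri == pytest.approx(w[1], abs=1e-12)
    table = average_all_terms(sel)
    assert set(table.index) == {"Season", "z.F_L", "z.F_A-BL"}
    assert (table["RI"] <= 1).all() and (table["RI"] >= 0).all()


# -- candidate enumeration ---------------------------------------------------


@pytest.fixture(scope="module")
def tiny_study():
    cfg = SimConfig(
        n_founders=24,
        years=8,
        does_recruited_per_year=8,
        bucks_recruited_per_year=3,
        periods=(("1992-12", "2001-12"),),
        coefficient_iterations=2000,
        true_model=TrueModel(sigma2_a=0.2),
        seed=99,
    )
    out = simulate_study(cfg)
    frame = prepare_analysis_frame(out.records, out.coefficients,
                                   period=cfg.periods[0])
    return out, frame


def test_enumerate_candidates_counts_and_null_model(tiny_study):
    out, frame = tiny_study
    cands = enumerate_candidates(frame, out.pedigree, "kalinowski", method="profile")
    assert isinstance(cands, CandidateSet)
    assert len(cands.fits) + len(cands.excluded) == 8
    subsets = {f.covariates for f in cands.fits}
    assert len(subsets) == len(cands.fits)  # no duplicated subsets
    null = [f for f in cands.fits if f.covariates == ()]
    assert null and null[0].label == "Parity + season + animal"
    # the null-subset design has exactly parity + season + intercept terms
    assert set(null[0].terms) == {"Intercept", "Parity A", "Parity B", "Parity C", "Season"}


def test_selection_weights_sum_to_one_on_fits(tiny_study):
    out, frame = tiny_study
    cands = enumerate_candidates(frame, out.pedigree, "ballou_boakes", method="profile")
    sel = select_models(cands)
    assert sel.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert (sel.delta <= 2.0).all()
    assert sel.delta[0] == 0.0
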