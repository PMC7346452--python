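"""Pedigree validation, exact F, A matrix, CGE, founder contributions, Ne."""

import numpy as np
import pandas as pd
import pytest

from purgekit import (
    Pedigree,
    PedigreeError,
    PedigreeRecord,
    add_dummy_progenies,
    complete_generation_equivalent,
    complete_generation_equivalents,
    dummy_id,
    estimate_Ne,
    exact_coefficients,
    founder_contributions,
    inbreeding,
    ne_from_delta_f,
    random_pedigree,
    read_pedigree,
    relationship_matrix,
)
from purgekit.genedrop import drop_once

from conftest import fullsib_line, fullsib_pedigree


# -- reading and validation --------------------------------------------------


def test_read_pedigree_smallest_nonfounder(tmp_path):
    p = tmp_path / "ped.csv"
    p.write_text("id,sire,dam,birth_date,sex\nA,0,0,1992-06,M\nB,0,0,,F\nC,A,B,1995-03-02,\n")
    ped = read_pedigree(p)
    assert set(ped.founders) == {"A", "B"}
    assert ped.topo_order == ("A", "B", "C")
    assert len(ped) == 3
    # month-precision date defaults to mid-month
    assert ped.record("A").birth_date == pd.Timestamp("1992-06-15")


def test_read_pedigree_shuffled_rows_give_identical_pedigree(tmp_path):
    rng = np.random.default_rng(7)
    ped = random_pedigree(rng, n_founders=20, n_nonfounders=80)
    df = ped.to_frame()[["id", "sire", "dam"]].fillna("0")
    sorted_path, shuffled_path = tmp_path / "s.csv", tmp_path / "r.csv"
    df.to_csv(sorted_path, index=False)
    df.sample(frac=1.0, random_state=1).to_csv(shuffled_path, index=False)
    assert read_pedigree(sorted_path) == read_pedigree(shuffled_path)


@pytest.mark.parametrize(
    "rows,match",
    [
        ("C,C,0,,\n", "own parent"),
        ("C,A,B,,\nC,0,0,,\n", "duplicate"),
        ("C,A,Z,,\n", "Z"),
    ],
)
def test_structural_errors(tmp_path, rows, match):
    p = tmp_path / "bad.csv"
    p.write_text("id,sire,dam,birth_date,sex\nA,0,0,,M\nB,0,0,,F\n" + rows)
    with pytest.raises(PedigreeError, match=match):
        read_pedigree(p)


def test_cycle_detected_names_individual():
    with pytest.raises(PedigreeError, match="cycle"):
        Pedigree(
            [
                PedigreeRecord("A", sire="B"),
                PedigreeRecord("B", sire="A"),
            ]
        )


def test_missing_parent_can_be_promoted_to_founder(tmp_path):
    p = tmp_path / "ped.csv"
    p.write_text("id,sire,dam,birth_date,sex\nC,A,B,,\n")
    ped = read_pedigree(p, missing_parents="founder")
    assert set(ped.founders) == {"A", "B"}


# -- dummy progenies ---------------------------------------------------------


def test_dummy_progenies_unique_per_pair(fullsib):
    ped = add_dummy_progenies(fullsib, [("D", "C"), ("D", "C"), ("B", "C")])
    assert len(ped) == len(fullsib) + 2
    assert dummy_id("D", "C") in ped
    # dummies are never founders and never parents
    assert all(not ped.record(i).sex == "dummy" for i in ped.founders)


def test_dummy_progenies_empty_is_noop(fullsib):
    assert add_dummy_progenies(fullsib, []) is fullsib


def test_dummy_progenies_unknown_parent_errors(fullsib):
    with pytest.raises(PedigreeError, match="unknown"):
        add_dummy_progenies(fullsib, [("D", "nope")])


def test_dummy_count_equals_distinct_pairs():
    rng = np.random.default_rng(0)
    does = [f"D{i}" for i in range(30)]
    bucks = [f"S{i}" for i in range(8)]
    ped = Pedigree([PedigreeRecord(i, sex="female") for i in does]
                   + [PedigreeRecord(i, sex="male") for i in bucks])
    matings = [
        (does[rng.integers(30)], bucks[rng.integers(8)]) for _ in range(400)
    ]
    extended = add_dummy_progenies(ped, matings)
    assert len(extended) - len(ped) == len(set(matings))


# -- exact inbreeding --------------------------------------------------------


def test_inbreeding_classic_values(fullsib):
    F = inbreeding(fullsib)
    assert F[["A", "B", "C", "D"]].eq(0).all()
    assert F["X"] == 0.25


def test_inbreeding_matches_enumeration_on_fullsib_line():
    ped = fullsib_line(4)  # 8 non-founders
    F = inbreeding(ped)
    exact = exact_coefficients(ped)["F"]
    assert (F == exact).all()  # both are exact dyadic rationals


# -- relationship matrix -----------------------------------------------------


def test_relationship_matrix_trivial_entries(fullsib):
    A = relationship_matrix(fullsib, ["A", "B", "C", "D", "X"])
    assert np.allclose(np.diag(A)[:4], 1.0)
    assert A.loc["A", "B"] == 0.0
    assert A.loc["A", "C"] == 0.5  # parent-offspring, unrelated parents
    assert A.loc["C", "D"] == 0.5  # full sibs
    assert A.loc["X", "X"] == 1.25


def _kinship_recursive(ped):
    """Independent oracle: top-down memoized kinship recursion."""
    from functools import lru_cache

    sire, dam = ped.sire_idx, ped.dam_idx

    @lru_cache(maxsize=None)
    def phi(i, j):
        if i > j:
            return phi(j, i)
        if i == j:
            s, d = sire[i], dam[i]
            fij = phi(s, d) if (s >= 0 and d >= 0) else 0.0
            return 0.5 * (1.0 + fij)
        # j is never an ancestor of i when i < j (topological order)
        s, d = sire[j], dam[j]
        out = 0.0
        if s >= 0:
            out += 0.5 * phi(i, s)
        if d >= 0:
            out += 0.5 * phi(i, d)
        return out

    n = len(ped)
    return np.array([[2.0 * phi(i, j) for j in range(n)] for i in range(n)])


def test_relationship_matrix_against_recursive_kinship_oracle():
    rng = np.random.default_rng(11)
    ped = random_pedigree(rng, n_founders=10, n_nonfounders=40)
    A = relationship_matrix(ped).to_numpy()
    assert np.allclose(A, _kinship_recursive(ped), atol=1e-12)


def test_diagonal_consistent_with_inbreeding():
    rng = np.random.default_rng(3)
    ped = random_pedigree(rng, n_founders=6, n_nonfounders=30)
    A = relationship_matrix(ped)
    F = inbreeding(ped)
    assert np.allclose(np.diag(A) - 1.0, F.to_numpy(), atol=1e-12)


def test_relationship_matrix_missing_subset_id_errors(fullsib):
    with pytest.raises(KeyError):
        relationship_matrix(fullsib, ["A", "nope"])


# -- complete generation equivalents -----------------------------------------


def test_cge_reference_values():
    # both parents known founders -> 1; fully known depth 3 -> 3
    ped = fullsib_line(3)
    cge = complete_generation_equivalents(ped)
    assert cge["G1a"] == 1.0
    assert cge["G3a"] == 3.0
    assert cge["G0a"] == 0.0  # founders


def test_cge_one_known_grandparent():
    ped = Pedigree(
        [
            PedigreeRecord("GS"),
            PedigreeRecord("S", sire="GS"),
            PedigreeRecord("D"),
            PedigreeRecord("X", sire="S", dam="D"),
        ]
    )
    # 2*(1/2) for the parents + 1*(1/4) for the single known grandparent
    assert complete_generation_equivalent(ped, "X") == 1.25


def test_cge_monotone_when_ancestors_added():
    base = Pedigree(
        [PedigreeRecord("S"), PedigreeRecord("D"), PedigreeRecord("X", sire="S", dam="D")]
    )
    deeper = Pedigree(
        [
            PedigreeRecord("GS"),
            PedigreeRecord("GD"),
            PedigreeRecord("S", sire="GS", dam="GD"),
            PedigreeRecord("D"),
            PedigreeRecord("X", sire="S", dam="D"),
        ]
    )
    assert complete_generation_equivalent(deeper, "X") > complete_generation_equivalent(
        base, "X"
    )


# -- founder contributions ---------------------------------------------------


def test_founder_contributions_trivial(fullsib):
    c = founder_contributions(fullsib, ["C"])
    assert c["A"] == 0.5 and c["B"] == 0.5
    both = founder_contributions(fullsib, ["A", "B"])
    assert np.allclose(both, 0.5)  # founders themselves: 1/|founders| each


def test_founder_contributions_sum_to_one_when_fully_pedigreed():
    rng = np.random.default_rng(5)
    ped = random_pedigree(rng, n_founders=8, n_nonfounders=40)
    cohort = list(ped.ids)[-10:]
    assert founder_contributions(ped, cohort).sum() == pytest.approx(1.0, abs=1e-9)


def test_founder_contributions_match_genedrop_allele_frequencies():
    rng = np.random.default_rng(17)
    ped = random_pedigree(rng, n_founders=5, n_nonfounders=12)
    target = list(ped.ids)[-1]
    expected = founder_contributions(ped, [target])
    # oracle: frequency of each founder's alleles among the target's copies.
    # Fresh labels are assigned in pedigree order, one per unknown-parent
    # slot, so the label -> founder map can be replayed deterministically.
    label_owner = {}
    nxt = 0
    for k, rec in enumerate(ped.records):
        for p in (ped.sire_idx[k], ped.dam_idx[k]):
            if p < 0:
                label_owner[nxt] = rec.id
                nxt += 1
    reps = 4000
    counts = {f: 0 for f in ped.founders}
    k = ped.index(target)
    for _ in range(reps):
        lab, _ = drop_once(ped, rng)
        for side in range(2):
            counts[label_owner[lab[k, side]]] += 1
    for f in ped.founders:
        freq = counts[f] / (2 * reps)
        se = np.sqrt(max(expected[f] * (1 - expected[f]), 1e-12) / (2 * reps))
        assert abs(freq - expected[f]) <= max(3 * se, 1e-9)


# -- effective population size -----------------------------------------------


def test_ne_from_delta_f_rounding():
    assert ne_from_delta_f(0.005).ne == 100
    with pytest.raises(ValueError):
        ne_from_delta_f(0.0)


def test_estimate_ne_regression_needs_two_generations(fullsib):
    founders_only = Pedigree([PedigreeRecord("A"), PedigreeRecord("B")])
    with pytest.raises(ValueError, match="distinct"):
        estimate_Ne(founders_only)


def test_estimate_ne_both_methods_positive_on_inbred_line():
    ped = fullsib_line(6)
    reg = estimate_Ne(ped, method="regression_logF")
    ind = estimate_Ne(ped, method="individual_deltaF")
    for est in (reg, ind):
        assert 0 < est.delta_f < 1
        assert est.ne == round(1 / (2 * est.delta_f))
    # repeated full-sib mating has ΔF ~ 0.19/generation, i.e. Ne ~ 2.6
    assert 1 <= reg.ne <= 4


def test_estimate_ne_independent_of_calendar_scale():
    """ΔF is per equivalent generation: shifting all dates leaves Ne alone."""
    recs = []
    date = pd.Timestamp("2000-01-01")
    for g, tag in enumerate(["G0a", "G0b"]):
        recs.append(PedigreeRecord(tag, birth_date=date, sex="male" if tag.endswith("a") else "female"))
    for g in range(1, 6):
        for tag, sex in (("a", "male"), ("b", "female")):
            recs.append(
                PedigreeRecord(
                    f"G{g}{tag}", sire=f"G{g-1}a", dam=f"G{g-1}b",
                    birth_date=date + pd.DateOffset(years=g), sex=sex,
                )
            )
    ped = Pedigree(recs)
    shifted = Pedigree(
        [
            PedigreeRecord(
                r.id, r.sire, r.dam,
                None if r.birth_date is None else r.birth_date + pd.DateOffset(years=10),
                r.sex,
            )
            for r in recs
        ]
    )
    a = estimate_Ne(ped, ("2000-01-01", "2010-01-01"))
    b = estimate_Ne(shifted, ("2010-01-01", "2020-01-01"))
    assert a.delta_f == pytest.approx(b.delta_f, rel=1e-12)
    assert a.ne == b.ne
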