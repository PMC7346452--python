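"""Monte-Carlo gene dropping for classical and ancestral inbreeding.

Gene dropping transmits uniquely labelled founder alleles down the
pedigree, one unlinked locus per replicate, and turns identity questions
into replicate frequencies:

* ``F``      — probability the individual's two alleles are copies of the
               same founder allele (autozygosity),
* ``F_ab``   — Ballou's ancestral inbreeding: probability a random allele
               of the individual has already been part of an autozygous
               ancestor genotype,
* ``F_ak``   — Kalinowski's ancestral inbreeding: probability the
               individual is autozygous *and* the involved allele has been
               autozygous before in an ancestor,
* ``F_new``  — Kalinowski's new inbreeding, autozygosity happening for the
               first time; by construction ``F = F_new + F_ak`` holds as an
               identity on every run.

Each transmitted allele copy carries an "ancestrally autozygous" flag set
when the transmitting parent was itself autozygous at the locus (or the
copy was already flagged); flags are therefore monotone down the pedigree
and exclude the individual's own, first-time autozygosity.

An exact enumeration oracle over all 4^m transmission outcomes (m
non-founders) provides ground truth for small pedigrees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator

from .pedigree import Pedigree

__all__ = [
    "GeneDropping",
    "estimate_coefficients",
    "exact_coefficients",
    "drop_once",
    "COEFFICIENT_COLUMNS",
]

#: default replicate count (full-study precision) and master seed
DEFAULT_ITERATIONS = 1_000_000
DEFAULT_SEED = 20200708

COEFFICIENT_COLUMNS = ["F", "F_new", "F_ak", "F_ab"]


@njit(cache=True)
def _drop_counts(sire, dam, n_iter, seed):  # pragma: no cover - via wrapper
    n = sire.size
    np.random.seed(seed)
    auto = np.zeros(n, np.int64)          # replicates autozygous
    flagged = np.zeros(n, np.int64)       # flagged copies over replicates
    auto_flagged = np.zeros(n, np.int64)  # flagged copies while autozygous
    lab = np.empty((n, 2), np.int64)
    flg = np.empty((n, 2), np.uint8)
    for _ in range(n_iter):
        nxt = 0
        for i in range(n):
            for side in range(2):
                p = sire[i] if side == 0 else dam[i]
                if p < 0:
                    # unknown parent slot = fresh allele from a phantom founder
                    lab[i, side] = nxt
                    nxt += 1
                    flg[i, side] = 0
                else:
                    c = 0 if np.random.random() < 0.5 else 1
                    lab[i, side] = lab[p, c]
                    parent_auto = lab[p, 0] == lab[p, 1]
                    flg[i, side] = 1 if (flg[p, c] == 1 or parent_auto) else 0
            nf = flg[i, 0] + flg[i, 1]
            flagged[i] += nf
            if lab[i, 0] == lab[i, 1]:
                auto[i] += 1
                auto_flagged[i] += nf
    return auto, flagged, auto_flagged


@njit(cache=True)
def _enum_counts(sire, dam, nonf):  # pragma: no cover - via wrapper
    n = sire.size
    m = nonf.size
    total = np.int64(1) << np.int64(2 * m)
    auto = np.zeros(n, np.int64)
    flagged = np.zeros(n, np.int64)
    auto_flagged = np.zeros(n, np.int64)
    lab = np.empty((n, 2), np.int64)
    flg = np.empty((n, 2), np.uint8)
    choice = np.empty(n, np.int64)  # two choice bits per non-founder
    for outcome in range(total):
        bits = outcome
        for k in range(m):
            choice[nonf[k]] = bits & 3
            bits >>= 2
        nxt = 0
        for i in range(n):
            for side in range(2):
                p = sire[i] if side == 0 else dam[i]
                if p < 0:
                    lab[i, side] = nxt
                    nxt += 1
                    flg[i, side] = 0
                else:
                    c = (choice[i] >> side) & 1
                    lab[i, side] = lab[p, c]
                    parent_auto = lab[p, 0] == lab[p, 1]
                    flg[i, side] = 1 if (flg[p, c] == 1 or parent_auto) else 0
            nf = flg[i, 0] + flg[i, 1]
            flagged[i] += nf
            if lab[i, 0] == lab[i, 1]:
                auto[i] += 1
                auto_flagged[i] += nf
    return auto, flagged, auto_flagged, total


def _coefficient_frame(ids, auto, flagged, auto_flagged, denom, n_iter, store_se):
    # F_new and F_ak are defined from the same replicate counts so that the
    # decomposition F = F_new + F_ak is an identity, not an approximation.
    two_r = 2.0 * denom
    f_ak = auto_flagged / two_r
    f_new = (2 * auto - auto_flagged) / two_r
    f = f_new + f_ak
    f_ab = flagged / two_r
    out = pd.DataFrame(
        {"F": f, "F_new": f_new, "F_ak": f_ak, "F_ab": f_ab}, index=list(ids)
    )
    if store_se:
        for col in COEFFICIENT_COLUMNS:
            p = out[col].to_numpy()
            out[f"se_{col}"] = np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / n_iter)
    return out


class GeneDropping(BaseEstimator):
    """Monte-Carlo gene-dropping estimator of inbreeding coefficients.

    Parameters
    ----------
    n_iterations
        Replicates (unlinked loci) to simulate; the package default of
        10^6 gives binomial standard errors below 5e-4 on any coefficient.
    seed
        Master seed of the replicate stream; identical seed + iterations
        give a bit-identical coefficient table.
    store_se
        Also store the binomial Monte-Carlo standard errors
        sqrt(p(1-p)/n_iterations) per coefficient.

    Attributes
    ----------
    coefficients_ : pandas.DataFrame
        One row per individual (pedigree order) with columns F, F_new,
        F_ak, F_ab and, optionally, se_F ... se_F_ab.
    n_individuals_ : int
    """

    def __init__(self, n_iterations: int = DEFAULT_ITERATIONS, seed: int = DEFAULT_SEED,
                 store_se: bool = True):
        self.n_iterations = n_iterations
        self.seed = seed
        self.store_se = store_se

    def fit(self, pedigree: Pedigree, y=None):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        auto, flagged, auto_flagged = _drop_counts(
            pedigree.sire_idx, pedigree.dam_idx,
            int(self.n_iterations), int(self.seed) % (2**32),
        )
        self.coefficients_ = _coefficient_frame(
            pedigree.ids, auto, flagged, auto_flagged,
            self.n_iterations, self.n_iterations, self.store_se,
        )
        self.n_individuals_ = len(pedigree)
        return self

    def fit_transform(self, pedigree: Pedigree, y=None) -> pd.DataFrame:
        return self.fit(pedigree).coefficients_


def estimate_coefficients(
    ped: Pedigree,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = DEFAULT_SEED,
    store_se: bool = True,
) -> pd.DataFrame:
    """Functional wrapper over :class:`GeneDropping`."""
    return GeneDropping(n_iterations, seed, store_se).fit_transform(ped)


def exact_coefficients(ped: Pedigree, max_nonfounders: int = 10) -> pd.DataFrame:
    """Exact coefficients by enumerating all 4^m transmission outcomes.

    Applies the same flag semantics as the Monte-Carlo kernel with equal
    weight 4^-m per outcome; standard errors are exactly zero.  Refuses
    pedigrees with more than ``max_nonfounders`` non-founders (the outcome
    space grows as 4^m).
    """
    nonf = np.flatnonzero((ped.sire_idx >= 0) | (ped.dam_idx >= 0)).astype(np.int64)
    if nonf.size > max_nonfounders:
        raise ValueError(
            f"exact enumeration refused: {nonf.size} non-founders exceeds the "
            f"cap of {max_nonfounders} (4^m outcomes)"
        )
    auto, flagged, auto_flagged, total = _enum_counts(ped.sire_idx, ped.dam_idx, nonf)
    out = _coefficient_frame(ped.ids, auto, flagged, auto_flagged, total, 1, False)
    for col in COEFFICIENT_COLUMNS:
        out[f"se_{col}"] = 0.0
    return out


def drop_once(ped: Pedigree, rng: np.random.Generator):
    """One gene-dropping replicate, returned in full for inspection.

    Returns ``(labels, flags)``: integer founder-allele labels and
    ancestral-autozygosity flags, both of shape (n, 2) in pedigree order.
    Founders (and phantom parents) receive fresh unique labels with clear
    flags; a transmitted copy is flagged if the parental copy was flagged
    or the parent was autozygous at the locus.
    """
    n = len(ped)
    lab = np.empty((n, 2), dtype=np.int64)
    flg = np.zeros((n, 2), dtype=bool)
    nxt = 0
    for i in range(n):
        for side, p in enumerate((ped.sire_idx[i], ped.dam_idx[i])):
            if p < 0:
                lab[i, side] = nxt
                nxt += 1
            else:
                c = int(rng.integers(0, 2))
                lab[i, side] = lab[p, c]
                flg[i, side] = bool(flg[p, c]) or (lab[p, 0] == lab[p, 1])
    return lab, flg
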