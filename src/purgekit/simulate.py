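"""Synthetic closed rabbit populations with known survival genetics.

The real study population (a closed, long-term selected meat-rabbit herd)
is not publicly deposited, so this module generates pedigrees and kindling
records with the statistical structure the analysis assumes:

* a closed population founded once, with overlapping generations, yearly
  doe/buck recruitment, no immigration, and optional truncation selection
  on a neutral index (which accelerates the loss of founder contributions),
* kindling records (dam, sire, date, parity, litter size) whose survival
  outcome is drawn from a known binomial-logit model with season, parity
  class, standardised inbreeding covariates and a polygenic dam effect
  a ~ N(0, sigma2_a * A) sampled exactly along the pedigree via Mendelian
  sampling.

Because the data-generating model is the same binomial logit the analysis
estimates, simulated datasets provide ground truth for end-to-end
parameter-recovery checks.  Default sizes are the study's order of
magnitude scaled down ten-fold (~140 bucks, ~530 does, ~2,200 kindlings
over 25 years) so a full study runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genedrop import estimate_coefficients
from .glmm import prepare_analysis_frame
from .pedigree import (
    Pedigree,
    PedigreeRecord,
    add_dummy_progenies,
    dummy_id,
    inbreeding,
)

__all__ = [
    "TrueModel",
    "SimConfig",
    "SimOutput",
    "simulate_pedigree",
    "simulate_kindlings",
    "simulate_study",
    "first_period_scenario",
    "random_pedigree",
    "DEFAULT_PERIODS",
]

#: the three analysis periods of the study design (month precision)
DEFAULT_PERIODS = (
    ("1992-12", "1997-08"),
    ("1997-09", "2007-10"),
    ("2007-11", "2017-11"),
)

_START_YEAR = 1992


@dataclass(frozen=True)
class TrueModel:
    """True fixed and random effects of the survival logit model.

    Coefficients of the z-standardised inbreeding covariates live in
    ``covariate_effects`` keyed by covariate name (any family).  Defaults
    encode a first-period-like purging pattern: strong depression through
    new litter inbreeding and a positive ancestral (Kalinowski) effect,
    with the season/parity/intercept magnitudes the study reports.
    """

    intercept: float = 3.2
    beta_season: float = -0.25
    beta_parity: tuple[float, float, float] = (0.20, 0.31, 0.37)  # A, B, C
    covariate_effects: dict = field(
        default_factory=lambda: {"z.F_NEWL": -0.4, "z.F_A-KL": 0.3}
    )
    sigma2_a: float = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Closed-population scenario definition (all counts per calendar year)."""

    n_founders: int = 54
    founder_doe_fraction: float = 0.78
    years: int = 25
    does_recruited_per_year: int = 21
    bucks_recruited_per_year: int = 6
    breeding_years: int = 2  # buck service life (fixed)
    max_doe_years: int = 6  # longevity cap for does
    litters_per_doe_year: float = 2.5
    mean_litter_size: float = 9.0
    #: yearly probability a doe is culled after her breeding year; stochastic
    #: retention gives a realistic longevity tail (some does reach parity 11+)
    #: while keeping the mean productive life at 1/replacement_fraction years
    replacement_fraction: float = 0.5
    mating_scheme: str = "random"  # random | circular | within_line
    n_lines: int = 4
    selection_on_index: bool = True
    true_model: TrueModel = field(default_factory=TrueModel)
    periods: tuple = DEFAULT_PERIODS
    coefficient_iterations: int = 5000
    standardisation: str = "z_1sd"
    seed: int = 20200708

    def __post_init__(self):
        if min(self.n_founders, self.breeding_years) < 1 or self.years < 0:
            raise ValueError("population counts must be positive")
        if self.mean_litter_size < 1:
            raise ValueError("mean_litter_size must be >= 1")
        if self.true_model.sigma2_a < 0:
            raise ValueError("sigma2_a must be >= 0")
        if self.mating_scheme not in {"random", "circular", "within_line"}:
            raise ValueError(f"unknown mating scheme {self.mating_scheme!r}")


@dataclass(frozen=True)
class SimOutput:
    """A simulated study: extended pedigree, outcome records, truth tables."""

    pedigree: Pedigree  # breeders + litter dummies
    records: pd.DataFrame  # kindlings with covariates and n_alive
    coefficients: pd.DataFrame  # per-individual gene-dropping coefficients
    polygenic: pd.Series  # true additive values per individual
    true_model: TrueModel
    config: SimConfig


def first_period_scenario(seed: int = 1, **overrides) -> SimConfig:
    """Single-period scenario sized to ~5,000 kindlings.

    Emulates the study's first analysis window as one standardisation
    period, at the scale used by the parameter-recovery checks.
    """
    cfg = SimConfig(
        n_founders=80,
        years=15,
        does_recruited_per_year=71,
        bucks_recruited_per_year=18,
        periods=(("1992-12", "2008-12"),),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# -- population dynamics -----------------------------------------------------


def _simulate_population(cfg: SimConfig, rng: np.random.Generator):
    """Breed the closed population; returns (pedigree records, kindling events)."""
    n_does = int(round(cfg.n_founders * cfg.founder_doe_fraction))
    n_bucks = cfg.n_founders - n_does
    if cfg.years > 0 and min(n_does, n_bucks) == 0:
        raise RuntimeError("population extinct in year 0: no founder of one sex")

    records: list[PedigreeRecord] = []
    index: dict[str, float] = {}
    line: dict[str, int] = {}
    founder_date = pd.Timestamp(_START_YEAR, 6, 15)
    does: list[dict] = []  # active herd state
    bucks: list[dict] = []
    for k in range(n_does):
        i = f"FD{k:03d}"
        records.append(PedigreeRecord(i, birth_date=founder_date, sex="female"))
        index[i] = float(rng.normal())
        line[i] = k % cfg.n_lines
        does.append({"id": i, "born": 0, "parity": 0})
    for k in range(n_bucks):
        i = f"FB{k:03d}"
        records.append(PedigreeRecord(i, birth_date=founder_date, sex="male"))
        index[i] = float(rng.normal())
        line[i] = k % cfg.n_lines
        bucks.append({"id": i, "born": 0})

    events = []
    for year in range(1, cfg.years + 1):
        # does: stochastic culling after each breeding year, capped longevity
        kept = []
        for d in does:
            age = year - d["born"]
            if age > cfg.max_doe_years:
                continue
            if age > 1 and rng.random() < cfg.replacement_fraction:
                continue
            kept.append(d)
        does = kept
        bucks = [b for b in bucks if year - b["born"] <= cfg.breeding_years]
        if not does or not bucks:
            raise RuntimeError(f"population extinct in year {year}: no eligible mates")
        buck_ids = [b["id"] for b in bucks]
        year_events = []
        for k, doe in enumerate(does):
            n_lit = rng.poisson(cfg.litters_per_doe_year)
            for _ in range(n_lit):
                if cfg.mating_scheme == "circular":
                    sire = buck_ids[(k + year) % len(buck_ids)]
                elif cfg.mating_scheme == "within_line":
                    same = [b for b in buck_ids if line[b] == line[doe["id"]]]
                    sire = (same[int(rng.integers(len(same)))] if same
                            else buck_ids[int(rng.integers(len(buck_ids)))])
                else:
                    sire = buck_ids[int(rng.integers(len(buck_ids)))]
                doe["parity"] += 1
                date = pd.Timestamp(
                    _START_YEAR + year,
                    int(rng.integers(1, 13)),
                    int(rng.integers(1, 29)),
                )
                n_total = 1 + int(rng.poisson(cfg.mean_litter_size - 1.0))
                ev = {
                    "dam": doe["id"],
                    "sire": sire,
                    "kindling_date": date,
                    "parity": doe["parity"],
                    "n_total": n_total,
                }
                events.append(ev)
                year_events.append(ev)

        # recruit next year's breeders from this year's kits
        if year < cfg.years and year_events:
            for sex, count in (("female", cfg.does_recruited_per_year),
                               ("male", cfg.bucks_recruited_per_year)):
                weights = np.array([e["n_total"] for e in year_events], dtype=float)
                pool = rng.choice(
                    len(year_events), size=max(3 * count, count), replace=True,
                    p=weights / weights.sum(),
                )
                kit_index = np.array(
                    [
                        0.5 * (index[year_events[j]["dam"]] + index[year_events[j]["sire"]])
                        + rng.normal()
                        for j in pool
                    ]
                )
                chosen = pool[np.argsort(-kit_index)[:count]] if cfg.selection_on_index \
                    else pool[:count]
                for k, j in enumerate(chosen):
                    ev = year_events[int(j)]
                    prefix = "D" if sex == "female" else "B"
                    i = f"{prefix}{year:02d}_{k:03d}"
                    records.append(
                        PedigreeRecord(
                            i, sire=ev["sire"], dam=ev["dam"],
                            birth_date=ev["kindling_date"], sex=sex,
                        )
                    )
                    index[i] = 0.5 * (index[ev["dam"]] + index[ev["sire"]]) + float(rng.normal())
                    line[i] = line[ev["sire"]]
                    if sex == "female":
                        does.append({"id": i, "born": year, "parity": 0})
                    else:
                        bucks.append({"id": i, "born": year})
    return records, events


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Breeder pedigree of the simulated closed population (no dummies)."""
    rng = np.random.default_rng(cfg.seed)
    records, _ = _simulate_population(cfg, rng)
    return Pedigree(records)


def _sample_polygenic(ped: Pedigree, sigma2: float, rng: np.random.Generator) -> pd.Series:
    """Exact draw of a ~ N(0, sigma2*A) by Mendelian sampling down the pedigree."""
    F = inbreeding(ped).to_numpy()
    a = np.zeros(len(ped))
    for i in range(len(ped)):
        s, d = int(ped.sire_idx[i]), int(ped.dam_idx[i])
        if s >= 0 and d >= 0:
            mean = 0.5 * (a[s] + a[d])
            var = sigma2 * (0.5 - 0.25 * (F[s] + F[d]))
        elif s >= 0 or d >= 0:
            mean = 0.5 * a[max(s, d)]
            var = sigma2 * (0.75 - 0.25 * F[max(s, d)])
        else:
            mean, var = 0.0, sigma2
        a[i] = mean + rng.normal() * np.sqrt(var)
    return pd.Series(a, index=list(ped.ids), name="polygenic")


def simulate_kindlings(
    ped: Pedigree,
    events: pd.DataFrame,
    coefficients: pd.DataFrame,
    true_model: TrueModel,
    rng: np.random.Generator,
    *,
    periods=DEFAULT_PERIODS,
    standardisation: str = "z_1sd",
    polygenic: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw binomial survival outcomes for kindling events.

    Covariates are standardised within the supplied periods exactly as in
    the analysis pipeline, so the true coefficients are on the reported
    scale.  A covariate with zero variance in a period (e.g. ancestral
    inbreeding before any autozygosity has occurred) contributes nothing
    there.  Returns the records with outcomes plus the sampled polygenic
    values.
    """
    frames = [
        prepare_analysis_frame(events, coefficients, period=p,
                               standardisation=standardisation)
        for p in periods
    ]
    frame = pd.concat([f for f in frames if not f.empty]).sort_values(
        ["kindling_date", "dam", "parity"], kind="stable"
    ).reset_index(drop=True)

    if polygenic is None:
        polygenic = _sample_polygenic(ped, true_model.sigma2_a, rng)
    eta = np.full(len(frame), true_model.intercept)
    eta += true_model.beta_season * (frame["season"] == "summer").to_numpy(float)
    for lvl, b in zip(("P2", "P3_10", "P11plus"), true_model.beta_parity):
        eta += b * (frame["parity_class"] == lvl).to_numpy(float)
    for cov, b in true_model.covariate_effects.items():
        eta += b * np.nan_to_num(frame[cov].to_numpy(float))
    eta += polygenic.reindex(frame["dam"]).to_numpy()
    p_surv = 1.0 / (1.0 + np.exp(-eta))
    frame["n_alive"] = rng.binomial(frame["n_total"].to_numpy(int), p_surv)
    return frame, polygenic


def simulate_study(cfg: SimConfig) -> SimOutput:
    """Full synthetic study: pedigree, dummies, coefficients, outcomes."""
    rng = np.random.default_rng(cfg.seed)
    records, events = _simulate_population(cfg, rng)
    ped = Pedigree(records)
    events = pd.DataFrame(events)
    if len(events):
        events["litter_dummy"] = [
            dummy_id(d, s) for d, s in zip(events["dam"], events["sire"])
        ]
        ped = add_dummy_progenies(ped, zip(events["dam"], events["sire"]))
        coeffs = estimate_coefficients(
            ped,
            n_iterations=cfg.coefficient_iterations,
            seed=(cfg.seed * 7919 + 13) % (2**31),
        )
        recs, poly = simulate_kindlings(
            ped, events, coeffs, cfg.true_model, rng,
            periods=cfg.periods, standardisation=cfg.standardisation,
        )
    else:
        coeffs = estimate_coefficients(ped, n_iterations=1, seed=cfg.seed)
        recs = events
        poly = _sample_polygenic(ped, cfg.true_model.sigma2_a, rng)
    return SimOutput(
        pedigree=ped, records=recs, coefficients=coeffs,
        polygenic=poly, true_model=cfg.true_model, config=cfg,
    )


# -- small random pedigrees (oracle fodder) ----------------------------------


def random_pedigree(
    rng: np.random.Generator, n_founders: int = 4, n_nonfounders: int = 6
) -> Pedigree:
    """A random small pedigree: each non-founder picks two distinct earlier
    individuals as parents (sexes left unrecorded).  Useful as input to the
    exact-enumeration oracle."""
    ids = [f"P{k}" for k in range(n_founders + n_nonfounders)]
    records = [PedigreeRecord(i) for i in ids[:n_founders]]
    for k in range(n_founders, n_founders + n_nonfounders):
        a, b = rng.choice(k, size=2, replace=False)
        records.append(PedigreeRecord(ids[k], sire=ids[int(a)], dam=ids[int(b)]))
    return Pedigree(records)
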