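"""Study orchestration: periods, coefficients, dual-family model averaging.

``run_study`` executes the whole analysis on a pedigree + kindling-record
pair (from files or in-memory objects):

1. validate the pedigree and append litter dummies for every unique
   (dam, sire) mating pair,
2. estimate F, F_NEW, F_A-K, F_A-B by gene dropping,
3. split records into consecutive periods (month precision) and
   z-standardise the inbreeding covariates within each period,
4. fit all 8 candidates of both covariate families per period, select by
   ΔAICc <= 2, and average with the natural-average method,
5. assemble descriptive tables (coefficient summaries per role, Pearson
   correlations, Ne per period, founder-contribution trend).

Everything is deterministic given the configuration seed, and every table
in the report is written as CSV when an output directory is configured.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genedrop import COEFFICIENT_COLUMNS, estimate_coefficients
from .glmm import _period_bounds, prepare_analysis_frame
from .multimodel import average_all_terms, enumerate_candidates, select_models
from .pedigree import (
    Pedigree,
    add_dummy_progenies,
    complete_generation_equivalents,
    dummy_id,
    estimate_Ne,
    founder_contributions,
    read_pedigree,
)
from .simulate import DEFAULT_PERIODS

__all__ = ["StudyConfig", "StudyReport", "run_study", "correlation_report"]

log = logging.getLogger(__name__)

APPROACHES = ("ballou_boakes", "kalinowski")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full study run."""

    pedigree: object = None  # path or Pedigree
    records: object = None  # path or DataFrame
    periods: tuple = DEFAULT_PERIODS
    iterations: int = 100_000
    seed: int = 20200708
    standardisation: str = "z_1sd"
    selection_threshold: float = 2.0
    ne_method: str = "regression_logF"
    glmm_method: str = "profile"  # batch-appropriate; "laplace" refines each fit
    response: str = "binomial_counts"
    out_dir: object = None

    def __post_init__(self):
        starts = [pd.Timestamp(str(p[0])) for p in self.periods]
        ends = [_period_bounds(p)[1] for p in self.periods]
        for k in range(len(self.periods) - 1):
            if not (starts[k] <= ends[k] < starts[k + 1]):
                raise ValueError("periods must be ordered and non-overlapping")


@dataclass(frozen=True)
class StudyReport:
    """All tables produced by one study run."""

    descriptives: pd.DataFrame
    correlations: dict  # role -> DataFrame
    ne: pd.DataFrame
    founder_trend: pd.DataFrame
    selection: dict  # (period index, approach) -> DataFrame
    averaged: dict  # (period index, approach) -> DataFrame
    coefficients: pd.DataFrame
    manifest: dict


def correlation_report(coefficients: pd.DataFrame, roles: dict) -> dict:
    """Pearson correlations among {F, F_new, F_ak, F_ab} within each role.

    ``roles`` maps a role name (e.g. "dam", "litter") to the ids it
    covers.  Zero-variance coefficients yield undefined (NaN) cells; fewer
    than 3 individuals in a role raises.
    """
    out = {}
    for role, ids in roles.items():
        ids = [i for i in ids if i in coefficients.index]
        if len(ids) < 3:
            raise ValueError(f"role {role!r} needs at least 3 individuals")
        sub = coefficients.loc[ids, COEFFICIENT_COLUMNS]
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = sub.corr(method="pearson")
        # a zero-variance column correlates with nothing (self-correlation
        # is kept at 1 by convention)
        for c in COEFFICIENT_COLUMNS:
            if sub[c].nunique() < 2:
                corr.loc[c, :] = np.nan
                corr.loc[:, c] = np.nan
        np.fill_diagonal(corr.values, 1.0)
        out[role] = corr
    return out


def _descriptives(coefficients: pd.DataFrame, cge: pd.Series, roles: dict) -> pd.DataFrame:
    rows = []
    for role, ids in roles.items():
        suffix = "L" if role == "litter" else "D"
        ids = list(ids)
        for col, label in zip(COEFFICIENT_COLUMNS, ("F_", "F_NEW", "F_A-K", "F_A-B")):
            v = coefficients.loc[ids, col]
            rows.append(
                {
                    "parameter": f"{label}{suffix}",  # F_L, F_NEWL, F_A-KL ...
                    "mean": v.mean(),
                    "median": v.median(),
                    "sd": v.std(ddof=1),
                    "max": v.max(),
                }
            )
        v = cge.loc[ids]
        rows.append(
            {"parameter": f"CGE_{suffix}", "mean": v.mean(), "median": v.median(),
             "sd": v.std(ddof=1), "max": v.max()}
        )
    return pd.DataFrame(rows).set_index("parameter")


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the full pipeline; see the module docstring for the stages."""
    t0 = time.time()

    # --- stage: read -------------------------------------------------------
    ped = cfg.pedigree if isinstance(cfg.pedigree, Pedigree) else read_pedigree(cfg.pedigree)
    records = (
        cfg.records.copy()
        if isinstance(cfg.records, pd.DataFrame)
        else pd.read_csv(cfg.records)
    )
    records["kindling_date"] = pd.to_datetime(records["kindling_date"])
    log.info("read stage: %d pedigree rows, %d kindling records", len(ped), len(records))

    # --- stage: dummy progenies -------------------------------------------
    pairs = set(zip(records["dam"], records["sire"]))
    existing = {i for i in ped.ids}
    new_pairs = [p for p in pairs if dummy_id(*p) not in existing]
    if new_pairs:
        ped = add_dummy_progenies(ped, new_pairs)
    records["litter_dummy"] = [dummy_id(d, s) for d, s in zip(records["dam"], records["sire"])]

    # --- stage: gene dropping ---------------------------------------------
    coeffs = estimate_coefficients(ped, n_iterations=cfg.iterations, seed=cfg.seed)
    cge = complete_generation_equivalents(ped)
    log.info("gene dropping: %d individuals x %d iterations", len(ped), cfg.iterations)

    dams = sorted(set(records["dam"]))
    litters = sorted(set(records["litter_dummy"]))
    roles = {"dam": dams, "litter": litters}
    descriptives = _descriptives(coeffs, cge, roles)
    correlations = correlation_report(coeffs, roles)

    # --- stage: Ne and founder contributions -------------------------------
    ne_rows = []
    whole = (str(cfg.periods[0][0]), str(cfg.periods[-1][1]))
    for name, window in [("overall", whole)] + [
        (f"period_{k + 1}", p) for k, p in enumerate(cfg.periods)
    ]:
        try:
            est = estimate_Ne(ped, _period_bounds(window), method=cfg.ne_method)
            ne_rows.append({"window": name, "delta_F": est.delta_f, "Ne": est.ne, "n": est.n})
        except ValueError as err:
            log.warning("Ne for %s unavailable: %s", name, err)
            ne_rows.append({"window": name, "delta_F": np.nan, "Ne": np.nan, "n": 0})
    ne = pd.DataFrame(ne_rows).set_index("window")

    trend_rows = []
    dates = ped.birth_dates
    years = sorted(
        {d.year for d in dates if d is not None}
    )
    dummies = set(ped.is_dummy.nonzero()[0])
    for y in years:
        cohort = [
            i for k, i in enumerate(ped.ids)
            if k not in dummies and dates.iloc[k] is not None and dates.iloc[k].year == y
        ]
        if not cohort:
            continue
        contrib = founder_contributions(ped, cohort)
        trend_rows.append(
            {
                "year": y,
                "n_cohort": len(cohort),
                "n_contributing_founders": int((contrib > 0).sum()),
                "total_contribution": contrib.sum(),
            }
        )
    founder_trend = pd.DataFrame(trend_rows).set_index("year")

    # --- stage: per-period model selection and averaging --------------------
    selection: dict = {}
    averaged: dict = {}
    for k, period in enumerate(cfg.periods):
        frame = prepare_analysis_frame(
            records, coeffs, period=period, standardisation=cfg.standardisation
        )
        if frame.empty:
            log.warning("period %d has no records; reported empty", k + 1)
            for approach in APPROACHES:
                selection[(k + 1, approach)] = pd.DataFrame()
                averaged[(k + 1, approach)] = pd.DataFrame()
            continue
        for approach in APPROACHES:
            cands = enumerate_candidates(
                frame, ped, approach, method=cfg.glmm_method, response=cfg.response
            )
            sel = select_models(cands, threshold=cfg.selection_threshold)
            selection[(k + 1, approach)] = sel.table()
            averaged[(k + 1, approach)] = average_all_terms(sel)
        log.info("period %d: %d records analysed", k + 1, len(frame))

    manifest = {
        "purgekit_version": __version__,
        "seed": cfg.seed,
        "iterations": cfg.iterations,
        "periods": [list(map(str, p)) for p in cfg.periods],
        "standardisation": cfg.standardisation,
        "selection_threshold": cfg.selection_threshold,
        "ne_method": cfg.ne_method,
        "glmm_method": cfg.glmm_method,
        "n_pedigree": len(ped),
        "n_records": int(len(records)),
        "wall_time_s": round(time.time() - t0, 2),
    }
    report = StudyReport(
        descriptives=descriptives,
        correlations=correlations,
        ne=ne,
        founder_trend=founder_trend,
        selection=selection,
        averaged=averaged,
        coefficients=coeffs,
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        _write_report(report, Path(cfg.out_dir))
    return report


def _write_report(report: StudyReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.descriptives.to_csv(out / "descriptives.csv")
    for role, corr in report.correlations.items():
        corr.to_csv(out / f"correlations_{role}.csv")
    report.ne.to_csv(out / "ne.csv")
    report.founder_trend.to_csv(out / "founder_trend.csv")
    report.coefficients.rename_axis("id").to_csv(out / "coefficients.csv")
    for (k, approach), table in report.selection.items():
        table.to_csv(out / f"selection_p{k}_{approach}.csv", index=False)
    for (k, approach), table in report.averaged.items():
        table.to_csv(out / f"averaged_p{k}_{approach}.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
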