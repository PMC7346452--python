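"""Shared fixtures: small reference pedigrees and the recovery harness."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from purgekit import (
    Pedigree,
    PedigreeRecord,
    first_period_scenario,
    simulate_study,
)
from purgekit.glmm import prepare_analysis_frame
from purgekit.multimodel import enumerate_candidates, natural_average, select_models


def fullsib_pedigree() -> Pedigree:
    """Two founders, two full sibs, and their offspring (F = 0.25)."""
    return Pedigree(
        [
            PedigreeRecord("A", sex="male"),
            PedigreeRecord("B", sex="female"),
            PedigreeRecord("C", sire="A", dam="B", sex="male"),
            PedigreeRecord("D", sire="A", dam="B", sex="female"),
            PedigreeRecord("X", sire="C", dam="D"),
        ]
    )


def fullsib_line(generations: int) -> Pedigree:
    """Repeated full-sib mating: each generation is a sib pair of the last."""
    records = [PedigreeRecord("G0a", sex="male"), PedigreeRecord("G0b", sex="female")]
    for g in range(1, generations + 1):
        for tag, sex in (("a", "male"), ("b", "female")):
            records.append(
                PedigreeRecord(
                    f"G{g}{tag}", sire=f"G{g - 1}a", dam=f"G{g - 1}b", sex=sex
                )
            )
    return Pedigree(records)


@pytest.fixture
def fullsib():
    return fullsib_pedigree()


@pytest.fixture(scope="session")
def recovery_harness():
    """50 simulated first-period studies analysed end to end.

    Each replicate simulates ~5,000 kindlings from the default purging
    truth (z.F_NEWL = -0.4, z.F_A-KL = +0.3, season = -0.25, parity
    A/B/C = 0.20/0.31/0.37, sigma2_a = 0.3), runs the Kalinowski candidate
    family, selects by dAICc <= 2 and averages with the natural-average
    method.  Shared (session-scoped) because several properties are read
    off the same replicates.
    """
    truth = {
        "Intercept": 3.2,
        "Season": -0.25,
        "Parity A": 0.20,
        "Parity B": 0.31,
        "Parity C": 0.37,
        "z.F_NEWL": -0.4,
        "z.F_A-KL": 0.3,
    }
    rows = []
    for rep in range(50):
        cfg = first_period_scenario(seed=1000 + rep)
        out = simulate_study(cfg)
        frame = prepare_analysis_frame(
            out.records, out.coefficients, period=cfg.periods[0]
        )
        cands = enumerate_candidates(frame, out.pedigree, "kalinowski", method="profile")
        sel = select_models(cands)
        row = {"rep": rep, "n_records": len(frame)}
        for term in truth:
            a = natural_average(sel, term)
            row[f"est:{term}"] = a.estimate
            row[f"ri:{term}"] = a.ri
            row[f"lo:{term}"] = None if a.ci is None else a.ci[0]
            row[f"hi:{term}"] = None if a.ci is None else a.ci[1]
        rows.append(row)
    table = pd.DataFrame(rows)
    return {"table": table, "truth": truth}
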