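"""Bundled datasets.

``load_ua_cohort`` returns the published 19-case pediatric
ultrasonic-aspirate cohort table: demographics, reference diagnosis,
microarray and nanopore methylation-class calls with their MC/MCF
classification scores, and the per-case concordance used for the cutoff
calibration (nanopore call vs microarray class where available,
otherwise vs the integrated reference diagnosis).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibration import ScoredCase

__all__ = ["load_ua_cohort", "scored_cases_from_cohort"]


def load_ua_cohort() -> pd.DataFrame:
    with resources.files("cnsmeth.data").joinpath("ua_cohort.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if df["concordant"].dtype != bool:
        df["concordant"] = df["concordant"].map({"true": True, "false": False})
    return df


def scored_cases_from_cohort(
    df: pd.DataFrame, score_column: str = "score_mc"
) -> list[ScoredCase]:
    """Turn a cohort table into calibration inputs (one score column)."""
    return [
        ScoredCase(
            case_id=row["case_id"],
            score=float(row[score_column]),
            concordant=bool(row["concordant"]),
        )
        for _, row in df.iterrows()
    ]
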