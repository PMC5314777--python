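"""Summary statistics for smFISH counts and growth-competition assays."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cytometry import cv


@dataclass(frozen=True)
class CountSummary:
    gene: str
    mean: float
    sd: float
    cv: float
    n: int

    def rounded(self, ndigits: int = 2) -> dict:
        """Reporting convention: CVs printed to two decimals."""
        return {"gene": self.gene, "mean": round(self.mean, ndigits),
                "sd": round(self.sd, ndigits), "cv": round(self.cv, ndigits),
                "n": self.n}


def count_summary(counts, gene: str = "") -> CountSummary:
    """Mean, sample SD and CV of per-cell mRNA counts."""
    c = np.asarray(counts)
    if c.size < 2:
        raise ValueError("need at least 2 cells")
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValueError("mRNA counts are non-negative integers")
    c = c.astype(float)
    return CountSummary(gene, float(c.mean()), float(c.std(ddof=1)), cv(c), c.size)


def summarize_counts_csv(df: pd.DataFrame) -> list[CountSummary]:
    """Per-gene summaries of a table with columns ``cell_id, gene, count``."""
    return [count_summary(sub["count"].to_numpy(), gene)
            for gene, sub in df.groupby("gene")]


@dataclass(frozen=True)
class CompetitionCounts:
    """Colony counts of the tested and competitor strains before/after growth."""

    tested_t0: float
    tested_t98: float
    competitor_t0: float
    competitor_t98: float

    def __post_init__(self) -> None:
        if min(self.tested_t0, self.tested_t98,
               self.competitor_t0, self.competitor_t98) <= 0:
            raise ValueError("colony counts must be positive")


def competition_fraction(counts: CompetitionCounts) -> float:
    """Percentage of the tested strain after the competition assay.

    r_t / (r_t + r_c) * 100 where r = colonies(t98) / colonies(t0) for each
    strain; the t0 normalization makes the result invariant to plating
    dilution.
    """
    r_t = counts.tested_t98 / counts.tested_t0
    r_c = counts.competitor_t98 / counts.competitor_t0
    return 100.0 * r_t / (r_t + r_c)
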