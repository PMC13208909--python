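"""Consensus ("at least k of 9 models agree") eligibility footprints.

For each participant the nine binary decisions are tallied; the consensus
curve maps each stringency level k = 1..9 to the percentage of the stratum
whose tally reaches k.  Coverage at k = 1 is the union of the nine eligible
sets, coverage at k = 9 the intersection (unanimity).  Denominators are full
stratum sizes, eligible or not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "consensus_counts",
    "ConsensusCurve",
    "consensus_curve",
    "curve_features",
    "CurveFeatures",
]


def consensus_counts(decisions: pd.DataFrame) -> pd.Series:
    """Per-participant number of models recommending treatment (row sums)."""
    return decisions.astype(bool).sum(axis=1)


@dataclass(frozen=True)
class ConsensusCurve:
    stratum: str
    #: mapping k (1..n_models) -> percent of stratum with tally >= k
    coverage: dict[int, float]
    counts: dict[int, int]
    denominator: int

    def as_frame(self) -> pd.DataFrame:
        ks = sorted(self.coverage)
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "k": ks,
                "count": [self.counts[k] for k in ks],
                "coverage_percent": [self.coverage[k] for k in ks],
            }
        )


def consensus_curve(
    decisions: pd.DataFrame,
    sex: pd.Series | np.ndarray | None = None,
    stratum: str = "overall",
) -> ConsensusCurve:
    """Coverage curve for one stratum ("overall", "female" or "male")."""
    if stratum != "overall":
        if sex is None:
            raise ValueError("sex vector required for sex-stratified curves")
        mask = np.asarray(pd.Series(sex).astype(str) == stratum)
        if not mask.any():
            raise ValueError(f"stratum {stratum!r} is empty")
        decisions = decisions.loc[mask]
    if len(decisions) == 0:
        raise ValueError("empty stratum")
    tallies = consensus_counts(decisions).to_numpy()
    n = len(tallies)
    n_models = decisions.shape[1]
    counts = {k: int(np.sum(tallies >= k)) for k in range(1, n_models + 1)}
    coverage = {k: 100.0 * counts[k] / n for k in counts}
    return ConsensusCurve(stratum=stratum, coverage=coverage, counts=counts, denominator=n)


@dataclass(frozen=True)
class CurveFeatures:
    steepest_drop: float
    steepest_drop_interval: tuple[int, int]
    half_coverage_k: int
    max_sex_gap_k: int | None
    max_sex_gap: float | None  # male minus female coverage, percentage points


def curve_features(
    overall: ConsensusCurve,
    female: ConsensusCurve | None = None,
    male: ConsensusCurve | None = None,
) -> CurveFeatures:
    """Summary features of the consensus curves.

    * steepest adjacent drop: max over k of coverage(k) - coverage(k+1),
      reported with its (k, k+1) interval;
    * half-coverage point: the k whose coverage is nearest 50%;
    * maximal sex divergence: the k at which |male - female| coverage is
      largest, with the signed gap (male minus female).

    Ties break toward smaller k for deterministic reporting.
    """
    ks = sorted(overall.coverage)
    drop, interval = 0.0, (ks[0], ks[0] + 1)
    for k in ks[:-1]:
        d = overall.coverage[k] - overall.coverage[k + 1]
        if d > drop + 1e-12:
            drop, interval = d, (k, k + 1)
    half_k = min(ks, key=lambda k: (abs(overall.coverage[k] - 50.0), k))
    gap_k = gap = None
    if female is not None and male is not None:
        gap_k = min(
            ks, key=lambda k: (-(abs(male.coverage[k] - female.coverage[k])), k)
        )
        gap = male.coverage[gap_k] - female.coverage[gap_k]
    return CurveFeatures(
        steepest_drop=drop,
        steepest_drop_interval=interval,
        half_coverage_k=half_k,
        max_sex_gap_k=gap_k,
        max_sex_gap=gap,
    )
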