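"""Pairwise agreement metrics for binary treatment-eligibility decisions.

Two models classifying the same n participants yield a 2x2 table

    a = both eligible, b = first only, c = second only, d = neither.

From this table the panel computes five complementary agreement measures plus
McNemar's test of marginal symmetry:

* Cohen's kappa — chance-corrected agreement with marginal-product expected
  agreement: po = (a+d)/n, pe = [(a+b)(a+c) + (c+d)(b+d)]/n^2,
  kappa = (po - pe)/(1 - pe).
* Gwet's AC1 — chance-corrected agreement whose chance term depends on the
  mean prevalence pi = ((a+b) + (a+c))/(2n): pe_g = 2*pi*(1-pi),
  AC1 = (po - pe_g)/(1 - pe_g).  More stable than kappa under extreme marginal
  imbalance (the situation that arises when one model flags two-thirds of the
  cohort and another three percent).
* PPA / NPA — positive and negative *specific agreement* in the Dice form,
  PPA = 2a/(2a + b + c) and NPA = 2d/(2d + b + c).
* Jaccard index — intersection over union of the two eligible sets,
  a/(a + b + c).  PPA and Jaccard are linked by PPA = 2J/(1 + J).
* McNemar — tests whether one model systematically labels more participants
  eligible than the other, using the discordant counts b and c only.

Degenerate margins yield flagged ``None`` values, never a silent zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwo",
    "crosstab",
    "cohen_kappa",
    "gwet_ac1",
    "ppa_npa",
    "jaccard",
    "mcnemar",
    "McNemarResult",
    "PairAgreement",
    "pairwise_panel",
    "panel_to_frame",
    "metric_matrix",
    "METRIC_NAMES",
]

#: Discordant-count threshold below which McNemar switches to the exact
#: binomial test (robustness when a pair has few discordant calls).
MCNEMAR_EXACT_THRESHOLD = 25

METRIC_NAMES = ("kappa", "ac1", "ppa", "npa", "jaccard")


class TwoByTwo(NamedTuple):
    """2x2 agreement table; a = both positive ... d = both negative."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def validate(self) -> "TwoByTwo":
        if min(self) < 0:
            raise ValueError(f"negative cell count in {self}")
        if self.n == 0:
            raise ValueError("empty 2x2 table")
        return self

    def swapped(self) -> "TwoByTwo":
        """Table with the two raters exchanged (b and c swap)."""
        return TwoByTwo(self.a, self.c, self.b, self.d)


def crosstab(x: Sequence, y: Sequence) -> TwoByTwo:
    """Cross-tabulate two equal-length binary vectors into a TwoByTwo."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty vectors")
    return TwoByTwo(
        a=int(np.sum(x & y)),
        b=int(np.sum(x & ~y)),
        c=int(np.sum(~x & y)),
        d=int(np.sum(~x & ~y)),
    )


def cohen_kappa(t: TwoByTwo) -> float | None:
    """Cohen's kappa; ``None`` (flagged undefined) when expected agreement is 1."""
    t.validate()
    n = t.n
    po = (t.a + t.d) / n
    pe = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if pe == 1.0:
        return None
    return (po - pe) / (1 - pe)


def gwet_ac1(t: TwoByTwo) -> float | None:
    """Gwet's first-order agreement coefficient AC1."""
    t.validate()
    n = t.n
    po = (t.a + t.d) / n
    pi_hat = ((t.a + t.b) + (t.a + t.c)) / (2 * n)
    pe = 2 * pi_hat * (1 - pi_hat)
    if pe == 1.0:  # unreachable for pe <= 0.5, kept for symmetry with kappa
        return None
    return (po - pe) / (1 - pe)


def ppa_npa(t: TwoByTwo) -> tuple[float | None, float | None]:
    """Positive/negative specific agreement (Dice form); None when the
    corresponding denominator vanishes."""
    t.validate()
    denom_p = 2 * t.a + t.b + t.c
    denom_n = 2 * t.d + t.b + t.c
    ppa = (2 * t.a / denom_p) if denom_p else None
    npa = (2 * t.d / denom_n) if denom_n else None
    return ppa, npa


def jaccard(t: TwoByTwo) -> float | None:
    """Intersection over union of the two positive sets; None when both
    positive sets are empty."""
    t.validate()
    denom = t.a + t.b + t.c
    return (t.a / denom) if denom else None


@dataclass(frozen=True)
class McNemarResult:
    stat: float | None
    p: float | None
    method: str  # "chi2_cc" | "exact" | "undefined"


def mcnemar(t: TwoByTwo, exact_threshold: int = MCNEMAR_EXACT_THRESHOLD) -> McNemarResult:
    """McNemar test of marginal symmetry on the discordant counts.

    Continuity-corrected chi-square (|b-c|-1)^2/(b+c) with 1 df when
    b + c >= ``exact_threshold``; exact two-sided binomial test otherwise;
    flagged undefined when there are no discordant pairs at all.
    """
    t.validate()
    b, c = t.b, t.c
    m = b + c
    if m == 0:
        return McNemarResult(None, None, "undefined")
    if m < exact_threshold:
        p = stats.binomtest(min(b, c), m, 0.5, alternative="two-sided").pvalue
        return McNemarResult(None, float(min(p, 1.0)), "exact")
    stat = (abs(b - c) - 1) ** 2 / m
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(float(stat), p, "chi2_cc")


@dataclass(frozen=True)
class PairAgreement:
    """Full metric panel for one unordered model pair."""

    pair: tuple[str, str]
    table: TwoByTwo
    kappa: float | None
    ac1: float | None
    ppa: float | None
    npa: float | None
    jaccard: float | None
    mcnemar_stat: float | None
    mcnemar_p: float | None
    mcnemar_method: str

    @classmethod
    def from_table(cls, pair: tuple[str, str], t: TwoByTwo) -> "PairAgreement":
        ppa, npa = ppa_npa(t)
        mc = mcnemar(t)
        return cls(
            pair=pair,
            table=t,
            kappa=cohen_kappa(t),
            ac1=gwet_ac1(t),
            ppa=ppa,
            npa=npa,
            jaccard=jaccard(t),
            mcnemar_stat=mc.stat,
            mcnemar_p=mc.p,
            mcnemar_method=mc.method,
        )

    @classmethod
    def from_vectors(cls, pair: tuple[str, str], x, y) -> "PairAgreement":
        return cls.from_table(pair, crosstab(x, y))

    def rounded(self) -> dict:
        """Presentation rounding: kappa/AC1/PPA/NPA to 2 dp; Jaccard to 3 dp
        below 0.1 and 2 dp otherwise."""
        def r2(v):
            return None if v is None else round(v, 2)

        jac = self.jaccard
        if jac is not None:
            jac = round(jac, 3) if abs(jac) < 0.1 else round(jac, 2)
        return {
            "kappa": r2(self.kappa), "ac1": r2(self.ac1),
            "ppa": r2(self.ppa), "npa": r2(self.npa), "jaccard": jac,
        }


def pairwise_panel(
    decisions: pd.DataFrame,
    sex: pd.Series | np.ndarray | None = None,
    stratum: str = "overall",
) -> tuple[list[PairAgreement], pd.DataFrame]:
    """Metric panel for every unordered pair of decision columns.

    Parameters
    ----------
    decisions
        n x m boolean table, one column per model (m=9 gives 36 pairs).
    sex, stratum
        ``stratum`` in {"overall", "female", "male"}; for the sex strata a
        ``sex`` vector aligned with the rows must be given.

    Returns the list of :class:`PairAgreement` plus a summary frame with the
    median and quartiles (linear interpolation) of each metric across pairs.
    """
    if stratum != "overall":
        if sex is None:
            raise ValueError("sex vector required for sex-stratified panels")
        mask = np.asarray(pd.Series(sex).astype(str) == stratum)
        if not mask.any():
            raise ValueError(f"stratum {stratum!r} is empty")
        decisions = decisions.loc[mask]
    if len(decisions) < 2:
        raise ValueError("pairwise agreement needs at least 2 participants")
    panels = [
        PairAgreement.from_vectors(
            (m1, m2), decisions[m1].to_numpy(), decisions[m2].to_numpy()
        )
        for m1, m2 in itertools.combinations(decisions.columns, 2)
    ]
    rows = []
    for metric in METRIC_NAMES:
        values = np.array(
            [getattr(p, metric) for p in panels if getattr(p, metric) is not None],
            dtype=float,
        )
        if values.size:
            q25, med, q75 = np.percentile(values, [25, 50, 75])
        else:
            q25 = med = q75 = np.nan
        rows.append(
            {"metric": metric, "median": med, "q25": q25, "q75": q75,
             "n_pairs": len(panels), "n_defined": int(values.size)}
        )
    return panels, pd.DataFrame(rows).set_index("metric")


def panel_to_frame(panels: Sequence[PairAgreement], stratum: str = "overall") -> pd.DataFrame:
    """Long-format export: one row per pair with counts and all metrics."""
    rows = []
    for p in panels:
        rows.append(
            {
                "stratum": stratum,
                "model_a": p.pair[0], "model_b": p.pair[1],
                "a": p.table.a, "b": p.table.b, "c": p.table.c, "d": p.table.d,
                "kappa": p.kappa, "ac1": p.ac1, "ppa": p.ppa, "npa": p.npa,
                "jaccard": p.jaccard,
                "mcnemar_stat": p.mcnemar_stat, "mcnemar_p": p.mcnemar_p,
                "mcnemar_method": p.mcnemar_method,
            }
        )
    df = pd.DataFrame(rows)
    # flagged-None metrics become NaN in stable float columns (keeps dtypes
    # consistent across strata when a whole column is undefined)
    numeric = ["kappa", "ac1", "ppa", "npa", "jaccard", "mcnemar_stat", "mcnemar_p"]
    df[numeric] = df[numeric].astype(float)
    return df


def metric_matrix(panels: Sequence[PairAgreement], metric: str, models: Sequence[str]) -> pd.DataFrame:
    """Square symmetric matrix of one metric (diagonal 1.0), e.g. for heatmaps."""
    if metric not in METRIC_NAMES:
        raise KeyError(metric)
    m = pd.DataFrame(np.eye(len(models)), index=models, columns=models)
    for p in panels:
        v = getattr(p, metric)
        m.loc[p.pair[0], p.pair[1]] = m.loc[p.pair[1], p.pair[0]] = (
            np.nan if v is None else v
        )
    return m
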