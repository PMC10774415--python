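"""Statistics over cross-progeny count tables.

Homing experiments cross a hemizygous transgenic parent to wild-type or
eye-mutant mates and classify progeny by the fluorescent construct marker,
sex phenotype and recessive eye-colour phenotype.  From such tables this
module computes drive transmission rates with score (Wilson) confidence
intervals, chi-square goodness-of-fit tests against a Mendelian (or any
binary) expectation, and point estimates of the germline cleavage rate ``c``
and HDR rate ``h`` from the transmission rate together with the mutant
fraction among non-carrier progeny.

The inference inverts the hemizygous-parent model

    T = (1 + c*h) / 2          (marker-positive fraction)
    m = c*(1 - h) / (1 - c*h)  (disrupted-site fraction among marker-negatives)

which assumes every NHEJ repair at the scored locus disrupts the visible
phenotype (an R2 fraction of 1 at that locus); in-frame repairs that preserve
pigmentation would bias ``m`` downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CrossCounts",
    "TransmissionEstimate",
    "transmission_rate",
    "chisq_gof",
    "infer_cleavage_hdr",
    "overall_fraction",
    "cross_summary",
]

MARKER_LEVELS = ("POSITIVE", "NEGATIVE")
SEX_LEVELS = ("MALE", "FEMALE", "INTERSEX")
EYE_LEVELS = ("RED", "MOSAIC", "WHITE")

_COLUMNS = ["replicate", "marker", "sex_phenotype", "eye_phenotype", "count"]


@dataclass
class CrossCounts:
    """Tidy progeny count table for one cross experiment.

    One row per (replicate, marker, sex phenotype, eye phenotype) cell;
    sex/eye columns may be empty when that phenotype was not scored.
    ``parent_sex``/``mate_type`` record which parent carried the construct and
    whether the mate was wild type or an eye-mutant strain.
    """

    counts: pd.DataFrame
    parent_sex: str | None = None
    mate_type: str | None = None
    true_params: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = self.counts.copy()
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table is missing columns {missing}")
        df = df[_COLUMNS]
        if (df["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if not (df["count"] == df["count"].astype(int)).all():
            raise ValueError("counts must be integers")
        df["count"] = df["count"].astype(int)
        for col, levels in (
            ("marker", MARKER_LEVELS),
            ("sex_phenotype", SEX_LEVELS),
            ("eye_phenotype", EYE_LEVELS),
        ):
            seen = set(df[col].dropna().unique())
            bad = seen - set(levels)
            if bad:
                raise ValueError(f"invalid {col} categories {sorted(bad)}; allowed {levels}")
        self.counts = df

    # -- totals -------------------------------------------------------------

    @property
    def total(self) -> int:
        return int(self.counts["count"].sum())

    def marker_positive(self) -> int:
        return int(self.counts.loc[self.counts["marker"] == "POSITIVE", "count"].sum())

    def mutant_fraction_among_negatives(self) -> float:
        """WHITE fraction among marker-negative progeny (needs eye scoring)."""
        neg = self.counts[self.counts["marker"] == "NEGATIVE"]
        denom = neg["count"].sum()
        if denom == 0:
            raise ValueError("no marker-negative progeny to score")
        if neg["eye_phenotype"].isna().any():
            raise ValueError("eye phenotype was not scored in this table")
        return float(neg.loc[neg["eye_phenotype"] == "WHITE", "count"].sum() / denom)

    def sex_fraction(self, sex: str, marker: str | None = None) -> float:
        df = self.counts
        if marker is not None:
            df = df[df["marker"] == marker]
        denom = df["count"].sum()
        if denom == 0:
            raise ValueError("no progeny in the requested stratum")
        return float(df.loc[df["sex_phenotype"] == sex, "count"].sum() / denom)

    def replicates(self) -> list["CrossCounts"]:
        return [
            CrossCounts(g.reset_index(drop=True), self.parent_sex, self.mate_type)
            for _, g in self.counts.groupby("replicate", sort=True)
        ]

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        parent_sex: str | None = None,
        mate_type: str | None = None,
    ) -> "CrossCounts":
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep)
        return cls(df, parent_sex=parent_sex, mate_type=mate_type)


class TransmissionEstimate(NamedTuple):
    proportion: float
    ci_low: float
    ci_high: float


def transmission_rate(
    positive: int, total: int, confidence: float = 0.95
) -> TransmissionEstimate:
    """Marker-positive proportion with a score-method binomial interval.

    50% is the Mendelian expectation from a hemizygous parent; anything above
    indicates drive.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= positive <= total:
        raise ValueError("positive must lie in [0, total]")
    low, high = proportion_confint(positive, total, alpha=1 - confidence, method="wilson")
    return TransmissionEstimate(positive / total, float(low), float(high))


def chisq_gof(
    observed: int, total: int, expected_proportion: float
) -> tuple[float, float]:
    """One-df chi-square goodness of fit against a binary split.

    No continuity correction.  Raises if either expected cell count is below
    one (the approximation breaks down).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= observed <= total:
        raise ValueError("observed must lie in [0, total]")
    exp1 = total * expected_proportion
    exp2 = total * (1 - expected_proportion)
    if exp1 < 1 or exp2 < 1:
        raise ValueError("expected count below 1; test not applicable")
    stat, p = stats.chisquare([observed, total - observed], [exp1, exp2])
    return float(stat), float(p)


def infer_cleavage_hdr(T: float, m: float) -> tuple[float, float]:
    """Cleavage and HDR rates from a hemizygous parent's cross outcomes.

    ``T`` is the marker-positive (transmission) proportion and ``m`` the
    disrupted-phenotype fraction among marker-negative progeny.  Inverting
    the forward model gives ``c = (2T - 1) + m*(2 - 2T)`` and
    ``h = (2T - 1)/c``.  When ``c = 0`` (no activity at all) ``h`` is
    indeterminate and returned as NaN.
    """
    if not 0.5 <= T <= 1.0:
        raise ValueError(
            f"transmission must lie in [0.5, 1] under this model, got {T!r}"
        )
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"mutant fraction must lie in [0, 1], got {m!r}")
    c = (2 * T - 1) + m * (2 - 2 * T)
    if c == 0.0:
        return 0.0, math.nan
    h = (2 * T - 1) / c
    return float(c), float(h)


def overall_fraction(p_pos: float, f_pos: float, f_neg: float) -> float:
    """Law of total probability over the marker split.

    The overall fraction of a phenotype equals the marker-positive fraction
    times its conditional fraction among positives, plus the complement times
    the conditional fraction among negatives.
    """
    for name, v in (("p_pos", p_pos), ("f_pos", f_pos), ("f_neg", f_neg)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    return p_pos * f_pos + (1 - p_pos) * f_neg


def cross_summary(
    cc: CrossCounts, expected_proportion: float = 0.5, pooled: bool = True
) -> dict:
    """Transmission, goodness of fit and rate inference for one count table.

    With ``pooled`` (default) counts are summed over replicates before
    analysis; otherwise statistics are computed per replicate and the
    transmission entries report the mean over replicates.  Both conventions
    occur in practice, so the output records which one was used.
    """
    out: dict = {"pooled": pooled, "n_total": cc.total}
    if pooled:
        pos, tot = cc.marker_positive(), cc.total
        est = transmission_rate(pos, tot)
        stat, p = chisq_gof(pos, tot, expected_proportion)
        out.update(
            transmission=est.proportion,
            transmission_ci=(est.ci_low, est.ci_high),
            chisq_statistic=stat,
            chisq_p=p,
        )
        try:
            m = cc.mutant_fraction_among_negatives()
        except ValueError:
            m = None
        if m is not None and est.proportion >= 0.5:
            c, h = infer_cleavage_hdr(est.proportion, m)
            out.update(mutant_fraction_negatives=m, cleavage_rate=c, hdr_rate=h)
    else:
        reps = cc.replicates()
        rates = [r.marker_positive() / r.total for r in reps if r.total > 0]
        out.update(
            n_replicates=len(reps),
            transmission=float(np.mean(rates)),
            transmission_per_replicate=rates,
        )
        tests = [
            chisq_gof(r.marker_positive(), r.total, expected_proportion)
            for r in reps
            if r.total > 0
        ]
        out["chisq_per_replicate"] = tests
    return out
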