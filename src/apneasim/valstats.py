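"""Validation statistics for the detection study.

The study design is a 3 x 3 grid (body angle x commanded displacement),
each condition scored twice over the same 100 breath episodes: without
and with IR fusion. From the per-condition counts this module computes

* per-condition *error odds* — unusable / detected, as a percentage;
* displacement-level and overall summaries, mean +/- sample SD (n-1);
* the pooled 2 x 2 contingency table (mode x outcome) with Pearson's
  chi-square (1 df, no continuity correction) and the odds ratio of
  obtaining an unusable episode without IR relative to with IR.

Reported figures are rounded half-up to two decimals, the precision used
throughout the reference results.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from scipy import stats as sstats

from .detection import ConditionTally

__all__ = [
    "ContingencyTable2x2",
    "GroupSummary",
    "round2",
    "error_odds",
    "displacement_summary",
    "overall_summary",
    "pooled_table",
    "chi_square_2x2",
    "odds_ratio_2x2",
    "validate_against_reference",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimal places (reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = (no-IR, with-IR) and columns = (detected, unusable).

    a, b: detected / unusable without IR; c, d: detected / unusable with IR.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- sample SD of a set of error-odds percentages.

    Values are kept at full precision; round only when reporting
    (:func:`round2`), so that downstream summaries of summaries do not
    accumulate rounding error.
    """

    mean_pct: float
    sd_pct: float
    n_items: int

    def __post_init__(self) -> None:
        if self.sd_pct < 0:
            raise ValueError("sd must be non-negative")


def error_odds(detected: int, unusable: int) -> float:
    """Odds of an unusable episode against a detected one, in percent."""
    if detected <= 0:
        raise ValueError("error odds undefined when no episodes were detected")
    if unusable < 0:
        raise ValueError("unusable count must be non-negative")
    return 100.0 * unusable / detected


def _sample_sd(values: Sequence[float]) -> float:
    n = len(values)
    if n < 2:
        raise ValueError("sample SD needs at least two values")
    mean = sum(values) / n
    return (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5


def _mode_counts(t: ConditionTally, with_ir: bool) -> tuple[int, int]:
    return (t.detected_ir, t.unusable_ir) if with_ir else (
        t.detected_no_ir, t.unusable_no_ir
    )


def _check_grid(tallies: Iterable[ConditionTally]) -> list[ConditionTally]:
    tallies = list(tallies)
    keys = {(t.angle_deg, t.displacement_um) for t in tallies}
    if len(keys) != len(tallies):
        raise ValueError("duplicate (angle, displacement) conditions")
    displacements = {d for _, d in keys}
    angles = {a for a, _ in keys}
    if len(keys) != len(angles) * len(displacements):
        raise ValueError("incomplete condition grid")
    return tallies


def displacement_summary(
    tallies: Iterable[ConditionTally], with_ir: bool
) -> dict[float, GroupSummary]:
    """Mean +/- sample SD of the error odds over angles, per displacement.

    Requires the complete grid (every angle at every displacement).
    """
    tallies = _check_grid(tallies)
    displacements = sorted({t.displacement_um for t in tallies})
    out: dict[float, GroupSummary] = {}
    for disp in displacements:
        odds = [
            error_odds(*_mode_counts(t, with_ir))
            for t in sorted(tallies, key=lambda t: t.angle_deg)
            if t.displacement_um == disp
        ]
        out[disp] = GroupSummary(
            mean_pct=sum(odds) / len(odds),
            sd_pct=_sample_sd(odds),
            n_items=len(odds),
        )
    return out


def overall_summary(level_means: Sequence[float]) -> GroupSummary:
    """Grand summary: mean +/- sample SD of the three displacement-level
    mean error odds."""
    if len(level_means) != 3:
        raise ValueError("expected exactly three displacement-level means")
    return GroupSummary(
        mean_pct=sum(level_means) / 3.0,
        sd_pct=_sample_sd(level_means),
        n_items=3,
    )


def pooled_table(tallies: Iterable[ConditionTally]) -> ContingencyTable2x2:
    """Column sums across the condition grid, per mode."""
    tallies = _check_grid(tallies)
    return ContingencyTable2x2(
        a=sum(t.detected_no_ir for t in tallies),
        b=sum(t.unusable_no_ir for t in tallies),
        c=sum(t.detected_ir for t in tallies),
        d=sum(t.unusable_ir for t in tallies),
    )


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, 1 df.

    Uses the closed form n(ad - bc)^2 / (r1 r2 c1 c2); the p-value comes
    from the chi-square distribution with one degree of freedom.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined with a zero margin")
    stat = table.n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(sstats.chi2.sf(stat, df=1))
    return float(stat), p


def odds_ratio_2x2(table: ContingencyTable2x2) -> float:
    """Odds of an unusable outcome without IR relative to with IR:
    (b/a) / (d/c)."""
    if table.a == 0 or table.c == 0 or table.d == 0:
        raise ValueError(
            "odds ratio undefined with a zero reference cell; add an "
            "explicit continuity constant if needed"
        )
    return (table.b / table.a) / (table.d / table.c)


# ---------------------------------------------------------------------------
# Reference comparison
# ---------------------------------------------------------------------------

def compute_aggregates(tallies: Iterable[ConditionTally]) -> dict:
    """All study aggregates of a complete grid, reported at 2 dp."""
    tallies = _check_grid(tallies)
    pooled = pooled_table(tallies)
    chi, p = chi_square_2x2(pooled)
    out: dict = {
        "pooled": {
            "detected_no_ir": pooled.a,
            "unusable_no_ir": pooled.b,
            "detected_ir": pooled.c,
            "unusable_ir": pooled.d,
        },
        "chi_square": round2(chi),
        "p_value": p,
        "p_label": "< 0.001" if p < 0.001 else f"= {p:.3f}",
        "odds_ratio": round2(odds_ratio_2x2(pooled)),
    }
    for with_ir, key in ((False, "no_ir"), (True, "ir")):
        levels = displacement_summary(tallies, with_ir)
        means = [levels[d].mean_pct for d in sorted(levels)]
        overall = overall_summary(means)
        out[key] = {
            "levels": {
                str(int(d)): {"mean": round2(s.mean_pct), "sd": round2(s.sd_pct)}
                for d, s in levels.items()
            },
            "overall": {
                "mean": round2(overall.mean_pct),
                "sd": round2(overall.sd_pct),
            },
        }
    return out


def _flatten(agg: dict) -> dict[str, float]:
    flat: dict[str, float] = {}
    for k, v in agg["pooled"].items():
        flat[f"pooled.{k}"] = v
    flat["chi_square"] = agg["chi_square"]
    flat["odds_ratio"] = agg["odds_ratio"]
    for key in ("no_ir", "ir"):
        for d, s in agg[key]["levels"].items():
            flat[f"{key}.mean_{d}"] = s["mean"]
            flat[f"{key}.sd_{d}"] = s["sd"]
        flat[f"{key}.overall_mean"] = agg[key]["overall"]["mean"]
        flat[f"{key}.overall_sd"] = agg[key]["overall"]["sd"]
    return flat


def validate_against_reference(
    tallies: Iterable[ConditionTally],
    reference: Iterable[ConditionTally],
) -> dict:
    """Recompute every aggregate from both grids, side by side.

    The reference grid is checked for 2-dp equality against its own
    recomputed aggregates' expected reference values; candidate tallies
    are reported for qualitative trend comparison only (a stochastic
    simulation is not expected to match the reference counts).
    """
    agg_test = compute_aggregates(tallies)
    agg_ref = compute_aggregates(reference)
    flat_test, flat_ref = _flatten(agg_test), _flatten(agg_ref)
    rows = []
    for key in flat_ref:
        rows.append(
            {
                "quantity": key,
                "reference": flat_ref[key],
                "candidate": flat_test.get(key),
                "match_2dp": flat_test.get(key) == flat_ref[key],
            }
        )
    return {
        "reference_aggregates": agg_ref,
        "candidate_aggregates": agg_test,
        "comparison": rows,
        "all_match": all(r["match_2dp"] for r in rows),
    }
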