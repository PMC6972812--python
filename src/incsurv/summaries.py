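"""Annual survival summaries, precision metrics, and group contrasts.

A weekly hazard draw lambda maps to annual survival S = exp(-52 lambda).
Summaries are equal-tailed 95% credible intervals on the survival scale;
the point estimate is the posterior median by default (survival posteriors
near 1 are left-skewed, where the median is the more robust center), with
the mean available by argument.

Precision of an estimate is measured by the spread of its 95% CrI
(upper - lower); the gain from adding incidental data is the percent
decrease 100 * (1 - combined_spread / radio_spread), reported to 1 decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
import numpy as np
import pandas as pd

from .model import PosteriorDraws
from .records import GROUP_LABELS, N_GROUPS, SITES, group_fields, reference_group

WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class SurvivalSummary:
    """Per-group annual survival estimate with 95% CrI and spread."""

    group_label: str
    estimable: bool
    estimate: float = np.nan
    lower: float = np.nan
    upper: float = np.nan

    @property
    def spread(self) -> float:
        return self.upper - self.lower

    def __str__(self) -> str:
        if not self.estimable:
            return f"{self.group_label}: inestimable"
        return (
            f"{self.group_label}: {self.estimate:.3f} "
            f"({self.lower:.3f}-{self.upper:.3f})"
        )


def annual_survival_draws(lambda_draws: np.ndarray) -> np.ndarray:
    """Per-draw annual survival exp(-52 lambda) for weekly hazard draws."""
    return np.exp(-WEEKS_PER_YEAR * np.asarray(lambda_draws, dtype=float))


def annual_survival(
    draws: PosteriorDraws, point: str = "median"
) -> list[SurvivalSummary]:
    """Summarize each group's annual survival from posterior hazard draws.

    Inestimable groups (prior-dominated; essentially no exposure) are
    flagged and carry no numbers, mirroring dashes in a report table.
    """
    if point not in ("median", "mean"):
        raise ValueError("point must be 'median' or 'mean'")
    surv = annual_survival_draws(draws.lambda_draws())
    out = []
    for j, label in enumerate(draws.group_labels):
        if not draws.estimable[j]:
            out.append(SurvivalSummary(group_label=label, estimable=False))
            continue
        s = surv[:, j]
        center = float(np.median(s) if point == "median" else np.mean(s))
        lo, hi = (float(q) for q in np.quantile(s, [0.025, 0.975]))
        out.append(
            SurvivalSummary(
                group_label=label, estimable=True, estimate=center, lower=lo, upper=hi
            )
        )
    return out


def cri_spread(lower: float, upper: float) -> float:
    """Width of an equal-tailed credible interval."""
    return upper - lower


def percent_decrease(radio_spread: float, combined_spread: float) -> float:
    """Precision gain 100 * (1 - combined/radio), rounded half-up to 1 dp."""
    if not np.isfinite(radio_spread) or radio_spread <= 0:
        raise ValueError("radio-only spread must be positive and finite")
    raw = 100.0 * (1.0 - float(combined_spread) / float(radio_spread))
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContrastResult:
    """Posterior of beta_j - beta_{resident adult, same site}."""

    group_label: str
    reference_label: str
    mean: float
    lower: float
    upper: float
    significant: bool  # 95% CrI excludes zero
    draws: np.ndarray


def contrast(draws: PosteriorDraws, group: int, site: str | None = None) -> ContrastResult:
    """Within-site log-hazard contrast against the resident-adult baseline.

    Cross-site contrasts are refused: the grouping confounds site with any
    residency/age effect, so comparisons are only meaningful within a site.
    """
    residency, age_class, group_site = group_fields(group)
    if site is None:
        site = group_site
    if site != group_site:
        raise ValueError(
            f"cross-site contrast refused: group {GROUP_LABELS[group]} is not in {site}"
        )
    ref = reference_group(site)
    if not (draws.estimable[group] and draws.estimable[ref]):
        raise ValueError("both contrasted groups must be estimable")
    beta = draws.flat_beta()
    diff = beta[:, group] - beta[:, ref]
    lo, hi = (float(q) for q in np.quantile(diff, [0.025, 0.975]))
    return ContrastResult(
        group_label=draws.group_labels[group],
        reference_label=draws.group_labels[ref],
        mean=float(diff.mean()),
        lower=lo,
        upper=hi,
        significant=bool(lo > 0 or hi < 0),
        draws=diff,
    )


def point_estimate_difference(
    radio_only: SurvivalSummary, combined: SurvivalSummary
) -> float:
    """Signed change in the survival point estimate, combined minus radio-only."""
    if not (radio_only.estimable and combined.estimable):
        raise ValueError("both summaries must be estimable")
    return combined.estimate - radio_only.estimate


@dataclass
class ComparisonReport:
    """Radio-only vs. combined fit, one row per group."""

    radio_only: list[SurvivalSummary]
    combined: list[SurvivalSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, c in zip(self.radio_only, self.combined):
            both = r.estimable and c.estimable
            rows.append(
                {
                    "group_label": c.group_label,
                    "combined_estimate": c.estimate if c.estimable else np.nan,
                    "combined_lower": c.lower if c.estimable else np.nan,
                    "combined_upper": c.upper if c.estimable else np.nan,
                    "radio_spread": r.spread if r.estimable else np.nan,
                    "combined_spread": c.spread if c.estimable else np.nan,
                    "percent_decrease": (
                        percent_decrease(r.spread, c.spread) if both else np.nan
                    ),
                    "point_difference": (
                        point_estimate_difference(r, c) if both else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("group_label")

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.6g")

    def render_text(self) -> str:
        """Aligned human-readable rendering; dashes mark inestimable cells."""
        frame = self.to_frame()
        lines = [
            f"{'group':<28}{'estimate':>9}{'95% CrI':>17}"
            f"{'radio sprd':>11}{'comb sprd':>10}{'% decr':>8}{'pt diff':>9}"
        ]
        for label, row in frame.iterrows():
            def fmt(v, spec=".3f"):
                return "-" if not np.isfinite(v) else format(v, spec)

            cri = (
                "-"
                if not np.isfinite(row.combined_lower)
                else f"({row.combined_lower:.3f}, {row.combined_upper:.3f})"
            )
            lines.append(
                f"{label:<28}{fmt(row.combined_estimate):>9}{cri:>17}"
                f"{fmt(row.radio_spread):>11}{fmt(row.combined_spread):>10}"
                f"{fmt(row.percent_decrease, '.1f'):>8}"
                f"{fmt(row.point_difference, '+.3f'):>9}"
            )
        return "\n".join(lines)
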