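"""Agreement statistics for movement-count validation.

Two sources (two human raters, or the raters' consensus versus the automated
count) each report a nonnegative integer count per participant.  Agreement is
summarised by:

* **ICC(2,1)** — the intraclass correlation from a two-way random-effects
  ANOVA (participants and raters both random), single measures, absolute
  agreement, with the standard F-based 95% confidence interval
  (McGraw & Wong's ICC(A,1)).  Interpretation follows the Fleiss bands:
  >= 0.75 excellent, < 0.40 poor, otherwise moderate.
* **Percentage agreement** — the paper-trail statistic for count data.  No
  canonical formula exists for unequal counts; this package uses the mean
  over participants of ``100 * min(a_i, b_i) / max(a_i, b_i)``, with the
  pair (0, 0) contributing 100.  This definition is a reconstruction: treat
  comparisons against previously published percentage-agreement figures as
  indicative only.
* **Bland-Altman limits of agreement** — mean difference +/- 1.96 sample
  standard deviations of the differences (1.96 literally, not a t quantile).

Counts enter as a tidy table (CSV, or XLSX via a column mapping) with one row
per participant x condition x skill and columns for each source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import DegenerateDataError, InsufficientDataError, ValidationError

FLEISS_EXCELLENT = 0.75
FLEISS_POOR = 0.40

REQUIRED_COLUMNS = ("participant", "condition", "skill", "rater1", "rater2", "consensus", "system")

COMPARISONS = {
    "raters": ("rater1", "rater2"),
    "consensus_vs_system": ("consensus", "system"),
}


def fleiss_category(icc: float) -> str:
    if icc >= FLEISS_EXCELLENT:
        return "excellent"
    if icc < FLEISS_POOR:
        return "poor"
    return "moderate"


@dataclass
class ICCResult:
    """ICC(2,1) point estimate with its 95% CI and Fleiss category."""

    icc: float
    ci95_low: float
    ci95_high: float
    n: int
    k: int
    ms_rows: float
    ms_cols: float
    ms_error: float
    category: str = field(init=False)

    def __post_init__(self):
        self.category = fleiss_category(self.icc)


@dataclass
class BAResult:
    """Bland-Altman summary of the differences a - b."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def _as_counts(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def icc_two_way_random_single(a, b, *, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares (rows = participants,
    columns = sources); the CI uses the F-based interval of McGraw & Wong.
    Requires n >= 3 participants and non-degenerate data.
    """
    a = _as_counts(a, "a")
    b = _as_counts(b, "b")
    if len(a) != len(b):
        raise ValidationError("count vectors must have equal length")
    n = len(a)
    k = 2
    if n < 3:
        raise InsufficientDataError(f"ICC needs at least 3 participants, got {n}")
    x = np.column_stack([a, b])
    grand = x.mean()
    if np.allclose(x, grand):
        raise DegenerateDataError("all counts identical: total variance is zero")

    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    # McGraw & Wong (1996) CI for ICC(A,1), Satterthwaite df for the
    # between-columns term.
    if mse > 0:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f_u = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_l = f_dist.ppf(1 - alpha / 2, v, n - 1)
        low = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        high = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    else:
        low = high = icc
    low = min(low, icc)
    high = max(high, icc)
    return ICCResult(icc=float(icc), ci95_low=float(low), ci95_high=float(high),
                     n=n, k=k, ms_rows=msr, ms_cols=msc, ms_error=mse)


def percentage_agreement(a, b) -> float:
    """Mean over participants of 100*min/max; the pair (0, 0) scores 100."""
    a = _as_counts(a, "a")
    b = _as_counts(b, "b")
    if len(a) != len(b):
        raise ValidationError("count vectors must have equal length")
    if len(a) == 0:
        raise InsufficientDataError("need at least one participant")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("counts must be nonnegative")
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    ratios = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), 1.0)
    return float(100.0 * ratios.mean())


def bland_altman(a, b) -> BAResult:
    """Limits of agreement for the differences a - b (counts)."""
    a = _as_counts(a, "a")
    b = _as_counts(b, "b")
    if len(a) != len(b):
        raise ValidationError("count vectors must have equal length")
    if len(a) < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 participants")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return BAResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        means=(a + b) / 2.0,
        diffs=d,
    )


def plot_bland_altman(result: BAResult, destination, *, title: str | None = None) -> None:
    """Scatter of per-participant (mean, difference) with the mean difference
    (solid) and the +/-1.96 SD limits of agreement (dotted)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=18, color="tab:blue", alpha=0.8)
    ax.axhline(result.mean_diff, color="black")
    ax.axhline(result.loa_low, color="black", linestyle=":")
    ax.axhline(result.loa_high, color="black", linestyle=":")
    ax.set_xlabel("Mean of the two counts")
    ax.set_ylabel("Difference between counts")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(destination, dpi=120)
    plt.close(fig)


# -- count tables ------------------------------------------------------------

@dataclass
class CountTable:
    """Per-participant movement counts from every source.

    One row per participant x condition x skill, columns
    participant, condition, skill, rater1, rater2, consensus, system.
    Consensus counts are an *input*: the raters' discussion that produces
    them is a human process, not computed here.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"count table is missing columns: {missing}")
        for col in ("rater1", "rater2", "consensus", "system"):
            vals = pd.to_numeric(self.df[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"column {col!r} contains non-numeric values")
            if (vals < 0).any():
                raise ValidationError(f"column {col!r} contains negative counts")
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError(f"column {col!r} contains non-integral counts")
            self.df[col] = vals.astype(int)

    @classmethod
    def from_csv(cls, source) -> "CountTable":
        return cls(pd.read_csv(source))

    @classmethod
    def from_xlsx(cls, source, column_map: dict[str, str], *, sheet_name=0) -> "CountTable":
        """Read an XLSX workbook, renaming its columns to the canonical names
        via *column_map* (canonical name -> workbook column)."""
        df = pd.read_excel(source, sheet_name=sheet_name, engine="openpyxl")
        rename = {v: k for k, v in column_map.items()}
        missing = [v for v in column_map.values() if v not in df.columns]
        if missing:
            raise ValidationError(f"workbook is missing mapped columns: {missing}")
        return cls(df.rename(columns=rename)[list(column_map.keys())])

    def select(self, skill: str, condition: str) -> pd.DataFrame:
        sub = self.df[(self.df["skill"] == skill) & (self.df["condition"] == condition)]
        if sub.empty:
            have = sorted(
                {(s, c) for s, c in zip(self.df["skill"], self.df["condition"])}
            )
            raise ValidationError(
                f"no rows for skill={skill!r}, condition={condition!r}; table has {have}"
            )
        return sub


def report(table: CountTable, skill: str, condition: str, comparison: str) -> dict:
    """Reliability report for one skill/condition/source-pair.

    Returns a JSON-serialisable dict with per-source mean +/- SD and totals,
    ICC(2,1) with its 95% CI and Fleiss category, percentage agreement, and
    Bland-Altman limits.  :func:`format_report` renders the same dict as an
    aligned text table, so the two outputs agree on every number.
    """
    if comparison not in COMPARISONS:
        raise ValidationError(
            f"unknown comparison {comparison!r}; choose from {sorted(COMPARISONS)}"
        )
    col_a, col_b = COMPARISONS[comparison]
    sub = table.select(skill, condition)
    a = sub[col_a].to_numpy(dtype=float)
    b = sub[col_b].to_numpy(dtype=float)
    n = len(a)
    small_n = n < 2

    out: dict = {
        "skill": skill,
        "condition": condition,
        "comparison": comparison,
        "sources": [col_a, col_b],
        "n": n,
        "mean": {col_a: float(a.mean()), col_b: float(b.mean())},
        "sd": {
            col_a: float(a.std(ddof=1)) if n > 1 else 0.0,
            col_b: float(b.std(ddof=1)) if n > 1 else 0.0,
        },
        "total": {col_a: int(a.sum()), col_b: int(b.sum())},
        "percentage_agreement": percentage_agreement(a, b),
        "small_n": small_n,
    }
    try:
        icc = icc_two_way_random_single(a, b)
        out["icc"] = {
            "value": icc.icc,
            "ci95": [icc.ci95_low, icc.ci95_high],
            "category": icc.category,
        }
    except (InsufficientDataError, DegenerateDataError) as exc:
        out["icc"] = {"value": None, "error": str(exc)}
    try:
        ba = bland_altman(a, b)
        out["bland_altman"] = {
            "mean_diff": ba.mean_diff,
            "sd_diff": ba.sd_diff,
            "loa": [ba.loa_low, ba.loa_high],
        }
    except InsufficientDataError as exc:
        out["bland_altman"] = {"mean_diff": None, "error": str(exc)}
    return out


def format_report(rep: dict) -> str:
    """Aligned-text rendering of a :func:`report` dict."""
    col_a, col_b = rep["sources"]
    lines = [
        f"Skill: {rep['skill']}   Condition: {rep['condition']}   "
        f"Comparison: {col_a} vs {col_b}   (n = {rep['n']})",
        "",
        f"{'':14s}{col_a:>14s}{col_b:>14s}",
        f"{'mean':14s}{rep['mean'][col_a]:14.2f}{rep['mean'][col_b]:14.2f}",
        f"{'sd':14s}{rep['sd'][col_a]:14.2f}{rep['sd'][col_b]:14.2f}",
        f"{'total':14s}{rep['total'][col_a]:14d}{rep['total'][col_b]:14d}",
        "",
    ]
    icc = rep["icc"]
    if icc.get("value") is not None:
        lines.append(
            f"ICC(2,1) = {icc['value']:.2f}  "
            f"(95% CI {icc['ci95'][0]:.2f}-{icc['ci95'][1]:.2f}, {icc['category']})"
        )
    else:
        lines.append(f"ICC(2,1): not computed ({icc['error']})")
    lines.append(f"Percentage agreement = {rep['percentage_agreement']:.2f}%")
    ba = rep["bland_altman"]
    if ba.get("mean_diff") is not None:
        lines.append(
            f"Bland-Altman: mean diff {ba['mean_diff']:.2f}, "
            f"limits of agreement [{ba['loa'][0]:.2f}, {ba['loa'][1]:.2f}]"
        )
    else:
        lines.append(f"Bland-Altman: not computed ({ba['error']})")
    if rep["small_n"]:
        lines.append("warning: single participant; SD reported as 0")
    return "\n".join(lines)


def report_to_json(rep: dict, destination=None) -> str:
    payload = json.dumps(rep, sort_keys=True, indent=2, default=float)
    if destination is not None:
        Path(destination).write_text(payload + "\n")
    return payload
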