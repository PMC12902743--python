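"""Longitudinal aggregation over the six assessment timepoints.

Outcome measures are tracked at baseline, post-FES-conditioning, after 6,
10 and 16 weeks of TESCS-ABT and at 12-week follow-up.  The overview
logic flags, per participant / limb / measure: presence of a response at
baseline, improvement after the intervention (16 weeks of TESCS-ABT
versus post-conditioning, strict), and whether an improvement was
sustained at follow-up.  A missing timepoint leaves the corresponding
flag not-evaluable (``None`` in code, blank in tables) rather than false.

GRASSP score changes are flagged against the minimal detectable
difference (per subscale: sensation 4, strength 5, prehension ability 4,
prehension performance 3 points) and the minimal clinically important
difference (2 points by default — the lower end of the reported 2–3
point range, which is the reading under which a 2-point strength gain
counts as clinically meaningful).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TIMEPOINTS, ValidationError, validate_scores

#: Minimal detectable difference per GRASSP subscale (points, per side).
GRASSP_MDD = {
    "sensation": 4,
    "strength": 5,
    "prehension_ability": 4,
    "prehension_performance": 3,
}

#: Default minimal clinically important difference (points).
GRASSP_MCID = 2

_BASELINE, _PRE, _POST, _FOLLOWUP = "base", "FES", "TESCS_16", "post_12"


@dataclass
class OverviewFlags:
    """Presence / improvement / sustained flags; ``None`` = not evaluable."""

    presence_at_base: bool | None
    improved_post_vs_pre: bool | None
    sustained_at_followup: bool | None
    measure: str = ""


def percent_change(pre: float, post: float) -> float:
    """Relative change in percent, ``100 * (post - pre) / pre``.

    Returns ``nan`` (not evaluable) when ``pre`` is zero.
    """
    if pre == 0:
        return math.nan
    return 100.0 * (post - pre) / pre


def overview_flags(
    series: dict[str, float],
    presence_threshold: float = 0.0,
    measure: str = "",
) -> OverviewFlags:
    """Apply the overview logic to one timepoint -> value series."""
    bad = set(series) - set(TIMEPOINTS)
    if bad:
        raise ValidationError(f"unknown timepoints {sorted(bad)}")
    vals = {tp: series[tp] for tp in series if not _is_missing(series[tp])}
    presence = (vals[_BASELINE] > presence_threshold) if _BASELINE in vals else None
    if _PRE in vals and _POST in vals:
        improved = vals[_POST] > vals[_PRE]
    else:
        improved = None
    if improved is None:
        sustained = None
    elif not improved:
        sustained = False
    elif _FOLLOWUP in vals:
        sustained = vals[_FOLLOWUP] > vals[_PRE]
    else:
        sustained = None
    return OverviewFlags(presence, improved, sustained, measure=measure)


def _is_missing(v) -> bool:
    try:
        return v is None or math.isnan(float(v))
    except (TypeError, ValueError):
        return True


def grassp_flags(change: float, subscale: str,
                 mcid_points: float = GRASSP_MCID) -> tuple[bool, bool]:
    """(meets_mdd, meets_mcid) for a GRASSP subscale change in points."""
    if subscale not in GRASSP_MDD:
        raise ValidationError(
            f"unknown subscale {subscale!r}; choose from {sorted(GRASSP_MDD)}"
        )
    return change >= GRASSP_MDD[subscale], change >= mcid_points


def rank_correlation(xs, ys) -> tuple[float, float]:
    """Spearman's rho with tie-corrected ranks and its two-sided p-value."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValidationError("inputs must have equal length")
    if xs.size < 3:
        raise ValidationError("need at least 3 pairs")
    res = stats.spearmanr(xs, ys)
    return float(res.statistic), float(res.pvalue)


def overview_table(scores: pd.DataFrame,
                   presence_threshold: float | dict[str, float] = 0.0) -> pd.DataFrame:
    """One overview row per (participant, limb, measure) from a score table.

    Not-evaluable flags appear as missing values (blank in TSV), never 0.
    """
    scores = validate_scores(scores)
    rows = []
    for (participant, limb, measure), grp in scores.groupby(
        ["participant", "limb", "measure"], sort=True
    ):
        series = dict(zip(grp["timepoint"], grp["value"]))
        thr = (presence_threshold.get(measure, 0.0)
               if isinstance(presence_threshold, dict) else presence_threshold)
        flags = overview_flags(series, thr, measure=measure)
        rows.append({
            "participant": participant, "limb": limb, "measure": measure,
            "presence_at_base": flags.presence_at_base,
            "improved_post_vs_pre": flags.improved_post_vs_pre,
            "sustained_at_followup": flags.sustained_at_followup,
        })
    out = pd.DataFrame(rows)
    for col in ("presence_at_base", "improved_post_vs_pre", "sustained_at_followup"):
        out[col] = out[col].astype(object).where(out[col].notna(), pd.NA)
    return out


def build_report(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                 fmt: str = "tsv") -> list[Path]:
    """Write named result tables deterministically as TSV or JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        df = tables[name]
        if fmt == "tsv":
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False, na_rep="")
        elif fmt == "json":
            path = out_dir / f"{name}.json"
            path.write_text(json.dumps(
                json.loads(df.to_json(orient="records")), indent=1
            ))
        else:
            raise ValidationError(f"unknown format {fmt!r}")
        written.append(path)
    return written
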