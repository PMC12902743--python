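"""The trial's adherence model.

Per therapy block (phase), attendance is ``a = x/s`` (sessions attended
over scheduled) and assessment-timing adherence is ``b = 1/(w+1)`` for a
delay of ``w`` weeks.  Phase adherence combines the two with equal weight,
``c = a/2 + b/2``, for interior phases; at baseline ``c := 1`` by
definition.  The source model defines follow-up as ``c := 1/b``, which
exceeds 1 whenever the assessment is late and so contradicts the stated
range ``c ∈ [0, 1]``; the default here uses ``c := b`` at follow-up
(timing only — there is no therapy block to attend), and the literal
``1/b`` reading (clipped to 1, with a warning) is available via
``followup_mode="literal"``.

Overall adherence ``C`` is the unweighted mean of ``c`` over all phases
including the baseline and follow-up sentinels.  The relative series
compares successive phases without knock-on effects:
``b̄_k = 1/(w_k − w_j + 1)`` and ``C̄_k = a_k/2 + b̄_k/2`` with
``C̄ := 1`` at baseline.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .io_formats import ValidationError, validate_attendance


def attendance(x: int, s: int) -> float:
    """Attendance ratio a = x/s."""
    if s <= 0:
        raise ValidationError("scheduled sessions must be positive")
    if not 0 <= x <= s:
        raise ValidationError(f"attended {x} outside [0, {s}]")
    return x / s


def timing(w: float) -> float:
    """Assessment-timing adherence b = 1/(w+1) for a delay of w weeks."""
    if w < 0:
        raise ValidationError("delay must be non-negative")
    return 1.0 / (w + 1.0)


def phase_adherence(
    x: int | None = None,
    s: int | None = None,
    w: float | None = None,
    boundary: str = "none",
    followup_mode: str = "timing_only",
) -> float:
    """Phase adherence c.

    Interior phases: ``c = x/(2s) + 1/(2w+2)``.  ``boundary="baseline"``
    returns 1 by definition; ``boundary="followup"`` uses ``c = b``
    (default) or the literal ``1/b`` clipped to 1.
    """
    if boundary == "baseline":
        return 1.0
    if boundary == "followup":
        if w is None:
            raise ValidationError("follow-up phase adherence needs the delay w")
        b = timing(w)
        if followup_mode == "timing_only":
            return b
        if followup_mode == "literal":
            if b < 1.0:
                warnings.warn(
                    "literal follow-up definition 1/b exceeds 1; clipping to 1"
                )
            return min(1.0 / b, 1.0)
        raise ValidationError(f"unknown followup_mode {followup_mode!r}")
    if boundary != "none":
        raise ValidationError(f"unknown boundary {boundary!r}")
    if x is None or s is None or w is None:
        raise ValidationError("interior phase adherence needs x, s and w")
    return attendance(x, s) / 2.0 + timing(w) / 2.0


def overall_adherence(phase_values: list[float]) -> float:
    """Overall adherence C: the mean of c over all N phases."""
    if len(phase_values) == 0:
        raise ValidationError("no phases")
    return float(sum(phase_values)) / len(phase_values)


def relative_timing(w_k: float, w_j: float) -> float:
    """Relative timing adherence b̄ between successive phases k and j."""
    if w_j < 0 or w_k < w_j:
        raise ValidationError("need w_k >= w_j >= 0")
    return 1.0 / (w_k - w_j + 1.0)


def relative_adherence(
    a_k: float | None,
    w_k: float,
    w_j: float,
    boundary: str = "none",
    followup_mode: str = "timing_only",
) -> tuple[float, float]:
    """Relative adherence (b̄_k, C̄_k) of phase k against the previous phase j."""
    if boundary == "baseline":
        return 1.0, 1.0
    b_rel = relative_timing(w_k, w_j)
    if boundary == "followup":
        if followup_mode == "timing_only":
            return b_rel, b_rel
        if followup_mode == "literal":
            if b_rel < 1.0:
                warnings.warn(
                    "literal follow-up definition 1/b̄ exceeds 1; clipping to 1"
                )
            return b_rel, min(1.0 / b_rel, 1.0)
        raise ValidationError(f"unknown followup_mode {followup_mode!r}")
    if boundary != "none":
        raise ValidationError(f"unknown boundary {boundary!r}")
    if a_k is None:
        raise ValidationError("interior relative adherence needs a_k")
    return b_rel, a_k / 2.0 + b_rel / 2.0


def study_adherence(
    log: pd.DataFrame,
    followup_mode: str = "timing_only",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-phase and overall adherence from an attendance log.

    Rows with ``scheduled == 0`` are sentinels: the first per
    (participant, outcome group) is the baseline, the last the follow-up.
    Returns ``(phases, overall)``: the per-phase table with a, b, c, the
    relative series b̄, C̄, and a per-(participant, group) table of the
    overall adherence C.
    """
    log = validate_attendance(log)
    phase_rows, overall_rows = [], []
    for (participant, group), grp in log.groupby(
        ["participant", "outcome_group"], sort=False
    ):
        grp = grp.reset_index(drop=True)
        sentinels = grp.index[grp["scheduled"] == 0].tolist()
        base_i = sentinels[0] if sentinels and sentinels[0] == 0 else None
        follow_i = (
            sentinels[-1]
            if sentinels and sentinels[-1] == len(grp) - 1 and sentinels[-1] != base_i
            else None
        )
        cs = []
        prev_w = None
        for i, row in grp.iterrows():
            x, s, w = int(row["attended"]), int(row["scheduled"]), float(row["delay_weeks"])
            if i == base_i:
                a = float("nan")
                b = timing(w)
                c = phase_adherence(boundary="baseline")
                b_rel, c_rel = relative_adherence(None, w, w, boundary="baseline")
            elif i == follow_i:
                a = float("nan")
                b = timing(w)
                c = phase_adherence(w=w, boundary="followup", followup_mode=followup_mode)
                b_rel, c_rel = relative_adherence(
                    None, w, prev_w if prev_w is not None else w,
                    boundary="followup", followup_mode=followup_mode,
                )
            else:
                a = attendance(x, s)
                b = timing(w)
                c = phase_adherence(x, s, w)
                w_j = prev_w if prev_w is not None else w
                b_rel, c_rel = relative_adherence(a, w, w_j)
            cs.append(c)
            prev_w = w
            phase_rows.append({
                "participant": participant, "outcome_group": group,
                "phase": row["phase"], "a": a, "b": b, "c": c,
                "b_rel": b_rel, "c_rel": c_rel,
            })
        overall_rows.append({
            "participant": participant, "outcome_group": group,
            "n_phases": len(cs), "C": overall_adherence(cs),
        })
    return pd.DataFrame(phase_rows), pd.DataFrame(overall_rows)
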