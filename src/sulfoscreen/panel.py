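"""Four-substrate rescreen classification.

Secondary hits are profiled on a small substrate panel: the coupled assay
(sulfated substrate + exogenous hexosaminidase), the sulfated substrate
alone, asulfated 4MU-GlcNAc, the generic aryl sulfate 4MU-SO4, and a
no-substrate control that catches autofluorescent clones (e.g. riboflavin
producers). Each condition is thresholded against control lysates at
mean + k*SD, and the resulting boolean pattern is mapped to an enzyme-class
label through a fixed first-match rule table.

The pattern (direct AND asulfated) is genuinely ambiguous between a single
sulfate-tolerant hexosaminidase and a sulfatase + ordinary hexosaminidase
pair; the tiebreak (coupled also positive -> the pair) is recorded with an
ambiguity flag on the call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .simulate import PANEL_CONDITIONS, PanelFluorescence

__all__ = [
    "ActivityPattern",
    "EnzymeClassCall",
    "threshold_activities",
    "classify",
    "summarize_cohort",
    "calls_to_frame",
]


@dataclass(frozen=True)
class ActivityPattern:
    """Boolean activity per panel condition; all 32 patterns are legal."""

    coupled: bool
    direct: bool
    asulfated: bool
    generic_sulfate: bool
    no_substrate: bool

    def as_tuple(self) -> tuple[bool, bool, bool, bool, bool]:
        return (self.coupled, self.direct, self.asulfated,
                self.generic_sulfate, self.no_substrate)


@dataclass(frozen=True)
class EnzymeClassCall:
    clone_id: str
    pattern: ActivityPattern
    label: str
    rule: str       # identifier of the rule that fired, for audit
    ambiguous: bool = False


def threshold_activities(panel: PanelFluorescence, control_stats: pd.DataFrame,
                         k: float = 3.0) -> ActivityPattern:
    """Threshold each condition at control mean + k*SD.

    ``control_stats`` is a long table (columns: condition, rfu) of control
    lysate readings, or a pre-aggregated one with columns condition/mean/sd.
    """
    if {"mean", "sd"}.issubset(control_stats.columns):
        agg = control_stats.set_index("condition")[["mean", "sd"]]
    else:
        agg = (control_stats.groupby("condition")["rfu"]
               .agg(mean="mean", sd="std"))
    missing = set(PANEL_CONDITIONS) - set(agg.index)
    if missing:
        raise ValueError(f"control stats missing conditions: {sorted(missing)}")

    flags = {}
    for cond in PANEL_CONDITIONS:
        mean, sd = float(agg.loc[cond, "mean"]), float(agg.loc[cond, "sd"])
        flags[cond] = panel.rfu[cond] >= mean + k * sd
    return ActivityPattern(**flags)


def classify(pattern: ActivityPattern, clone_id: str = "") -> EnzymeClassCall:
    """Map an activity pattern to an enzyme-class label (total function).

    First-match precedence:

    1. fluorescence without substrate -> autofluorescent false positive
    2. aryl-sulfate activity -> general (non-sugar-specific) sulfatase
    3. coupled only -> sulfo-specific sulfatase (the F1 phenotype)
    4. direct without asulfated -> sulfate-dependent hexosaminidase (F10)
    5. direct and asulfated -> sulfatase + hexosaminidase combination when
       coupled is also positive, else sulfate-tolerant hexosaminidase;
       flagged ambiguous either way
    6. asulfated only -> plain hexosaminidase, indeterminate for this screen
    7. nothing -> inactive; any residual pattern -> indeterminate
    """
    c, d, a, g, n = pattern.as_tuple()
    if n:
        return EnzymeClassCall(clone_id, pattern,
                               "autofluorescent_false_positive", "R1-no-substrate")
    if g:
        return EnzymeClassCall(clone_id, pattern, "general_sulfatase",
                               "R2-generic-sulfate")
    if c and not d and not a:
        return EnzymeClassCall(clone_id, pattern, "sulfo_specific_sulfatase",
                               "R3-coupled-only")
    if d and not a:
        return EnzymeClassCall(clone_id, pattern,
                               "sulfate_dependent_hexosaminidase", "R4-direct-no-asulfated")
    if d and a:
        label = ("sulfatase_plus_hexosaminidase" if c
                 else "sulfotolerant_hexosaminidase")
        return EnzymeClassCall(clone_id, pattern, label,
                               "R5-direct-and-asulfated", ambiguous=True)
    if a and not c and not d:
        return EnzymeClassCall(clone_id, pattern, "indeterminate",
                               "R6-asulfated-only")
    if not any(pattern.as_tuple()):
        return EnzymeClassCall(clone_id, pattern, "inactive", "R7-all-negative")
    return EnzymeClassCall(clone_id, pattern, "indeterminate", "R8-residual")


def summarize_cohort(calls: list[EnzymeClassCall]) -> dict:
    """Cohort counts in the form the screen reports them.

    ``n_direct`` counts clones active on the sulfated substrate without the
    exogenous hexosaminidase; ``n_direct_and_asulfated`` those also active on
    asulfated GlcNAc; ``n_generic`` those active on the aryl sulfate.
    """
    summary = {
        "n_clones": len(calls),
        "n_direct": sum(c.pattern.direct for c in calls),
        "n_direct_and_asulfated": sum(c.pattern.direct and c.pattern.asulfated
                                      for c in calls),
        "n_generic": sum(c.pattern.generic_sulfate for c in calls),
        "by_label": {},
    }
    for c in calls:
        summary["by_label"][c.label] = summary["by_label"].get(c.label, 0) + 1
    return summary


def calls_to_frame(calls: list[EnzymeClassCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "clone": c.clone_id,
        "coupled": c.pattern.coupled, "direct": c.pattern.direct,
        "asulfated": c.pattern.asulfated,
        "generic_sulfate": c.pattern.generic_sulfate,
        "no_substrate": c.pattern.no_substrate,
        "label": c.label, "rule": c.rule, "ambiguous": c.ambiguous,
    } for c in calls])
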