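"""Exoglycosidase-digest and binding-mode inference from paired traces.

Comparing annotated peak tables before and after enzyme treatment yields
per-substrate verdicts: *hydrolyzed* when the substrate peak loses relative
height and the transition rule's product appears (the diagnostic migration
shift, e.g. FA2G0-SO4 at ~150 MTU" moving to FA1G0 at ~245 MTU" on loss of
a sulfated GlcNAc); *unchanged* when nothing moves; *depleted_no_product*
when the substrate shrinks with no product — the signature of an apo-enzyme
binding its substrate so the complex is lost during clean-up. The binding
interpretation is confirmed by a proteinase-K arm: digesting the enzyme
releases the glycan, so the substrate peak is restored.

All comparisons use relative peak heights (percent of analyte total), and
"significant" change defaults to a 20% relative drop, configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ce import Peak
from .simulate import GlycanLibraryEntry

__all__ = [
    "TransitionRule",
    "DigestCall",
    "BindingCall",
    "MatchedPeaks",
    "match_peaks_across",
    "call_digest",
    "call_binding",
    "concentration_response",
    "digest_calls_to_frame",
]


@dataclass(frozen=True)
class TransitionRule:
    """One enzyme transition: substrate glycan -> product glycan."""

    enzyme: str
    substrate: str
    product: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise ValueError(f"substrate == product in rule for {self.substrate!r}")

    def validate_against(self, library: list[GlycanLibraryEntry]) -> None:
        names = {e.name for e in library}
        for n in (self.substrate, self.product):
            if n not in names:
                raise ValueError(f"rule references glycan absent from library: {n!r}")


@dataclass(frozen=True)
class DigestCall:
    substrate: str
    verdict: str                # hydrolyzed | unchanged | depleted_no_product | not_detected
    height_change_pct: float    # post - pre relative height (percentage points)
    product_appeared: bool
    rule: TransitionRule | None = None


@dataclass(frozen=True)
class BindingCall:
    verdict: str                # binding | hydrolysis | none
    substrate: str
    control_height: float
    direct_height: float
    protk_height: float


@dataclass(frozen=True)
class MatchedPeaks:
    pairs: list[tuple[Peak, Peak]]
    appeared: list[Peak]      # in post only
    disappeared: list[Peak]   # in pre only


def _require_normalized(peaks: list[Peak], label: str) -> None:
    for p in peaks:
        if not p.is_standard and p.mtu is None:
            raise ValueError(f"{label} peaks must be normalized (MTU missing)")


def _analytes(peaks: list[Peak]) -> list[Peak]:
    return [p for p in peaks if not p.is_standard]


def match_peaks_across(pre: list[Peak], post: list[Peak],
                       tol_mtu: float = 1.0) -> MatchedPeaks:
    """Pair analyte peaks across two annotated tables.

    Peaks sharing an unambiguous assignment are paired by name; the rest are
    paired greedily by MTU" proximity within ``tol_mtu``. Unpaired peaks are
    reported as appeared (post only) or disappeared (pre only).
    """
    _require_normalized(pre, "pre")
    _require_normalized(post, "post")
    pre_a, post_a = _analytes(pre), _analytes(post)

    def named(peaks):
        return {p.assignment: p for p in peaks
                if p.assignment not in (None, "ambiguous")}

    pre_named, post_named = named(pre_a), named(post_a)
    pairs = [(pre_named[n], post_named[n])
             for n in sorted(set(pre_named) & set(post_named))]
    used_pre = {id(a) for a, _ in pairs}
    used_post = {id(b) for _, b in pairs}

    rest_pre = [p for p in pre_a if id(p) not in used_pre]
    rest_post = [p for p in post_a if id(p) not in used_post]
    # greedy nearest-MTU pairing among the unnamed remainder
    candidates = sorted(((abs(a.mtu - b.mtu), i, j)
                         for i, a in enumerate(rest_pre)
                         for j, b in enumerate(rest_post)
                         if abs(a.mtu - b.mtu) <= tol_mtu))
    taken_i, taken_j = set(), set()
    for _d, i, j in candidates:
        if i in taken_i or j in taken_j:
            continue
        pairs.append((rest_pre[i], rest_post[j]))
        taken_i.add(i)
        taken_j.add(j)

    disappeared = [p for i, p in enumerate(rest_pre) if i not in taken_i]
    appeared = [p for j, p in enumerate(rest_post) if j not in taken_j]
    return MatchedPeaks(pairs=pairs, appeared=appeared, disappeared=disappeared)


def _rel_height(peaks: list[Peak], name: str) -> float | None:
    """Relative height of the peak assigned to ``name`` (None if absent)."""
    for p in _analytes(peaks):
        if p.assignment == name:
            return p.relative_height if p.relative_height is not None else 0.0
    return None


def call_digest(pre: list[Peak], post: list[Peak],
                rules: list[TransitionRule],
                decrease_threshold: float = 0.20,
                library: list[GlycanLibraryEntry] | None = None,
                ) -> list[DigestCall]:
    """Per-substrate digest verdicts from pre/post annotated peak tables.

    For each rule substrate present in the pre trace: *hydrolyzed* if its
    relative height drops by at least ``decrease_threshold`` of its pre value
    and the rule's product appears (or grows by at least the same fraction);
    *unchanged* if the change is below threshold either way;
    *depleted_no_product* if it drops without the expected product.
    """
    _require_normalized(pre, "pre")
    _require_normalized(post, "post")
    if library is not None:
        for r in rules:
            r.validate_against(library)

    calls = []
    for rule in rules:
        pre_h = _rel_height(pre, rule.substrate)
        if pre_h is None or pre_h == 0:
            calls.append(DigestCall(rule.substrate, "not_detected", 0.0,
                                    False, rule))
            continue
        post_h = _rel_height(post, rule.substrate) or 0.0
        change = post_h - pre_h
        dropped = (pre_h - post_h) >= decrease_threshold * pre_h

        prod_pre = _rel_height(pre, rule.product)
        prod_post = _rel_height(post, rule.product)
        if prod_post is None:
            product_appeared = False
        elif prod_pre is None:
            product_appeared = prod_post > 0
        else:
            product_appeared = (prod_post - prod_pre) >= decrease_threshold * max(prod_pre, 1e-12)

        if dropped and product_appeared:
            verdict = "hydrolyzed"
        elif dropped:
            verdict = "depleted_no_product"
        else:
            verdict = "unchanged"
        calls.append(DigestCall(rule.substrate, verdict, float(change),
                                product_appeared, rule))
    return calls


def call_binding(control: list[Peak], direct_arm: list[Peak],
                 protk_arm: list[Peak], substrate: str,
                 rules: list[TransitionRule] | None = None,
                 decrease_threshold: float = 0.20) -> BindingCall:
    """Calcium-free binding inference with the proteinase-K rescue control.

    *binding*: the substrate's relative height in the directly cleaned-up arm
    falls below (1 - threshold) of the control, while the proteinase-K arm
    stays within +/- threshold of the control (the enzyme-glycan complex is
    lost in clean-up unless the enzyme is destroyed first). *hydrolysis*: a
    rule product appears in either arm (calcium present). *none* otherwise.
    """
    for peaks, label in ((control, "control"), (direct_arm, "direct"),
                         (protk_arm, "proteinase-K")):
        _require_normalized(peaks, label)
    ctrl_h = _rel_height(control, substrate)
    if ctrl_h is None or ctrl_h == 0:
        raise ValueError(f"substrate {substrate!r} absent from control trace")
    direct_h = _rel_height(direct_arm, substrate) or 0.0
    protk_h = _rel_height(protk_arm, substrate) or 0.0

    if rules:
        # a product peak counts as hydrolysis evidence only when it is a new
        # peak: depletion of the substrate renormalizes co-run reference
        # glycans upward, so growth of a pre-existing peak is not diagnostic
        sub_rules = [r for r in rules if r.substrate == substrate]
        for arm in (direct_arm, protk_arm):
            for r in sub_rules:
                prod = _rel_height(arm, r.product)
                in_control = _rel_height(control, r.product)
                if prod is not None and prod > 0 and in_control is None:
                    return BindingCall("hydrolysis", substrate, ctrl_h,
                                       direct_h, protk_h)

    depleted = direct_h < (1.0 - decrease_threshold) * ctrl_h
    rescued = abs(protk_h - ctrl_h) <= decrease_threshold * ctrl_h
    verdict = "binding" if (depleted and rescued) else "none"
    return BindingCall(verdict, substrate, ctrl_h, direct_h, protk_h)


@dataclass(frozen=True)
class ConcentrationReport:
    monotone_decreasing: bool
    span: float               # depletion from zero-enzyme to highest amount
    amounts: tuple[float, ...]
    heights: tuple[float, ...]
    violations: int           # increases exceeding the slack


def concentration_response(series: list[tuple[float, float]],
                           slack: float = 5.0) -> ConcentrationReport:
    """Concentration dependence of substrate depletion.

    ``series`` is (enzyme amount, substrate relative height) with at least
    three amounts including zero. The response is concentration-dependent if
    heights are non-increasing in amount, allowing single-step increases up
    to ``slack`` percentage points of noise.
    """
    if len(series) < 3:
        raise ValueError("need >= 3 enzyme amounts including zero")
    amounts = [a for a, _ in series]
    if len(set(amounts)) != len(amounts):
        raise ValueError("duplicate enzyme amounts")
    if amounts != sorted(amounts):
        raise ValueError("enzyme amounts must be given in increasing order")
    if amounts[0] != 0:
        raise ValueError("series must include a zero-enzyme point")

    heights = [h for _, h in series]
    violations = sum(1 for h0, h1 in zip(heights, heights[1:])
                     if h1 - h0 > slack)
    span = heights[0] - heights[-1]
    monotone = violations == 0 and span > slack
    return ConcentrationReport(monotone, float(span), tuple(amounts),
                               tuple(heights), violations)


def digest_calls_to_frame(calls: list[DigestCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "substrate": c.substrate, "verdict": c.verdict,
        "height_change_pct": c.height_change_pct,
        "product_appeared": c.product_appeared,
        "enzyme": c.rule.enzyme if c.rule else None,
        "product": c.rule.product if c.rule else None,
    } for c in calls])
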