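"""Two-stage sigma-threshold hit calling over plate time courses.

A primary hit is a clone well whose fluorescence reaches at least
mean + 3*SD of the control background at one or more timepoints (an
intentionally liberal definition). Re-screened wells pass the secondary
stage only if they exceed mean + 6*SD at two or more timepoints (strict
inequality). Control statistics are computed per scope — per plate by
default, since plate effects dominate in practice, or batch-wide — with
the sample SD (n-1 denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import ScreenDataset

__all__ = [
    "ControlStats",
    "HitCall",
    "control_stats",
    "call_primary",
    "call_secondary",
    "call_hits",
    "hit_rate",
    "fpr_analytic",
    "hits_to_frame",
]


@dataclass(frozen=True)
class ControlStats:
    """Per-timepoint control background statistics for one scope."""

    scope: str
    timepoints: tuple[float, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError(f"scope {self.scope!r}: need >= 2 controls, "
                             f"got {self.n_controls}")
        if any(s < 0 for s in self.sd):
            raise ValueError("SD must be >= 0")

    def at(self, t: float) -> tuple[float, float]:
        try:
            i = self.timepoints.index(t)
        except ValueError:
            raise KeyError(f"scope {self.scope!r} has no control stats at "
                           f"timepoint {t}") from None
        return self.mean[i], self.sd[i]


@dataclass(frozen=True)
class HitCall:
    """Audit record for one well at one stage of the funnel."""

    well_id: str        # "plate/well"
    stage: str          # "primary" | "secondary"
    timepoints: tuple[float, ...]
    z_scores: tuple[float, ...]
    n_timepoints_above: int
    is_hit: bool
    k: float
    min_timepoints: int

    def recompute_is_hit(self, strict: bool) -> bool:
        """Re-derive the verdict from the stored z-scores (audit contract)."""
        if strict:
            n = sum(z > self.k for z in self.z_scores if np.isfinite(z))
        else:
            n = sum(z >= self.k for z in self.z_scores if np.isfinite(z))
        return n >= self.min_timepoints


def control_stats(dataset: ScreenDataset, scope: str = "plate") -> dict[str, ControlStats]:
    """Control background mean and sample SD per (scope, timepoint).

    ``scope="plate"`` computes statistics independently per plate;
    ``scope="batch"`` pools every control well in the dataset.
    """
    if scope not in ("plate", "batch"):
        raise ValueError(f"scope must be plate|batch, got {scope!r}")
    df = dataset.data
    controls = df[df["role"] == "control"]
    if controls.empty:
        raise ValueError("dataset contains no control wells")

    key = controls["plate"] if scope == "plate" else pd.Series("batch", index=controls.index)
    out: dict[str, ControlStats] = {}
    for scope_id, grp in controls.groupby(key):
        agg = grp.groupby("timepoint_h")["rfu"].agg(["mean", "std", "count"])
        n = int(agg["count"].min())
        if n < 2:
            raise ValueError(f"scope {scope_id!r}: fewer than 2 control wells "
                             f"at some timepoint")
        out[str(scope_id)] = ControlStats(
            scope=str(scope_id),
            timepoints=tuple(float(t) for t in agg.index),
            mean=tuple(float(m) for m in agg["mean"]),
            sd=tuple(float(s) for s in agg["std"]),
            n_controls=n,
        )
    # every scope present in the data must be covered
    scopes_needed = set(df["plate"].unique()) if scope == "plate" else {"batch"}
    missing = scopes_needed - set(out)
    if missing:
        raise ValueError(f"no control wells for scope(s): {sorted(missing)}")
    return out


def _call_stage(dataset: ScreenDataset, stats: dict[str, ControlStats],
                stage: str, k: float, min_timepoints: int,
                strict: bool) -> list[HitCall]:
    df = dataset.data
    clones = df[df["role"] == "clone"]
    batch_mode = set(stats) == {"batch"}

    calls = []
    warned_scopes = set()
    for (plate, well), grp in clones.groupby(["plate", "well"], sort=True):
        scope_id = "batch" if batch_mode else str(plate)
        if scope_id not in stats:
            raise ValueError(f"no control stats for scope {scope_id!r}")
        st = stats[scope_id]
        grp = grp.sort_values("timepoint_h")
        zs, above = [], 0
        for t, v in zip(grp["timepoint_h"], grp["rfu"]):
            mean, sd = st.at(float(t))
            if sd == 0.0:
                # degenerate: all controls identical; exclude this timepoint
                if (scope_id, t) not in warned_scopes:
                    warnings.warn(
                        f"scope {scope_id!r} timepoint {t}: control SD is 0; "
                        f"timepoint excluded from the hit rule", stacklevel=2)
                    warned_scopes.add((scope_id, t))
                zs.append(float("nan"))
                continue
            z = (v - mean) / sd
            zs.append(float(z))
            if (z > k) if strict else (z >= k):
                above += 1
        calls.append(HitCall(
            well_id=f"{plate}/{well}", stage=stage,
            timepoints=tuple(float(t) for t in grp["timepoint_h"]),
            z_scores=tuple(zs), n_timepoints_above=above,
            is_hit=above >= min_timepoints, k=k, min_timepoints=min_timepoints))
    return calls


def call_primary(dataset: ScreenDataset, stats: dict[str, ControlStats],
                 k: float = 3.0, min_timepoints: int = 1) -> list[HitCall]:
    """Primary-stage calls: RFU >= mean + k*SD at >= min_timepoints timepoints."""
    return _call_stage(dataset, stats, "primary", k, min_timepoints, strict=False)


def call_secondary(dataset: ScreenDataset, stats: dict[str, ControlStats],
                   k: float = 6.0, min_timepoints: int = 2) -> list[HitCall]:
    """Secondary-stage calls: RFU strictly over mean + k*SD at >= min_timepoints."""
    return _call_stage(dataset, stats, "secondary", k, min_timepoints, strict=True)


def call_hits(dataset: ScreenDataset, stage: str, scope: str = "plate",
              k: float | None = None, min_timepoints: int | None = None) -> list[HitCall]:
    """Convenience wrapper: estimate control stats then call one stage."""
    stats = control_stats(dataset, scope)
    if stage == "primary":
        return call_primary(dataset, stats, k if k is not None else 3.0,
                            min_timepoints if min_timepoints is not None else 1)
    if stage == "secondary":
        return call_secondary(dataset, stats, k if k is not None else 6.0,
                              min_timepoints if min_timepoints is not None else 2)
    raise ValueError(f"stage must be primary|secondary, got {stage!r}")


def hit_rate(n_hits: int, n_screened: int) -> tuple[float, float]:
    """Screen hit rate in percent: (full precision, rounded to one decimal)."""
    if n_screened <= 0:
        raise ValueError("n_screened must be > 0")
    if n_hits > n_screened or n_hits < 0:
        raise ValueError("need 0 <= n_hits <= n_screened")
    pct = 100.0 * n_hits / n_screened
    return pct, round(pct, 1)


def fpr_analytic(k: float, n_timepoints: int, min_timepoints: int) -> float:
    """Per-well false-positive probability of a sigma rule under iid Gaussian noise.

    P(X >= min_timepoints) with X ~ Binomial(n_timepoints, sf(k)); assumes
    independent timepoints, which holds for pure read noise but not for
    autocorrelated kinetic curves.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if not 1 <= min_timepoints <= n_timepoints:
        raise ValueError("need 1 <= min_timepoints <= n_timepoints")
    p = sps.norm.sf(k)
    return float(sps.binom.sf(min_timepoints - 1, n_timepoints, p))


def hits_to_frame(calls: list[HitCall]) -> pd.DataFrame:
    """Flatten hit calls to a table (one row per well, z per timepoint)."""
    rows = []
    for c in calls:
        row = {"well_id": c.well_id, "stage": c.stage,
               "n_timepoints_above": c.n_timepoints_above, "is_hit": c.is_hit}
        for t, z in zip(c.timepoints, c.z_scores):
            row[f"z_{t:g}h"] = z
        rows.append(row)
    return pd.DataFrame(rows)
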