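"""Synthetic inputs for every pipeline stage.

The study's raw plate reads and electropherograms are not deposited, so this
module generates them: 384-well plate screens with planted ground truth
(background wells, clones with planted sulfatase/hexosaminidase kinetics,
riboflavin-like autofluorescent false positives), four-substrate rescreen
panels, and raw capillary-electrophoresis traces built from Gaussian peaks
under an affine migration-time warp with two spiked internal standards.

Every generator is deterministic under a fixed seed and returns the planted
truth alongside the data, so downstream stages (hit calling, classification,
trace processing, digest inference) can be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import KineticParams, NoiseModel, fluorescence_curve

__all__ = [
    "CLASSES",
    "CLASS_RATE_MAP",
    "PANEL_CONDITIONS",
    "WellProfile",
    "ScreenConfig",
    "ScreenDataset",
    "PanelFluorescence",
    "TraceSpec",
    "TraceComponent",
    "StandardSpec",
    "GlycanLibraryEntry",
    "EnzymeSpec",
    "Electropherogram",
    "simulate_screen",
    "simulate_panel",
    "simulate_panel_controls",
    "simulate_trace",
    "simulate_digest_pair",
    "builtin_glycan_library",
    "builtin_enzymes",
    "write_screen_csv",
    "read_screen_csv",
    "write_glycan_library_tsv",
    "read_glycan_library_tsv",
    "write_trace_csv",
    "read_trace_csv",
]

# ---------------------------------------------------------------------------
# enzyme-class enumeration and rate wiring
# ---------------------------------------------------------------------------

#: clone classes; labels match what the four-substrate rescreen distinguishes
CLASSES = (
    "inactive",
    "sulfo_specific_sulfatase",
    "general_sulfatase",
    "sulfate_dependent_hexosaminidase",
    "sulfotolerant_hexosaminidase",
    "sulfatase_plus_hexosaminidase",
    "autofluorescent_false_positive",
)

#: which latent activities each class carries:
#: (sulfatase, generic aryl-sulfatase, hexosaminidase on sulfated GlcNAc,
#:  hexosaminidase on asulfated GlcNAc, autofluorescence)
CLASS_RATE_MAP: dict[str, tuple[bool, bool, bool, bool, bool]] = {
    "inactive":                         (False, False, False, False, False),
    "sulfo_specific_sulfatase":         (True,  False, False, False, False),
    "general_sulfatase":                (True,  True,  False, False, False),
    "sulfate_dependent_hexosaminidase": (False, False, True,  False, False),
    "sulfotolerant_hexosaminidase":     (False, False, True,  True,  False),
    "sulfatase_plus_hexosaminidase":    (True,  False, False, True,  False),
    "autofluorescent_false_positive":   (False, False, False, False, True),
}

#: rescreen panel conditions, in fixed order
PANEL_CONDITIONS = ("coupled", "direct", "asulfated", "generic_sulfate", "no_substrate")


@dataclass(frozen=True)
class WellProfile:
    """Latent ground truth for one well.

    Latent activities are first-order rates (1/h): ``sulfatase_rate`` acts on
    sugar-linked sulfate, ``generic_sulfatase`` marks additional activity on
    the aryl sulfate substrate (4MU-SO4), ``hex_sulfated_rate`` releases 4MU
    directly from the sulfated substrate, ``hex_asulfated_rate`` acts on
    asulfated 4MU-GlcNAc, and ``autofluor_rate`` (RFU/h) accumulates signal
    without any substrate.
    """

    well_id: str
    role: str  # "clone" | "control"
    true_class: str
    sulfatase_rate: float = 0.0
    generic_sulfatase: bool = False
    hex_sulfated_rate: float = 0.0
    hex_asulfated_rate: float = 0.0
    autofluor_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("clone", "control"):
            raise ValueError(f"role must be clone|control, got {self.role!r}")
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.role == "control" and self.true_class != "inactive":
            raise ValueError("control wells must be inactive")
        has = (self.sulfatase_rate > 0, self.generic_sulfatase,
               self.hex_sulfated_rate > 0, self.hex_asulfated_rate > 0,
               self.autofluor_rate > 0)
        if has != CLASS_RATE_MAP[self.true_class]:
            raise ValueError(
                f"rates {has} inconsistent with class {self.true_class!r} "
                f"(expected {CLASS_RATE_MAP[self.true_class]})")

    def condition_params(self, condition: str, assay) -> KineticParams:
        """Kinetic parameters for one rescreen condition.

        Wiring: in ``coupled`` the exogenous hexosaminidase processes the
        desulfated intermediate; in ``direct`` (no exogenous enzyme) only the
        clone's own asulfated-active hexosaminidase can process it; the
        ``asulfated`` and ``generic_sulfate`` substrates release 4MU in a
        single step.
        """
        base = dict(s0=assay.s0, f_yield=assay.f_yield, baseline=assay.baseline,
                    autofluor_rate=self.autofluor_rate)
        if condition == "coupled":
            return KineticParams(k_sulf=self.sulfatase_rate,
                                 k_hex_exo=assay.exo_hex_rate,
                                 k_hex_direct=self.hex_sulfated_rate, **base)
        if condition == "direct":
            return KineticParams(k_sulf=self.sulfatase_rate,
                                 k_hex_exo=self.hex_asulfated_rate,
                                 k_hex_direct=self.hex_sulfated_rate, **base)
        if condition == "asulfated":
            return KineticParams(k_hex_direct=self.hex_asulfated_rate, **base)
        if condition == "generic_sulfate":
            rate = self.sulfatase_rate if self.generic_sulfatase else 0.0
            return KineticParams(k_hex_direct=rate, **base)
        if condition == "no_substrate":
            base["f_yield"] = 0.0
            return KineticParams(**base)
        raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class AssayConstants:
    """Shared assay-level constants (not per-well)."""

    s0: float = 1.0
    f_yield: float = 2000.0      # RFU per unit fluorophore at full conversion
    baseline: float = 100.0      # RFU
    exo_hex_rate: float = 2.0    # 1/h, exogenous hexosaminidase in excess


DEFAULT_TIMEPOINTS = (1.0, 3.0, 6.0, 24.0, 30.0, 48.0)

#: default planted class mix: mostly empty wells, a small hit fraction whose
#: composition mirrors the screen cohort (combination clones dominate)
DEFAULT_CLASS_FREQUENCIES = {
    "inactive": 0.993,
    "sulfo_specific_sulfatase": 0.0005,
    "general_sulfatase": 0.0005,
    "sulfate_dependent_hexosaminidase": 0.001,
    "sulfotolerant_hexosaminidase": 0.001,
    "sulfatase_plus_hexosaminidase": 0.003,
    "autofluorescent_false_positive": 0.001,
}


@dataclass(frozen=True)
class ScreenConfig:
    n_plates: int = 5
    wells_per_plate: int = 384
    controls_per_plate: int = 16
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    class_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FREQUENCIES))
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(sd_additive=5.0))
    assay: AssayConstants = field(default_factory=AssayConstants)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class frequencies must sum to 1, got {total}")
        unknown = set(self.class_frequencies) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in frequencies: {sorted(unknown)}")
        if self.controls_per_plate < 2:
            raise ValueError("need >= 2 control wells per plate for an SD")
        if self.controls_per_plate >= self.wells_per_plate:
            raise ValueError("controls_per_plate must leave room for clones")


@dataclass
class ScreenDataset:
    """Long-format plate reads: one row per (plate, well, timepoint)."""

    data: pd.DataFrame  # columns: plate, well, role, timepoint_h, rfu

    def __post_init__(self) -> None:
        missing = {"plate", "well", "role", "timepoint_h", "rfu"} - set(self.data.columns)
        if missing:
            raise ValueError(f"screen dataset missing columns: {sorted(missing)}")


# full-scale preset: half of a 23,040-clone library across 384-well plates
def full_scale_config(seed: int = 0, **overrides) -> ScreenConfig:
    """Preset at the original screen's scale (11,520 clone wells)."""
    cfg = ScreenConfig(n_plates=32, wells_per_plate=384, controls_per_plate=24,
                       seed=seed)
    # 32 plates x 360 clone wells = 11,520 clones
    return replace(cfg, **overrides) if overrides else cfg


def _well_ids(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    ids = []
    n_cols = max(1, -(-n // len(rows)))
    for c in range(1, n_cols + 1):
        for r in rows:
            ids.append(f"{r}{c:02d}")
            if len(ids) == n:
                return ids
    return ids


def _draw_profile(well_id: str, cls: str, rng: np.random.Generator) -> WellProfile:
    """Planted latent rates for one clone well of a given class."""
    def rate() -> float:
        # lognormal around ~0.2/h: visible well within the 48 h window
        return float(rng.lognormal(mean=np.log(0.2), sigma=0.5))

    sulf, generic, hex_s, hex_a, auto = CLASS_RATE_MAP[cls]
    return WellProfile(
        well_id=well_id, role="clone", true_class=cls,
        sulfatase_rate=rate() if sulf else 0.0,
        generic_sulfatase=generic,
        hex_sulfated_rate=rate() if hex_s else 0.0,
        hex_asulfated_rate=rate() if hex_a else 0.0,
        autofluor_rate=float(rng.uniform(20.0, 60.0)) if auto else 0.0,
    )


def simulate_screen(config: ScreenConfig) -> tuple[ScreenDataset, pd.DataFrame]:
    """Simulate the primary screen; returns the dataset and a truth table.

    Control wells (empty-vector lysates) occupy the first
    ``controls_per_plate`` positions of each plate and read pure background.
    The truth table has one row per well with the planted class and rates.
    """
    rng = np.random.default_rng(config.seed)
    # sorted so the draw sequence is independent of dict insertion order
    classes = sorted(config.class_frequencies)
    probs = np.array([config.class_frequencies[c] for c in classes])
    ids = _well_ids(config.wells_per_plate)
    timepoints = np.asarray(config.timepoints, dtype=float)

    rows, truth_rows = [], []
    for p in range(1, config.n_plates + 1):
        plate = f"P{p:03d}"
        for i, wid in enumerate(ids):
            is_control = i < config.controls_per_plate
            if is_control:
                profile = WellProfile(wid, "control", "inactive")
            else:
                cls = classes[int(rng.choice(len(classes), p=probs))]
                profile = _draw_profile(wid, cls, rng)
            params = profile.condition_params("coupled", config.assay)
            rfu = fluorescence_curve(params, timepoints, config.noise,
                                     rng_seed=int(rng.integers(0, 2**31)))
            for t, v in zip(timepoints, rfu):
                rows.append((plate, wid, profile.role, float(t), float(v)))
            truth_rows.append({
                "plate": plate, "well": wid, "role": profile.role,
                "true_class": profile.true_class,
                "sulfatase_rate": profile.sulfatase_rate,
                "generic_sulfatase": profile.generic_sulfatase,
                "hex_sulfated_rate": profile.hex_sulfated_rate,
                "hex_asulfated_rate": profile.hex_asulfated_rate,
                "autofluor_rate": profile.autofluor_rate,
            })

    data = pd.DataFrame(rows, columns=["plate", "well", "role", "timepoint_h", "rfu"])
    truth = pd.DataFrame(truth_rows)
    return ScreenDataset(data), truth


# ---------------------------------------------------------------------------
# four-substrate rescreen panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelFluorescence:
    """Endpoint RFU for the five rescreen conditions of one clone."""

    clone_id: str
    rfu: dict  # condition -> endpoint RFU

    def __post_init__(self) -> None:
        missing = set(PANEL_CONDITIONS) - set(self.rfu)
        if missing:
            raise ValueError(f"panel missing conditions: {sorted(missing)}")


def simulate_panel(profile: WellProfile, seed: int = 0,
                   assay: AssayConstants | None = None,
                   noise: NoiseModel | None = None,
                   endpoint_h: float = 48.0) -> PanelFluorescence:
    """Endpoint fluorescence of one clone across the five panel conditions."""
    assay = assay or AssayConstants()
    rng = np.random.default_rng(seed)
    rfu = {}
    for cond in PANEL_CONDITIONS:
        params = profile.condition_params(cond, assay)
        val = fluorescence_curve(params, [endpoint_h], noise,
                                 rng_seed=int(rng.integers(0, 2**31)))[0]
        rfu[cond] = float(val)
    return PanelFluorescence(profile.well_id, rfu)


def simulate_panel_controls(n_controls: int = 16, seed: int = 0,
                            assay: AssayConstants | None = None,
                            noise: NoiseModel | None = None,
                            endpoint_h: float = 48.0) -> pd.DataFrame:
    """Empty-vector control readings per condition (for threshold stats)."""
    assay = assay or AssayConstants()
    rows = []
    for i in range(n_controls):
        ctrl = WellProfile(f"CTRL{i:02d}", "control", "inactive")
        panel = simulate_panel(ctrl, seed=seed * 100003 + i, assay=assay,
                               noise=noise, endpoint_h=endpoint_h)
        for cond, v in panel.rfu.items():
            rows.append({"clone": ctrl.well_id, "condition": cond, "rfu": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# glycan library and electropherogram simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlycanLibraryEntry:
    name: str
    mtu: float  # reference double-normalized migration time (MTU")
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.mtu) or self.mtu <= 0:
            raise ValueError(f"reference MTU must be finite and positive: {self.mtu}")


def builtin_glycan_library() -> list[GlycanLibraryEntry]:
    """Reference N-glycan library with MTU" positions.

    FA2G0-SO4 (150), paucimannose M3 (178), fucosylated paucimannose FM3
    (207) and FA1G0 (245) sit at the positions reported for the real
    migration-time scale. The remaining entries (FA2G0, A2G0, FA2G2,
    FA2G2-SO4, FA2G2S2-SO4) have synthetic fixture positions chosen only to
    be distinct and bracketed by the standards.
    """
    return [
        GlycanLibraryEntry("FA2G2S2-SO4", 95.0, ("sulfated", "sialylated", "fucosylated")),
        GlycanLibraryEntry("FA2G2-SO4", 120.0, ("sulfated", "galactose-capped", "fucosylated")),
        GlycanLibraryEntry("FA2G2", 130.0, ("galactose-capped", "fucosylated")),
        GlycanLibraryEntry("FA2G0-SO4", 150.0, ("terminal-GlcNAc-6-SO4", "fucosylated")),
        GlycanLibraryEntry("M3", 178.0, ("paucimannose",)),
        GlycanLibraryEntry("FM3", 207.0, ("paucimannose", "fucosylated")),
        GlycanLibraryEntry("A2G0", 230.0, ("terminal-GlcNAc",)),
        GlycanLibraryEntry("FA1G0", 245.0, ("terminal-GlcNAc", "fucosylated")),
        GlycanLibraryEntry("FA2G0", 265.0, ("terminal-GlcNAc", "fucosylated")),
    ]


@dataclass(frozen=True)
class StandardSpec:
    """One spiked normalization standard: known reference MTU" and the raw-time
    window in which to search for its peak."""

    name: str
    ref_mtu: float
    window: tuple[float, float]  # raw-time search window (lo, hi)


@dataclass(frozen=True)
class TraceComponent:
    name: str
    mtu: float        # true MTU" position
    abundance: float  # peak height in RFU before noise

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError(f"abundance must be > 0: {self.name}")


#: synthetic two-point normalization standards (the proprietary NormMiX
#: composition is not public); they bracket all library analytes
STD_LOW_MTU = 50.0
STD_HIGH_MTU = 320.0


@dataclass(frozen=True)
class TraceSpec:
    components: tuple[TraceComponent, ...]
    warp_slope: float = 1.0        # raw time per MTU"
    warp_intercept: float = 0.0    # raw-time offset
    warp_curvature: float = 0.0    # mild quadratic distortion (synthetic)
    peak_width: float = 2.0        # Gaussian sigma in raw-time units
    noise_sd: float = 2.0          # baseline noise SD (RFU)
    std_low_mtu: float = STD_LOW_MTU
    std_high_mtu: float = STD_HIGH_MTU
    std_height: float = 500.0
    grid_step: float = 0.25        # raw-time sampling interval
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warp_slope <= 0:
            raise ValueError("warp slope must be > 0 (orientation preserved)")
        for c in self.components:
            if not (self.std_low_mtu < c.mtu < self.std_high_mtu):
                raise ValueError(
                    f"standards must bracket all analytes: {c.name} @ {c.mtu} "
                    f"outside ({self.std_low_mtu}, {self.std_high_mtu})")

    def warp(self, mtu) -> np.ndarray:
        """Map true MTU" to raw migration time."""
        mtu = np.asarray(mtu, dtype=float)
        return (self.warp_intercept + self.warp_slope * mtu
                + self.warp_curvature * mtu ** 2)


@dataclass
class Electropherogram:
    """Uniformly sampled raw trace with standards metadata."""

    times: np.ndarray
    intensities: np.ndarray
    standards: tuple[StandardSpec, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.standards) < 2:
            raise ValueError("need >= 2 declared normalization standards")


def simulate_trace(spec: TraceSpec) -> tuple[Electropherogram, dict]:
    """Simulate a raw electropherogram; returns (trace, truth mapping).

    The truth maps each planted component name to its raw apex time and true
    MTU". Standards are appended as Gaussian peaks at the warped positions of
    their reference MTU" values.
    """
    rng = np.random.default_rng(spec.seed)
    std_specs = (
        StandardSpec("STD-LOW", spec.std_low_mtu,
                     _window(spec, spec.std_low_mtu)),
        StandardSpec("STD-HIGH", spec.std_high_mtu,
                     _window(spec, spec.std_high_mtu)),
    )
    all_peaks = [(s.name, s.ref_mtu, spec.std_height) for s in std_specs]
    all_peaks += [(c.name, c.mtu, c.abundance) for c in spec.components]

    raw_pos = spec.warp([m for _, m, _ in all_peaks])
    lo = raw_pos.min() - 10 * spec.peak_width
    hi = raw_pos.max() + 10 * spec.peak_width
    times = np.arange(lo, hi + spec.grid_step, spec.grid_step)

    intensity = np.zeros_like(times)
    for (name, _mtu, height), pos in zip(all_peaks, raw_pos):
        intensity += height * np.exp(-0.5 * ((times - pos) / spec.peak_width) ** 2)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=times.shape)

    truth = {name: {"raw_time": float(pos), "mtu": float(mtu)}
             for (name, mtu, _h), pos in zip(all_peaks, raw_pos)}
    return Electropherogram(times, intensity, std_specs), truth


def _window(spec: TraceSpec, mtu: float) -> tuple[float, float]:
    """Raw-time search window around a standard's warped position."""
    pos = float(spec.warp(mtu))
    return (pos - 5 * spec.peak_width, pos + 5 * spec.peak_width)


# ---------------------------------------------------------------------------
# exoglycosidase digests and binding-mode depletion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeSpec:
    """A digest enzyme: named substrate->product transitions, or a binding
    mode that depletes substrates without producing products."""

    name: str
    transitions: tuple[tuple[str, str], ...]  # (substrate, product) pairs
    mode: str = "hydrolysis"  # "hydrolysis" | "binding"
    conversion: float = 1.0   # fraction of substrate converted (or depleted)

    def __post_init__(self) -> None:
        if self.mode not in ("hydrolysis", "binding"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.conversion <= 1.0:
            raise ValueError("conversion must be in [0, 1]")
        for sub, prod in self.transitions:
            if self.mode == "hydrolysis" and sub == prod:
                raise ValueError(f"substrate == product in rule for {sub}")


def builtin_enzymes() -> dict[str, EnzymeSpec]:
    """Digest-enzyme fixtures mirroring the characterized activities.

    * F1-ORF13 sulfatase: desulfates FA2G0-SO4 (terminal GlcNAc-6-SO4 only;
      galactose-capped FA2G2-SO4 and sialylated FA2G2S2-SO4 untouched).
    * F1-ORF13 apo (no calcium): binds and depletes FA2G0-SO4, no product.
    * F10-ORF19 hexosaminidase: removes intact GlcNAc-6-SO4 (FA2G0-SO4 ->
      FA1G0) but not asulfated GlcNAc.
    * beta-GlcNAcase S: removes sulfated and asulfated terminal GlcNAc,
      collapsing structures to (fucosylated) paucimannose.
    """
    return {
        "F1_SULFATASE": EnzymeSpec(
            "F1_SULFATASE", (("FA2G0-SO4", "FA2G0"),)),
        "F1_APO_BINDING": EnzymeSpec(
            "F1_APO_BINDING", (("FA2G0-SO4", "FA2G0-SO4"),), mode="binding",
            conversion=0.6),
        "F10_HEXOSAMINIDASE": EnzymeSpec(
            "F10_HEXOSAMINIDASE", (("FA2G0-SO4", "FA1G0"),)),
        "BGLCNACASE_S": EnzymeSpec(
            "BGLCNACASE_S", (("FA2G0-SO4", "FM3"), ("FA2G0", "FM3"),
                             ("FA1G0", "FM3"), ("A2G0", "M3"))),
    }


def simulate_digest_pair(pool: dict[str, float], enzyme: EnzymeSpec,
                         spec: TraceSpec,
                         library: list[GlycanLibraryEntry] | None = None,
                         ) -> tuple[Electropherogram, Electropherogram]:
    """Pre/post electropherogram pair for an enzyme acting on a glycan pool.

    ``pool`` maps library glycan names to abundances (peak heights). The post
    pool applies the enzyme's transitions at its conversion fraction; in
    binding mode substrate abundance is depleted without creating product.
    """
    library = library if library is not None else builtin_glycan_library()
    by_name = {e.name: e for e in library}
    unknown = set(pool) - set(by_name)
    if unknown:
        raise ValueError(f"pool glycans not in library: {sorted(unknown)}")
    for sub, prod in enzyme.transitions:
        if sub not in by_name or prod not in by_name:
            raise ValueError(f"transition {sub}->{prod} references unknown glycan")

    post_pool = dict(pool)
    rules = dict(enzyme.transitions)
    for sub in list(post_pool):
        if sub in rules and post_pool[sub] > 0:
            moved = post_pool[sub] * enzyme.conversion
            post_pool[sub] -= moved
            if enzyme.mode == "hydrolysis":
                post_pool[rules[sub]] = post_pool.get(rules[sub], 0.0) + moved

    def components(p: dict[str, float]) -> tuple[TraceComponent, ...]:
        return tuple(TraceComponent(n, by_name[n].mtu, a)
                     for n, a in sorted(p.items()) if a > 1e-12)

    pre_spec = replace(spec, components=components(pool))
    post_spec = replace(spec, components=components(post_pool),
                        seed=spec.seed + 1)
    pre, _ = simulate_trace(pre_spec)
    post, _ = simulate_trace(post_spec)
    return pre, post


# ---------------------------------------------------------------------------
# plain-text IO (CSV/TSV + JSON sidecar)
# ---------------------------------------------------------------------------

def write_screen_csv(dataset: ScreenDataset, path) -> None:
    dataset.data.to_csv(path, index=False)


def read_screen_csv(path) -> ScreenDataset:
    return ScreenDataset(pd.read_csv(path))


def write_glycan_library_tsv(library: list[GlycanLibraryEntry], path) -> None:
    df = pd.DataFrame([{"name": e.name, "mtu": e.mtu, "tags": ";".join(e.tags)}
                       for e in library])
    df.to_csv(path, sep="\t", index=False)


def read_glycan_library_tsv(path) -> list[GlycanLibraryEntry]:
    df = pd.read_csv(path, sep="\t")
    entries = [GlycanLibraryEntry(r["name"], float(r["mtu"]),
                                  tuple(str(r.get("tags", "") or "").split(";"))
                                  if r.get("tags") else ())
               for r in df.to_dict("records")]
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("glycan library names must be unique")
    return entries


def write_trace_csv(trace: Electropherogram, path, sidecar_path=None) -> None:
    """Two-column CSV (time, intensity) plus a JSON sidecar for standards."""
    pd.DataFrame({"time": trace.times, "intensity": trace.intensities}
                 ).to_csv(path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else Path(path).with_suffix(".standards.json")
    sidecar.write_text(json.dumps({
        "standards": [{"name": s.name, "ref_mtu": s.ref_mtu,
                       "window": list(s.window)} for s in trace.standards]
    }, indent=2))


def read_trace_csv(path, sidecar_path=None) -> Electropherogram:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty trace file: {path}")
    sidecar = Path(sidecar_path) if sidecar_path else Path(path).with_suffix(".standards.json")
    meta = json.loads(Path(sidecar).read_text())
    standards = tuple(StandardSpec(s["name"], float(s["ref_mtu"]),
                                   tuple(s["window"])) for s in meta["standards"])
    return Electropherogram(df["time"].to_numpy(), df["intensity"].to_numpy(),
                            standards)
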