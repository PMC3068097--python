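"""Pollen-accumulation-rate (PAR) palaeodemography.

PAR — pollen grains deposited per cm² of lake-sediment surface per year —
is a proxy for the local population size of a wind-pollinated tree. The
pipeline here goes: age–depth model from calibrated radiocarbon control
points → pollen concentration (exotic-marker spike method) → PAR =
concentration × sedimentation rate → running-mean smoothing → optional
calibration to stem density (trees/ha) → zone statistics and detection of
expansion/bottleneck events from the smoothed trajectory.

Ages are calibrated years before present (cal yr BP, present = AD 1950);
larger ages are older, so event intervals run from a larger (start) to a
smaller (end) age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd


@dataclass
class AgeDepthModel:
    """Piecewise-linear age(depth) from calibrated control points.

    Depths in cm below surface (strictly increasing), ages in cal yr BP
    (strictly increasing with depth; reversals must be screened upstream).
    Prediction outside the dated interval is refused rather than
    extrapolated.
    """

    depths: np.ndarray
    ages: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.depths.size != self.ages.size or self.depths.size < 2:
            raise ValueError("age-depth model needs >= 2 (depth, age) control points")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("control-point depths must be strictly increasing")
        if np.any(np.diff(self.ages) <= 0):
            bad = np.where(np.diff(self.ages) <= 0)[0]
            pairs = [
                (float(self.depths[i]), float(self.ages[i]),
                 float(self.depths[i + 1]), float(self.ages[i + 1]))
                for i in bad
            ]
            raise ValueError(f"age reversal(s) at control points: {pairs}")

    def _check_range(self, depth: np.ndarray) -> None:
        if np.any(depth < self.depths[0]) or np.any(depth > self.depths[-1]):
            raise ValueError(
                f"depth outside dated interval "
                f"[{self.depths[0]}, {self.depths[-1]}] cm; refusing to extrapolate"
            )

    def age(self, depth) -> np.ndarray | float:
        """Interpolated age (cal yr BP) at depth (cm)."""
        d = np.asarray(depth, dtype=float)
        self._check_range(d)
        out = np.interp(d, self.depths, self.ages)
        return float(out) if np.isscalar(depth) else out

    def sedimentation_rate(self, depth) -> np.ndarray | float:
        """Deposition rate (cm/yr): reciprocal slope of the containing segment."""
        d = np.atleast_1d(np.asarray(depth, dtype=float))
        self._check_range(d)
        seg = np.clip(np.searchsorted(self.depths, d, side="right") - 1, 0,
                      self.depths.size - 2)
        rate = (self.depths[seg + 1] - self.depths[seg]) / (
            self.ages[seg + 1] - self.ages[seg]
        )
        return float(rate[0]) if np.isscalar(depth) else rate


def build_age_depth_model(control_points: Sequence[tuple[float, float]] | pd.DataFrame) -> AgeDepthModel:
    """Build an :class:`AgeDepthModel` from (depth_cm, age_calBP) points."""
    if isinstance(control_points, pd.DataFrame):
        depths = control_points["depth_cm"].to_numpy()
        ages = control_points["age_calBP"].to_numpy()
    else:
        pts = np.asarray(control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError("need >= 2 control points")
        depths, ages = pts[:, 0], pts[:, 1]
    return AgeDepthModel(depths, ages)


def compute_concentration(
    pollen_count: float, spike_count: float, spike_added: float, volume_cm3: float
) -> float:
    """Exotic-marker concentration estimate (grains/cm³).

    concentration = pollen_count × (spike_added / spike_count) / volume.
    """
    if spike_count <= 0:
        raise ValueError("spike_count must be positive (concentration undefined)")
    if volume_cm3 <= 0:
        raise ValueError("sample volume must be positive")
    if pollen_count < 0:
        raise ValueError("pollen count cannot be negative")
    return pollen_count * (spike_added / spike_count) / volume_cm3


def compute_par(
    concentrations: Sequence[float],
    depths: Sequence[float],
    model: AgeDepthModel,
) -> pd.DataFrame:
    """PAR series: PAR_i = concentration_i × sedimentation_rate(depth_i).

    Returns a DataFrame with depth_cm, age_calBP, concentration, sed_rate
    and par columns, sorted by age descending (oldest first).
    """
    conc = np.asarray(concentrations, dtype=float)
    d = np.asarray(depths, dtype=float)
    if conc.size != d.size:
        raise ValueError("concentrations and depths differ in length")
    if np.any(conc < 0):
        raise ValueError("negative concentration")
    rate = np.atleast_1d(model.sedimentation_rate(d))
    df = pd.DataFrame(
        {
            "depth_cm": d,
            "age_calBP": np.atleast_1d(model.age(d)),
            "concentration": conc,
            "sed_rate": rate,
            "par": conc * rate,
        }
    )
    return df.sort_values("age_calBP", ascending=False, ignore_index=True)


def smooth_par(series: pd.DataFrame, window: int = 3, column: str = "par") -> pd.DataFrame:
    """Centered running mean; endpoints use the available (shrinking) window."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    out = series.copy()
    out["par_smooth"] = (
        out[column].rolling(window, center=True, min_periods=1).mean()
    )
    return out


@dataclass
class DensityCalibration:
    """Power-law PAR → stem density mapping: trees/ha = a × PAR^b.

    Coefficients default to a fit through two published anchor pairs for
    boreal spruce woodland (PAR 200 → 9 trees/ha, PAR 7000 → 101 trees/ha);
    the provenance note travels with every output because such transfer
    functions are region-specific and indicative at best.
    """

    a: float
    b: float
    provenance: str

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("calibration must be strictly increasing (a, b > 0)")

    @classmethod
    def from_anchors(
        cls,
        p1: tuple[float, float] = (200.0, 9.0),
        p2: tuple[float, float] = (7000.0, 101.0),
        provenance: str = (
            "power law through anchor pairs (200, 9) and (7000, 101) "
            "grains cm-2 yr-1 -> trees/ha; indicative only"
        ),
    ) -> "DensityCalibration":
        (x1, y1), (x2, y2) = p1, p2
        b = float(np.log(y2 / y1) / np.log(x2 / x1))
        a = float(y1 / x1**b)
        return cls(a, b, provenance)

    def density(self, par) -> np.ndarray | float:
        p = np.asarray(par, dtype=float)
        if np.any(p < 0):
            raise ValueError("PAR cannot be negative")
        out = self.a * p**self.b
        return float(out) if np.isscalar(par) else out


def par_to_density(par, calibration: DensityCalibration | None = None):
    """Convert PAR to approximate stem density (trees/ha)."""
    calibration = calibration or DensityCalibration.from_anchors()
    return calibration.density(par)


def zone_statistics(
    series: pd.DataFrame, zone_boundaries: Sequence[float], column: str = "par"
) -> pd.DataFrame:
    """Mean/min/max PAR per age zone.

    ``zone_boundaries`` are ages (cal yr BP) splitting the series into
    len(boundaries)+1 zones from oldest to youngest; zones with zero or one
    sample are flagged, never silently averaged away.
    """
    ages = series["age_calBP"].to_numpy()
    bounds = sorted(zone_boundaries, reverse=True)
    edges = [np.inf] + list(bounds) + [-np.inf]
    rows = []
    for i, (old, young) in enumerate(zip(edges, edges[1:])):
        mask = (ages <= old) & (ages > young)
        vals = series.loc[mask, column]
        rows.append(
            {
                "zone": i + 1,
                "age_from": old if np.isfinite(old) else float(ages.max()),
                "age_to": young if np.isfinite(young) else float(ages.min()),
                "n": int(mask.sum()),
                "mean": vals.mean() if mask.sum() else np.nan,
                "min": vals.min() if mask.sum() else np.nan,
                "max": vals.max() if mask.sum() else np.nan,
                "flag": "" if mask.sum() > 1 else ("empty" if mask.sum() == 0 else "n=1"),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DemographicEvent:
    """An inferred expansion or bottleneck interval.

    ``start_age > end_age`` (cal yr BP decreases toward the present);
    ``magnitude`` is the ratio of the smoothed-PAR extrema bounding the
    swing (> 1 for both kinds).
    """

    kind: Literal["expansion", "bottleneck"]
    start_age: float
    end_age: float
    magnitude: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.start_age <= self.end_age:
            raise ValueError("event must run from older (start) to younger (end) age")
        if self.magnitude <= 1:
            raise ValueError("event magnitude must exceed 1")


def detect_events(
    series: pd.DataFrame,
    rise_threshold: float = 2.0,
    fall_threshold: float = 0.5,
    min_duration: float = 200.0,
    column: str = "par_smooth",
) -> list[DemographicEvent]:
    """Detect expansions and bottlenecks in a smoothed PAR trajectory.

    Scanning from oldest to youngest sample: an *expansion* is a confirmed
    rise of >= ``rise_threshold``× from the running minimum (dated at the
    last sample attaining that minimum, ending at the subsequent peak); a
    *bottleneck* begins at a local maximum followed by a decline to
    <= ``fall_threshold``× that stays below threshold for at least
    ``min_duration`` years. Thresholds are ratios, so detection is
    invariant to uniform rescaling of the series.
    """
    if rise_threshold <= 0 or fall_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if fall_threshold >= 1:
        raise ValueError("fall_threshold must be < 1")
    if column not in series:
        raise ValueError(f"series lacks column {column!r}; smooth it first")
    if len(series) < 5:
        raise ValueError("need at least 5 samples for event detection")

    df = series.sort_values("age_calBP", ascending=False, ignore_index=True)
    vals = df[column].to_numpy(dtype=float)
    ages = df["age_calBP"].to_numpy(dtype=float)
    eps = 1e-12

    events: list[DemographicEvent] = []
    # "down" also covers the initial search phase: run_max is the local
    # maximum since the last event, run_min the running minimum since then
    # (ties resolved toward the youngest sample, so a flat trough is dated
    # at its departure point).
    mode = "down"
    run_max_v, run_max_a = vals[0], ages[0]
    run_min_v, run_min_a = vals[0], ages[0]
    cross_age: float | None = None  # first age below the fall threshold

    def emit_bottleneck() -> None:
        events.append(
            DemographicEvent(
                "bottleneck", run_max_a, run_min_a,
                run_max_v / max(run_min_v, eps),
            )
        )

    for v, a in zip(vals[1:], ages[1:]):
        if mode == "down":
            # the rise trigger uses the running minimum *before* this
            # sample can reset it, so a monotone climb is still seen as
            # one swing from its trough
            if v > run_min_v and v >= rise_threshold * max(run_min_v, eps) - eps:
                mode = "up"
                pending_min_v, pending_min_a = run_min_v, run_min_a
                run_max_v, run_max_a = v, a
                cross_age = None
                continue
            if v >= run_max_v:
                # ties advance the age: a flat plateau is dated at its
                # departure point, where the decline actually begins
                run_max_v, run_max_a = v, a
                cross_age = None
            if v <= run_min_v:
                run_min_v, run_min_a = v, a
            if cross_age is None and v <= fall_threshold * run_max_v + eps:
                cross_age = a
            if cross_age is not None and v > fall_threshold * run_max_v + eps:
                # recovered above threshold before the decline was sustained
                if cross_age - a < min_duration:
                    cross_age = None
            if cross_age is not None and cross_age - a >= min_duration:
                emit_bottleneck()
                # re-arm so a later rebound-and-crash is a fresh event
                run_max_v, run_max_a = v, a
                cross_age = None
        else:  # mode == "up"
            if v >= run_max_v:
                run_max_v, run_max_a = v, a
            if v <= fall_threshold * run_max_v + eps:
                events.append(
                    DemographicEvent(
                        "expansion", pending_min_a, run_max_a,
                        run_max_v / max(pending_min_v, eps),
                    )
                )
                mode = "down"
                run_min_v, run_min_a = v, a
                cross_age = a

    if mode == "up":
        events.append(
            DemographicEvent(
                "expansion", pending_min_a, run_max_a,
                run_max_v / max(pending_min_v, eps),
            )
        )
    elif cross_age is not None and cross_age - ages[-1] >= min_duration:
        emit_bottleneck()
    return events


def plot_par(series: pd.DataFrame, path, events: Iterable[DemographicEvent] = ()) -> None:
    """Basic PAR figure: raw series, running mean, event markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(series["age_calBP"], series["par"], lw=0.8, label="PAR")
    if "par_smooth" in series:
        ax.plot(series["age_calBP"], series["par_smooth"], "--", label="running mean")
    for ev in events:
        color = "tab:green" if ev.kind == "expansion" else "tab:red"
        ax.axvspan(ev.start_age, ev.end_age, alpha=0.15, color=color)
    ax.set_xlabel("age (cal yr BP)")
    ax.set_ylabel("PAR (grains cm$^{-2}$ yr$^{-1}$)")
    ax.invert_xaxis()
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
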