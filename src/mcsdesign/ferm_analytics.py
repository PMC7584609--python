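"""Fermentation quantification and titer/rate/yield (TRY) analytics.

Converts raw plate-reader observables to concentrations (indigoidine
standard curve on OD612, dry-cell-weight conversion on OD600), derives the
TRY triple plus %-of-maximum-theoretical-yield from a time course, and
classifies whether production is growth-associated or stationary-phase.

Standard curve: ``g/L = 0.212 * OD612 - 0.0035`` (average of independent
calibrations on purified pigment). DCW: ``1.0 OD600 = 0.38 g/L``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "FermentationTimeCourse",
    "TRYReport",
    "od612_to_indigoidine",
    "od600_to_dcw",
    "compute_try",
    "fold_change",
    "classify_production_phase",
    "STANDARD_CURVE_SLOPE",
    "STANDARD_CURVE_INTERCEPT",
    "DCW_PER_OD600",
]

STANDARD_CURVE_SLOPE = 0.212  # g/L per OD612
STANDARD_CURVE_INTERCEPT = -0.0035  # g/L
DCW_PER_OD600 = 0.38  # gDCW/L per OD600


@dataclass
class FermentationTimeCourse:
    """A batch or fed-batch cultivation record.

    ``feed_events`` lists (time_h, substrate_g) boluses on a per-litre
    basis (use ``volume_l`` for an explicit reactor volume).
    """

    time: np.ndarray  # h, strictly increasing
    substrate: np.ndarray  # g/L
    product: np.ndarray  # g/L
    od600: np.ndarray | None = None
    od612: np.ndarray | None = None
    feed_events: list[tuple[float, float]] = field(default_factory=list)
    volume_l: float | None = None
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        if self.od600 is not None:
            self.od600 = np.asarray(self.od600, dtype=float)
        if self.od612 is not None:
            self.od612 = np.asarray(self.od612, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("substrate", "product"):
            arr = getattr(self, name)
            if arr.shape != self.time.shape:
                raise ValueError(f"{name} length does not match time")
            if np.any(arr < 0):
                warnings.warn(f"negative {name} values clamped to 0", stacklevel=2)
                setattr(self, name, np.clip(arr, 0, None))

    @property
    def n(self) -> int:
        return len(self.time)

    @classmethod
    def from_csv(
        cls, path: str | Path, feed_path: str | Path | None = None, label: str = ""
    ) -> "FermentationTimeCourse":
        """Read a course from CSV with header
        ``time_h,od600,od612,substrate_gL,product_gL`` (od columns optional)."""
        df = pd.read_csv(path)
        required = {"time_h", "substrate_gL", "product_gL"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        bad = df["time_h"].isna()
        if bad.any():
            raise ValueError(f"{path}: unparseable time at row {int(bad.idxmax()) + 2}")
        feeds: list[tuple[float, float]] = []
        if feed_path is not None:
            fdf = pd.read_csv(feed_path)
            feeds = [(float(t), float(g)) for t, g in zip(fdf["time_h"], fdf["substrate_g"])]
        return cls(
            time=df["time_h"].to_numpy(),
            substrate=df["substrate_gL"].to_numpy(),
            product=df["product_gL"].to_numpy(),
            od600=df["od600"].to_numpy() if "od600" in df else None,
            od612=df["od612"].to_numpy() if "od612" in df else None,
            feed_events=feeds,
            label=label or Path(path).stem,
        )

    def to_csv(self, path: str | Path) -> None:
        cols = {"time_h": self.time}
        if self.od600 is not None:
            cols["od600"] = self.od600
        if self.od612 is not None:
            cols["od612"] = self.od612
        cols["substrate_gL"] = self.substrate
        cols["product_gL"] = self.product
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class TRYReport:
    titer: float  # g/L
    rate_overall: float  # g/L/h
    rate_window_max: float  # g/L/h
    rate_window: tuple[float, float]  # h
    yield_gg: float | None  # g product / g substrate consumed
    yield_gg_supplied: float | None  # g product / g substrate supplied
    percent_mty: float | None
    phase_class: str | None = None
    growth_phase_fraction: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        d["units"] = {
            "titer": "g/L",
            "rate_overall": "g/L/h",
            "rate_window_max": "g/L/h",
            "yield_gg": "g/g",
            "percent_mty": "%",
        }
        return json.dumps(d, indent=1, default=list)


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------


def od612_to_indigoidine(od612, clamp: bool = True):
    """Indigoidine concentration (g/L) from DMSO-extract absorbance at 612 nm.

    The calibration has a small negative intercept, so very low readings
    map below zero; reported values are clamped at 0 by default while the
    raw affine value is available with ``clamp=False``.
    """
    od612 = np.asarray(od612, dtype=float)
    if np.any(od612 < 0):
        raise ValueError("OD612 must be >= 0")
    raw = STANDARD_CURVE_SLOPE * od612 + STANDARD_CURVE_INTERCEPT
    out = np.clip(raw, 0.0, None) if clamp else raw
    return out.item() if out.ndim == 0 else out


def od600_to_dcw(od600):
    """Dry cell weight (g/L) from culture OD600 (linear, 0.38 g/L per OD)."""
    od600 = np.asarray(od600, dtype=float)
    if np.any(od600 < 0):
        raise ValueError("OD600 must be >= 0")
    out = DCW_PER_OD600 * od600
    return out.item() if out.ndim == 0 else out


def fold_change(engineered_titer: float, control_titer: float, rounding: str = "report"):
    """Engineered/control titer ratio.

    ``rounding='report'`` rounds to the nearest integer above 10-fold and
    to one decimal below (the convention used when quoting improvements);
    ``rounding='none'`` returns the raw ratio. A non-positive control
    titer makes the ratio undefined (returns ``nan``).
    """
    if control_titer <= 0:
        warnings.warn("control titer <= 0; fold change undefined", stacklevel=2)
        return float("nan")
    ratio = engineered_titer / control_titer
    if rounding == "none":
        return ratio
    return round(ratio) if ratio >= 10 else round(ratio, 1)


# ---------------------------------------------------------------------------
# TRY metrics
# ---------------------------------------------------------------------------


def _sliding_slope(t: np.ndarray, y: np.ndarray, window: int) -> tuple[float, tuple[float, float]]:
    """Max least-squares slope of y(t) over contiguous windows of ``window`` points."""
    best, span = -np.inf, (t[0], t[-1])
    for i in range(len(t) - window + 1):
        tt, yy = t[i : i + window], y[i : i + window]
        slope = np.polyfit(tt, yy, 1)[0]
        if slope > best:
            best, span = slope, (float(tt[0]), float(tt[-1]))
    return float(best), span


def compute_try(
    tc: FermentationTimeCourse,
    mty_gg: float | None = None,
    rate_window_points: int = 3,
) -> TRYReport:
    """Titer, rates, yields and %MTY from one time course.

    Yield is reported on two bases: substrate *consumed* (initial charge
    plus feeds minus residual) and substrate *supplied* (initial charge
    plus feeds). ``percent_mty`` uses the consumed basis.
    """
    if tc.n < 3:
        raise ValueError("need at least 3 time points")
    flags: list[str] = []
    i_max = int(np.argmax(tc.product))
    titer = float(tc.product[i_max])
    dt = tc.time[i_max] - tc.time[0]
    rate_overall = float((titer - tc.product[0]) / dt) if dt > 0 else 0.0
    window = min(rate_window_points, tc.n)
    rate_max, span = _sliding_slope(tc.time, tc.product, window)

    fed = sum(g for _, g in tc.feed_events)
    consumed = float(tc.substrate[0] - tc.substrate[-1] + fed)
    supplied = float(tc.substrate[0] + fed)
    delta_p = float(tc.product[-1] - tc.product[0])
    if consumed <= 0:
        flags.append("substrate_consumed_nonpositive_yield_undefined")
        y_cons = None
    else:
        y_cons = delta_p / consumed
    y_sup = delta_p / supplied if supplied > 0 else None
    pct = 100.0 * y_cons / mty_gg if (y_cons is not None and mty_gg) else None
    if mty_gg and y_cons is not None and y_cons > mty_gg:
        flags.append("yield_exceeds_theoretical_max")
        warnings.warn("observed yield exceeds supplied theoretical maximum", stacklevel=2)

    phase_class = None
    frac = None
    if tc.od600 is not None:
        if titer <= 0:
            phase_class, frac = "degenerate", None
            flags.append("zero_production_phase_undefined")
        else:
            try:
                phase_class, frac, _ = classify_production_phase(tc)
            except ValueError as e:
                phase_class = "degenerate"
                flags.append(str(e))
    return TRYReport(
        titer=titer,
        rate_overall=rate_overall,
        rate_window_max=rate_max,
        rate_window=span,
        yield_gg=y_cons,
        yield_gg_supplied=y_sup,
        percent_mty=pct,
        phase_class=phase_class,
        growth_phase_fraction=frac,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Production-phase classification
# ---------------------------------------------------------------------------


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window edges keep the raw values."""
    if window <= 1 or len(y) < window:
        return y
    kernel = np.ones(window) / window
    out = np.convolve(y, kernel, mode="same")
    h = window // 2
    out[:h], out[-h:] = y[:h], y[-h:]
    return out


def _drop_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Remove True runs shorter than ``min_run`` (noise-induced blips)."""
    out = mask.copy()
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            if j - i < min_run:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


def _mu_max(t: np.ndarray, ln_od: np.ndarray, fit_points: int = 4) -> float:
    """Specific growth rate from a log-linear fit over the steepest window."""
    k = min(fit_points, len(t))
    best = 0.0
    for i in range(len(t) - k + 1):
        slope = np.polyfit(t[i : i + k], ln_od[i : i + k], 1)[0]
        best = max(best, float(slope))
    return best


def classify_production_phase(
    tc: FermentationTimeCourse,
    mu_threshold_fraction: float = 0.05,
    growth_fraction_cutoff: tuple[float, float] = (0.3, 0.7),
    smooth_points: int = 5,
    min_run: int = 3,
) -> tuple[str, float, float]:
    """Label a course growth_associated / stationary / mixed.

    The smoothed specific growth rate mu(t) = d ln(OD)/dt defines the
    growth phase (mu above ``mu_threshold_fraction`` of mu_max, keeping
    only runs of at least ``min_run`` samples so assay noise cannot open
    spurious growth windows). Production is attributed per interval from
    the smoothed product trace, and the classification is by the fraction
    of total product formed inside the growth phase: >= 0.7
    growth_associated, <= 0.3 stationary, else mixed.
    Returns ``(class, fraction, mu_max)``.
    """
    if tc.od600 is None:
        raise ValueError("od600 required for phase classification")
    od = np.clip(tc.od600, 1e-6, None)
    if np.ptp(od) < 1e-9:
        raise ValueError("constant OD: phase classification undefined")
    ln_od = np.log(od)
    ln_s = _smooth(ln_od, smooth_points)
    prod_s = _smooth(tc.product, smooth_points)
    mu = np.gradient(ln_s, tc.time)
    mu_max = _mu_max(tc.time, ln_od)
    if mu_max <= 0:
        raise ValueError("no positive growth detected: phase classification undefined")
    growing = _drop_short_runs(mu > mu_threshold_fraction * mu_max, min_run)

    dp = np.diff(prod_s)
    total = prod_s[-1] - prod_s[0]
    if total <= 0:
        raise ValueError("no net production: phase classification undefined")
    # attribute each interval's net production to growth if either endpoint grows
    interval_growing = growing[:-1] | growing[1:]
    frac = float(np.clip(dp[interval_growing].sum() / total, 0.0, 1.0))
    lo, hi = growth_fraction_cutoff
    if frac >= hi:
        cls = "growth_associated"
    elif frac <= lo:
        cls = "stationary"
    else:
        cls = "mixed"
    return cls, frac, mu_max
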