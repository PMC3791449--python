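"""From raw retraction curves to a table of specific rupture events.

A retraction curve records cantilever force against tip--sample separation
while a functionalized tip is pulled away from the surface. The sign
convention is that of the deflection signal: force is *negative* while the
tether loads the cantilever (attraction), and a rupture appears as an abrupt
positive jump back to the zero baseline.

The pipeline stages are: read/validate (`read_curves`), baseline correction
(`baseline_correct`), rupture-candidate detection (`detect_rupture`),
worm-like-chain fitting of the loading stretch (`fit_wlc`), apparent
loading-rate estimation (`apparent_loading_rate`), and specificity filtering
on fitted contour length (`filter_specific`). `extract_events` chains them
over a curve collection and returns an events table plus a rejects table
with per-curve rejection reasons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd

from .core_model import PhysicalConstants, WLCParams, wlc_force

__all__ = [
    "ForceCurve",
    "RuptureEvent",
    "CurveFormatError",
    "BaselineError",
    "read_curve",
    "read_curves",
    "write_curve",
    "baseline_correct",
    "detect_rupture",
    "fit_wlc",
    "apparent_loading_rate",
    "filter_specific",
    "extract_events",
]

_REQUIRED_METADATA = ("spring_constant_pN_per_nm", "speed_nm_per_s", "sampling_hz", "curve_id")


class CurveFormatError(ValueError):
    """Raised when a curve file violates the documented TSV dialect."""


class BaselineError(ValueError):
    """Raised when a curve has too few free-baseline points to correct."""


@dataclass
class ForceCurve:
    """One retraction trace: separation (nm) vs force (pN) plus acquisition metadata."""

    separation: np.ndarray
    force: np.ndarray
    spring_constant: float  # pN/nm
    speed: float            # nm/s
    sampling_rate: float    # Hz
    curve_id: str

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.separation.shape != self.force.shape:
            raise CurveFormatError(
                f"curve {self.curve_id}: separation/force length mismatch"
            )
        if self.separation.size < 100:
            raise CurveFormatError(
                f"curve {self.curve_id}: needs >= 100 points, got {self.separation.size}"
            )
        if np.any(np.diff(self.separation) < 0):
            raise CurveFormatError(
                f"curve {self.curve_id}: separation must be monotone non-decreasing"
            )

    @property
    def time(self) -> np.ndarray:
        """Time axis in s, reconstructed from the sampling rate."""
        return np.arange(self.separation.size) / self.sampling_rate


@dataclass
class RuptureEvent:
    """One detected specific unbinding event with its WLC-fit diagnostics."""

    curve_id: str
    rupture_force: float          # pN, positive magnitude
    rupture_distance: float       # nm, separation at rupture
    contour_length: float         # nm, from WLC fit
    persistence_length: float     # nm, from WLC fit
    apparent_loading_rate: float  # pN/s
    fit_rss: float
    rupture_index: int = 0
    n_candidates_on_curve: int = 1
    flag: str = "ok"              # ok | unfit | nonpositive_rate


def write_curve(curve: ForceCurve, path: str | Path) -> None:
    """Write a curve in the package TSV dialect (# key=value header lines)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# curve_id={curve.curve_id}\n")
        fh.write(f"# spring_constant_pN_per_nm={curve.spring_constant:.6g}\n")
        fh.write(f"# speed_nm_per_s={curve.speed:.6g}\n")
        fh.write(f"# sampling_hz={curve.sampling_rate:.6g}\n")
        fh.write("separation_nm\tforce_pN\n")
        for s, f in zip(curve.separation, curve.force):
            fh.write(f"{s:.6g}\t{f:.6g}\n")


def read_curve(path: str | Path) -> ForceCurve:
    """Read one TSV curve file; malformed files raise CurveFormatError."""
    path = Path(path)
    meta: dict[str, str] = {}
    data_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
        else:
            data_start = i
            break
    for key in _REQUIRED_METADATA:
        if key not in meta:
            raise CurveFormatError(f"{path}: missing metadata key '{key}'")
    try:
        table = pd.read_csv(
            path, sep="\t", comment="#", header=0, skiprows=data_start,
            names=None, engine="c",
        )
        sep = table["separation_nm"].to_numpy(float)
        force = table["force_pN"].to_numpy(float)
    except (KeyError, ValueError) as exc:
        raise CurveFormatError(f"{path}: bad data section ({exc})") from exc
    return ForceCurve(
        separation=sep,
        force=force,
        spring_constant=float(meta["spring_constant_pN_per_nm"]),
        speed=float(meta["speed_nm_per_s"]),
        sampling_rate=float(meta["sampling_hz"]),
        curve_id=meta["curve_id"],
    )


def read_curves(path: str | Path, pattern: str = "*.tsv") -> list[ForceCurve]:
    """Read every curve file under ``path`` (sorted by name for determinism)."""
    path = Path(path)
    files = sorted(path.glob(pattern))
    if not files:
        raise CurveFormatError(f"no curve files matching {pattern} under {path}")
    return [read_curve(f) for f in files]


def _far_mask(curve: ForceCurve, tether_span: float) -> np.ndarray:
    return curve.separation > 1.2 * tether_span


def baseline_correct(curve: ForceCurve, tether_span: float = 70.0,
                     min_far_fraction: float = 0.2) -> ForceCurve:
    """Remove force offset and linear drift using the far-from-surface region.

    The region beyond 1.2x the expected maximum tether span carries no tether
    load; a first-order polynomial fitted there is subtracted from the whole
    trace. Curves with fewer than ``min_far_fraction`` of their points in the
    far region (e.g. all-contact curves) raise BaselineError.
    """
    mask = _far_mask(curve, tether_span)
    if mask.sum() < min_far_fraction * curve.separation.size:
        raise BaselineError(
            f"curve {curve.curve_id}: only {int(mask.sum())} free-baseline points"
        )
    coef = np.polyfit(curve.separation[mask], curve.force[mask], 1)
    corrected = curve.force - np.polyval(coef, curve.separation)
    return replace(curve, force=corrected)


def _robust_noise_sd(curve: ForceCurve, tether_span: float) -> float:
    """Noise sd from the median absolute deviation of the baseline region."""
    mask = _far_mask(curve, tether_span)
    region = curve.force[mask] if mask.sum() >= 20 else curve.force
    mad = np.median(np.abs(region - np.median(region)))
    return float(1.4826 * mad)


def detect_rupture(curve: ForceCurve, tether_span: float = 70.0,
                   min_jump: float = 15.0, noise_factor: float = 4.0,
                   window: int = 4, smooth: int = 5) -> list[int]:
    """Locate rupture candidates: sharp force release back toward baseline.

    A candidate is a force increase exceeding max(noise_factor * robust
    noise sd, min_jump) within at most ``window`` sampling intervals,
    starting from an attractive (negative) force level. Detection runs on a
    lightly boxcar-smoothed trace (a raw point-to-point jump statistic on
    thousands of noisy samples would fire on noise extremes alone); each
    candidate index is then refined to the most attractive raw point of its
    release edge, i.e. the last loaded sample. Returns candidates ordered by
    separation; an empty list is a valid result (blank curve).
    """
    raw = curve.force
    kernel = np.ones(max(1, smooth)) / max(1, smooth)
    f = np.convolve(raw, kernel, mode="same")
    smoothed = replace(curve, force=f)
    sd = _robust_noise_sd(smoothed, tether_span)
    threshold = max(noise_factor * sd, min_jump)
    n = f.size
    jump = np.full(n, -np.inf)
    for w in range(1, window + 1):
        jump[: n - w] = np.maximum(jump[: n - w], f[w:] - f[:-w])
    hit = (jump > threshold) & (f < -0.5 * threshold)
    if not hit.any():
        return []
    # group nearby hits into one candidate each
    idx = np.flatnonzero(hit)
    groups: list[list[int]] = [[idx[0]]]
    for i in idx[1:]:
        if i - groups[-1][-1] <= window + smooth:
            groups[-1].append(i)
        else:
            groups.append([i])
    candidates = []
    for g in groups:
        lo = max(0, g[0] - smooth)
        hi = min(n - 1, g[-1] + smooth)
        local = np.arange(lo, hi + 1)
        candidates.append(int(local[np.argmin(raw[local])]))  # most negative = rupture
    return sorted(set(candidates))


def _stretch_start(curve: ForceCurve, rupture_index: int, noise_sd: float,
                   smooth: int = 5) -> int:
    """Walk back from the rupture to the last zero-force crossing.

    The crossing is located on a boxcar-smoothed trace so that single noise
    excursions through the zero level cannot truncate the loading stretch.
    """
    f = np.convolve(curve.force, np.ones(smooth) / smooth, mode="same")
    level = -max(3.0 * noise_sd / math.sqrt(smooth), 2.0)
    i = rupture_index
    while i > 0 and f[i - 1] < level:
        i -= 1
    return i


def fit_wlc(curve: ForceCurve, rupture_index: int, tether_span: float = 70.0,
            fit_persistence: bool = True, persistence_fixed: float = 0.38,
            p_bounds: tuple[float, float] = (0.1, 1.0), lc_max: float = 120.0,
            min_points: int = 20,
            constants: PhysicalConstants = PhysicalConstants()) -> RuptureEvent:
    """Fit the loading stretch before a rupture candidate with a WLC.

    Nonlinear least squares of the Marko--Siggia force over the stretch from
    the last zero-force crossing to the rupture point. Persistence length is
    fitted within ``p_bounds`` by default (the tether is a PEG--peptide
    composite) or held at ``persistence_fixed``. The rupture force is the
    fitted model force at the rupture separation, which suppresses the
    single-point noise of the raw last sample. Non-convergent or
    boundary-pinned fits are flagged "unfit".
    """
    sd = _robust_noise_sd(curve, tether_span)
    start = _stretch_start(curve, rupture_index, sd)
    x = curve.separation[start: rupture_index + 1]
    y = -curve.force[start: rupture_index + 1]
    x_rupt = float(curve.separation[rupture_index])

    def _flagged() -> RuptureEvent:
        return RuptureEvent(
            curve_id=curve.curve_id, rupture_force=float(max(y[-1], 0.0)) if y.size else 0.0,
            rupture_distance=x_rupt, contour_length=math.nan,
            persistence_length=math.nan, apparent_loading_rate=math.nan,
            fit_rss=math.nan, rupture_index=rupture_index, flag="unfit",
        )

    if x.size < min_points:
        return _flagged()

    lc_min = x_rupt * (1.0 + 1e-6) + 1e-6
    if lc_min >= lc_max:
        return _flagged()
    params = lmfit.Parameters()
    params.add("lc", value=min(max(x_rupt / 0.85, lc_min * 1.05), lc_max * 0.99),
               min=lc_min, max=lc_max)
    if fit_persistence:
        params.add("p", value=persistence_fixed, min=p_bounds[0], max=p_bounds[1])
    else:
        params.add("p", value=persistence_fixed, vary=False)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        w = WLCParams(persistence_length=pars["p"].value, contour_length=pars["lc"].value)
        return wlc_force(x, w, constants) - y

    try:
        result = lmfit.minimize(residual, params, method="least_squares")
    except Exception:
        return _flagged()
    if not result.success:
        return _flagged()
    lc = float(result.params["lc"].value)
    p = float(result.params["p"].value)
    pinned = lc >= lc_max * (1 - 1e-3) or lc <= lc_min * (1 + 1e-3)
    if fit_persistence:
        span = p_bounds[1] - p_bounds[0]
        pinned = pinned or p <= p_bounds[0] + 1e-3 * span or p >= p_bounds[1] - 1e-3 * span
    if pinned:
        return _flagged()
    wfit = WLCParams(persistence_length=p, contour_length=lc)
    f_rupt = float(wlc_force(x_rupt, wfit, constants))
    return RuptureEvent(
        curve_id=curve.curve_id, rupture_force=f_rupt, rupture_distance=x_rupt,
        contour_length=lc, persistence_length=p, apparent_loading_rate=math.nan,
        fit_rss=float(np.sum(np.asarray(result.residual) ** 2)),
        rupture_index=rupture_index, flag="ok",
    )


def apparent_loading_rate(curve: ForceCurve, event: RuptureEvent,
                          tail_fraction: float = 0.1,
                          min_points: int = 10) -> RuptureEvent:
    """Loading rate (pN/s) from a linear fit of force vs time just before rupture.

    The slope is taken over the final ``tail_fraction`` of the points before
    the rupture (at least ``min_points``). A non-positive slope flags the
    event.
    """
    n_tail = max(min_points, int(round(tail_fraction * event.rupture_index)))
    i0 = max(0, event.rupture_index - n_tail + 1)
    if event.rupture_index - i0 + 1 < min_points:
        return replace(event, flag="nonpositive_rate", apparent_loading_rate=math.nan)
    t = curve.time[i0: event.rupture_index + 1]
    y = -curve.force[i0: event.rupture_index + 1]
    slope = float(np.polyfit(t, y, 1)[0])
    if slope <= 0:
        return replace(event, flag="nonpositive_rate", apparent_loading_rate=math.nan)
    return replace(event, apparent_loading_rate=slope)


def filter_specific(events: Sequence[RuptureEvent], linker_total: float,
                    inter_terminus: float, n_residues: int,
                    per_residue_length: float, lo_margin: float = 3.0,
                    hi_margin: float = 5.0) -> tuple[list[RuptureEvent], list[tuple[str, str]]]:
    """Keep specific single-rupture events by their fitted contour length.

    The acceptance window spans the geometry of the tethered dimer: from the
    linker stack alone (minus ``lo_margin``) to the linkers plus the
    inter-terminus gap plus both fully stretched monomers (plus ``hi_margin``).
    Curves with more than one rupture candidate are discarded as ambiguous.
    Returns (kept events, [(curve_id, reason), ...]).
    """
    lo = linker_total - lo_margin
    hi = linker_total + inter_terminus + 2.0 * n_residues * per_residue_length + hi_margin
    kept: list[RuptureEvent] = []
    rejected: list[tuple[str, str]] = []
    for ev in events:
        if ev.flag != "ok":
            rejected.append((ev.curve_id, ev.flag))
        elif ev.n_candidates_on_curve > 1:
            rejected.append((ev.curve_id, "multi_rupture"))
        elif not (lo <= ev.contour_length <= hi):
            rejected.append((ev.curve_id, "lc_out_of_window"))
        else:
            assert ev.contour_length > ev.rupture_distance
            assert ev.apparent_loading_rate > 0
            kept.append(ev)
    return kept, rejected


def extract_events(curves: Iterable[ForceCurve], linker_total: float = 24.5,
                   inter_terminus: float = 1.0, n_residues: int = 41,
                   per_residue_length: float = 0.41, tether_span: float = 70.0,
                   min_jump: float = 15.0, fit_persistence: bool = True,
                   constants: PhysicalConstants = PhysicalConstants(),
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full curve pipeline and return (events, rejects) DataFrames.

    Curves are processed in curve_id order so repeated runs on the same
    inputs are byte-identical.
    """
    events: list[RuptureEvent] = []
    rejects: list[tuple[str, str]] = []
    for curve in sorted(curves, key=lambda c: c.curve_id):
        try:
            corrected = baseline_correct(curve, tether_span=tether_span)
        except BaselineError:
            rejects.append((curve.curve_id, "baseline_failed"))
            continue
        candidates = detect_rupture(corrected, tether_span=tether_span, min_jump=min_jump)
        if not candidates:
            continue  # blank curve, not an error
        for idx in candidates:
            ev = fit_wlc(corrected, idx, tether_span=tether_span,
                         fit_persistence=fit_persistence, constants=constants)
            ev.n_candidates_on_curve = len(candidates)
            if ev.flag == "ok":
                ev = apparent_loading_rate(corrected, ev)
            events.append(ev)
    kept, filt_rejects = filter_specific(
        events, linker_total, inter_terminus, n_residues, per_residue_length
    )
    rejects.extend(filt_rejects)
    ev_df = pd.DataFrame(
        [
            {
                "curve_id": e.curve_id,
                "rupture_force_pN": e.rupture_force,
                "rupture_distance_nm": e.rupture_distance,
                "contour_length_nm": e.contour_length,
                "persistence_length_nm": e.persistence_length,
                "apparent_loading_rate_pN_s": e.apparent_loading_rate,
                "fit_rss": e.fit_rss,
            }
            for e in kept
        ],
        columns=[
            "curve_id", "rupture_force_pN", "rupture_distance_nm",
            "contour_length_nm", "persistence_length_nm",
            "apparent_loading_rate_pN_s", "fit_rss",
        ],
    )
    rej_df = pd.DataFrame(rejects, columns=["curve_id", "reason"])
    return ev_df, rej_df
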