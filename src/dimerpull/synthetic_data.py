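"""End-to-end simulation of tethered-dimer pulling experiments.

Generates force--distance retraction curves and rupture-event tables with
known ground truth, so every estimator in the pipeline can be validated by
parameter recovery. The simulated instrument pulls a Hookean cantilever
against a worm-like-chain tether (PEG + the non-interacting peptide
segments; same-persistence WLCs in series at common tension behave exactly
like one WLC with the summed contour length, so a single chain with the
event's total contour length is simulated). Rupture times are drawn from
the inhomogeneous-hazard process with the Bell rate evaluated along the
actual nonlinear force trajectory; the fast event-table route instead uses
the constant-loading-rate Evans--Ritchie closed form.

Three curve classes are produced: specific (tether-mediated dimer rupture),
nonspecific (short-range adhesion releasing within ~15 nm of contact), and
blank (baseline only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import (
    BellParams,
    PhysicalConstants,
    WLCParams,
    bell_rate,
    most_probable_force,
    wlc_force,
    wlc_inverse,
    wlc_stiffness,
)
from .curve_pipeline import ForceCurve, write_curve
from .segment_mapping import LinkerModel

__all__ = [
    "SimulationConfig",
    "GroundTruthAnnotation",
    "sample_rupture_force",
    "effective_loading_rate",
    "simulate_event_table",
    "simulate_force_curve",
    "generate_dataset",
]


@dataclass
class SimulationConfig:
    """Ground truth and acquisition settings for one simulated experiment.

    Defaults mirror the experimental regime the package targets: retraction
    speeds 100-4000 nm/s giving loading rates ~1e3-4e4 pN/s, rupture forces
    ~40-100 pN, contour lengths ~25-60 nm.
    """

    bell: BellParams = field(default_factory=lambda: BellParams(k_off=5.56, x_beta=0.30))
    anchor_mixture: tuple[tuple[int, float], ...] = ((9, 0.6), (20, 0.25), (38, 0.15))
    per_residue_length: float = 0.41   # nm/residue
    linker: LinkerModel = field(default_factory=LinkerModel)
    retraction_speeds: tuple[float, ...] = (500.0, 1000.0, 2000.0, 4000.0)
    cantilever_stiffness: float = 30.0  # pN/nm
    sampling_rate: float = 10000.0      # points/s
    force_noise_sd: float = 5.0         # pN, additive white noise
    length_noise_sd: float = 1.5        # nm, contour-length scatter
    specific_fraction: float = 0.3
    nonspecific_fraction: float = 0.2   # of all curves; remainder are blank
    n_curves: int = 100
    seed: int = 0
    tether_persistence: float = 0.38    # nm
    max_separation: float = 110.0       # nm, pull span
    adhesion_decay: float = 3.0         # nm, nonspecific force decay length
    rebind_force: float = 15.0          # pN; below this, dissociations rebind
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        weights = [w for _, w in self.anchor_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"anchor mixture weights must sum to 1, got {sum(weights)}")
        if not 0.0 <= self.specific_fraction <= 1.0:
            raise ValueError("specific_fraction must be in [0, 1]")
        if self.specific_fraction + self.nonspecific_fraction > 1.0:
            raise ValueError("specific + nonspecific fractions exceed 1")
        for v in self.retraction_speeds:
            if v <= 0:
                raise ValueError("retraction speeds must be positive")


@dataclass
class GroundTruthAnnotation:
    """Hidden truth for one simulated curve (never consumed by the pipeline)."""

    curve_id: str
    curve_class: str                 # specific | nonspecific | blank
    anchor_residue: float = math.nan
    true_contour_length: float = math.nan  # nm
    true_rupture_force: float = math.nan   # pN
    true_loading_rate: float = math.nan    # pN/s
    retraction_speed: float = math.nan     # nm/s


def sample_rupture_force(loading_rate: float, bell: BellParams,
                         constants: PhysicalConstants = PhysicalConstants(),
                         rng: np.random.Generator | None = None,
                         size: int | None = None):
    """Draw rupture forces from the Evans--Ritchie law by exact inverse CDF.

    With beta = kBT/x_beta and a = k_off*beta/r the CDF is
    1 - exp[a(1 - e^{F/beta})], inverted as
    F = beta * ln(1 - ln(1-U)/a) for U uniform on [0, 1).
    """
    if loading_rate <= 0:
        raise ValueError("loading_rate must be positive")
    rng = np.random.default_rng() if rng is None else rng
    beta = constants.thermal_energy / bell.x_beta
    a = bell.k_off * beta / loading_rate
    u = rng.random(size)
    f = beta * np.log1p(-np.log1p(-u) / a)
    return f if size is not None else float(f)


def effective_loading_rate(speed: float, contour_length: float,
                           config: SimulationConfig) -> float:
    """Apparent loading rate (pN/s) at rupture for a given retraction speed.

    The cantilever and the tether load in series, so r = v * k_eff with
    k_eff = k_c*k_t/(k_c + k_t) and k_t the WLC stiffness at the rupture
    force. The rupture force itself depends on r, so the self-consistent
    force F = F*(v * k_eff(F)) is found by fixed-point iteration started
    above the physical root: the map is increasing in F with slope < 1
    there, so the iteration descends monotonically onto it (deterministic).
    """
    wlc = WLCParams(config.tether_persistence, contour_length)
    force = 200.0
    r = speed * config.cantilever_stiffness
    for _ in range(200):
        x = wlc_inverse(force, wlc, config.constants)
        k_t = wlc_stiffness(x, wlc, config.constants)
        k_eff = config.cantilever_stiffness * k_t / (config.cantilever_stiffness + k_t)
        r = speed * k_eff
        f_new = max(most_probable_force(r, config.bell, config.constants), 1.0)
        if abs(f_new - force) < 1e-8:
            break
        force = f_new
    return r


def _draw_anchor(config: SimulationConfig, rng: np.random.Generator) -> int:
    residues = np.array([r for r, _ in config.anchor_mixture])
    weights = np.array([w for _, w in config.anchor_mixture])
    return int(rng.choice(residues, p=weights))


def _event_contour_length(anchor: int, config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> float:
    lc = (
        config.linker.linker_total
        + config.linker.inter_terminus
        + 2.0 * anchor * config.per_residue_length
    )
    if rng is not None and config.length_noise_sd > 0:
        lc += rng.normal(0.0, config.length_noise_sd)
    return float(lc)


def simulate_event_table(config: SimulationConfig,
                         loading_rates: Sequence[float] | None = None,
                         n_events: int | None = None,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a rupture-event table directly (no curves; closed-form route).

    Each event draws an anchor residue from the mixture, builds the contour
    length from the tether arithmetic plus Gaussian length noise, assigns a
    loading rate (either given per event or derived from a random retraction
    speed through the series stiffness at rupture), and samples the rupture
    force from the Evans--Ritchie law at that rate. Deterministic for a
    fixed config seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if loading_rates is not None:
        rates = np.asarray(loading_rates, dtype=float)
        n = rates.size
        speeds = np.full(n, math.nan)
    else:
        n = config.n_curves if n_events is None else n_events
        speeds = rng.choice(np.asarray(config.retraction_speeds, float), size=n)
        rates = np.empty(n)
    rows = []
    for i in range(n):
        anchor = _draw_anchor(config, rng)
        lc_true = _event_contour_length(anchor, config, rng=None)
        lc_meas = _event_contour_length(anchor, config, rng=rng)
        if loading_rates is None:
            rates[i] = effective_loading_rate(speeds[i], lc_true, config)
        force = sample_rupture_force(rates[i], config.bell, config.constants, rng)
        rows.append(
            {
                "event_id": f"ev{i:05d}",
                "curve_class": "specific",
                "anchor_residue": anchor,
                "true_contour_length_nm": lc_true,
                "contour_length_nm": lc_meas,
                "loading_rate_pN_s": float(rates[i]),
                "rupture_force_pN": float(force),
                "retraction_speed_nm_s": float(speeds[i]),
            }
        )
    return pd.DataFrame(rows)


def simulate_force_curve(config: SimulationConfig, curve_id: str,
                         curve_class: str = "specific",
                         anchor: int | None = None,
                         speed: float | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[ForceCurve, GroundTruthAnnotation]:
    """Time-stepped simulation of one retraction curve.

    The cantilever base retracts at constant speed; at each sample the force
    balances the Hookean cantilever against the WLC tether (solved by a
    precomputed monotone inversion table). The rupture time is drawn from
    the inhomogeneous-hazard process with rate k(F(t)); after rupture the
    force relaxes to baseline. Gaussian noise of sd ``force_noise_sd`` is
    added pointwise. Nonspecific curves show a short-range (< 15 nm)
    exponential adhesion peak; blanks show none.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    speed = float(rng.choice(np.asarray(config.retraction_speeds, float))) if speed is None else speed
    dt = 1.0 / config.sampling_rate
    n_pts = max(100, int(math.ceil(config.max_separation / (speed * dt))))
    t = np.arange(n_pts) * dt
    z = speed * t  # cantilever base position, nm
    noise = rng.normal(0.0, config.force_noise_sd, n_pts) if config.force_noise_sd > 0 else np.zeros(n_pts)

    annotation = GroundTruthAnnotation(curve_id=curve_id, curve_class=curve_class,
                                       retraction_speed=speed)

    if curve_class == "blank":
        curve = ForceCurve(z, noise, config.cantilever_stiffness, speed,
                           config.sampling_rate, curve_id)
        return curve, annotation

    if curve_class == "nonspecific":
        amplitude = rng.uniform(30.0, 80.0)
        detach = rng.uniform(3.0, 12.0)
        force = np.where(z < detach, -amplitude * np.exp(-z / config.adhesion_decay), 0.0)
        curve = ForceCurve(z, force + noise, config.cantilever_stiffness, speed,
                           config.sampling_rate, curve_id)
        return curve, annotation

    if curve_class != "specific":
        raise ValueError(f"unknown curve class '{curve_class}'")

    anchor = _draw_anchor(config, rng) if anchor is None else anchor
    lc = _event_contour_length(anchor, config, rng=rng)
    wlc = WLCParams(config.tether_persistence, lc)
    k_c = config.cantilever_stiffness

    # monotone inversion table: base position z(x) = x + F(x)/k_c
    x_grid = np.linspace(0.0, 0.995 * lc, 4000)
    f_grid = wlc_force(x_grid, wlc, config.constants)
    z_grid = x_grid + f_grid / k_c
    loaded = z <= z_grid[-1]
    x_t = np.where(loaded, np.interp(z, z_grid, x_grid), x_grid[-1])
    f_t = np.where(loaded, np.interp(z, z_grid, f_grid), f_grid[-1])

    hazard = bell_rate(np.clip(f_t, 0.0, 700.0 * config.constants.thermal_energy
                               / config.bell.x_beta), config.bell, config.constants)
    # below the rebind threshold the tip is still at the surface and transient
    # dissociations re-form; only above it does a rupture become irreversible
    hazard = np.where(f_t < config.rebind_force, 0.0, hazard)
    cumulative = np.cumsum(hazard) * dt
    draw = rng.exponential()
    over = np.flatnonzero(cumulative >= draw)
    last_loaded = int(np.flatnonzero(loaded)[-1]) if loaded.any() else 0
    rupture_idx = int(over[0]) if over.size else last_loaded
    rupture_idx = min(rupture_idx, last_loaded)

    separation = np.where(np.arange(n_pts) <= rupture_idx, x_t, z)
    force = np.where(np.arange(n_pts) <= rupture_idx, -f_t, 0.0)

    # instantaneous pre-rupture loading rate from the noiseless trace
    n_tail = max(10, int(round(0.1 * rupture_idx)))
    i0 = max(0, rupture_idx - n_tail + 1)
    if rupture_idx - i0 >= 2:
        slope = float(np.polyfit(t[i0: rupture_idx + 1], f_t[i0: rupture_idx + 1], 1)[0])
    else:
        slope = math.nan

    annotation.anchor_residue = float(anchor)
    annotation.true_contour_length = lc
    annotation.true_rupture_force = float(f_t[rupture_idx])
    annotation.true_loading_rate = slope

    curve = ForceCurve(separation, force + noise, k_c, speed,
                       config.sampling_rate, curve_id)
    return curve, annotation


def generate_dataset(config: SimulationConfig, outdir: str | Path,
                     ) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Simulate ``config.n_curves`` curves, write TSVs plus a manifest CSV.

    The manifest holds one ground-truth row per curve. Byte-identical
    reruns are guaranteed for a fixed config (all randomness flows from
    ``config.seed``).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {outdir}: {exc}") from exc
    rng = np.random.default_rng(config.seed)
    classes = rng.choice(
        ["specific", "nonspecific", "blank"],
        size=config.n_curves,
        p=[
            config.specific_fraction,
            config.nonspecific_fraction,
            1.0 - config.specific_fraction - config.nonspecific_fraction,
        ],
    )
    curves: list[ForceCurve] = []
    annotations: list[GroundTruthAnnotation] = []
    for i, cls in enumerate(classes):
        curve_id = f"curve{i:05d}"
        curve, ann = simulate_force_curve(config, curve_id, curve_class=str(cls), rng=rng)
        curves.append(curve)
        annotations.append(ann)
        try:
            write_curve(curve, outdir / f"{curve_id}.tsv")
        except OSError as exc:
            raise OSError(f"cannot write curve file {outdir / curve_id}: {exc}") from exc
    manifest = pd.DataFrame([asdict(a) for a in annotations])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return curves, manifest
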