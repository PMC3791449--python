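"""Map measured contour lengths to interacting-segment residue positions.

The measured contour length of a specific rupture is the sum of the tether
stack (PEG + maleimide silatrane), the gap between the two peptide N-termini,
and the stretched non-interacting N-terminal segments of *both* monomers.
Subtracting the tether stack and dividing by twice the per-residue length
therefore places the N-terminal boundary of the interacting segment on the
peptide sequence. Kernel-smoothed histograms of those boundary positions,
with called peaks, form per-peptide interaction profiles that can be
compared across alloforms and mutants.

The factor of two is essential: both monomers' non-interacting segments
stretch in series in the symmetric dimer geometry, and only with it do the
canonical contour-length clusters (~33, ~42, ~57 nm) land on the ~10, ~20
and ~35+ residue boundaries expected for the amyloid-beta alloforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core_model import PegModel, peg_contour_length

__all__ = [
    "LinkerModel",
    "PeptideModel",
    "SegmentProfile",
    "PEPTIDES",
    "peptide_extension",
    "residue_index",
    "build_profile",
    "compare_profiles",
]


@dataclass(frozen=True)
class LinkerModel:
    """The tether stack between the anchoring surfaces and the peptides.

    ``peg_length`` defaults to the nominal 22.0 nm of a 3400 Da PEG (see
    :func:`dimerpull.core_model.peg_contour_length`; use :meth:`from_peg` to
    derive it from a two-state model instead). The maleimide silatrane (MAS,
    tip side) adds 2.5 nm. The aminopropyl silatrane (APS, mica side) sits
    underneath the PEG anchor and is recorded for provenance but not added,
    so linker_total = peg_length + mas_length = 24.5 nm at defaults.
    ``inter_terminus`` is the ~1.0 nm gap between the two peptide N-termini
    in the bound dimer.
    """

    peg: PegModel = PegModel()
    peg_length: float = 22.0
    mas_length: float = 2.5
    aps_length: float = 2.5
    inter_terminus: float = 1.0

    def __post_init__(self) -> None:
        for name in ("peg_length", "mas_length", "aps_length", "inter_terminus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def linker_total(self) -> float:
        return self.peg_length + self.mas_length

    @classmethod
    def from_peg(cls, peg: PegModel, **kwargs) -> "LinkerModel":
        """Build a LinkerModel with peg_length derived from the two-state model."""
        return cls(peg=peg, peg_length=peg_contour_length(peg), **kwargs)


@dataclass(frozen=True)
class PeptideModel:
    """A pulled peptide: residue count (incl. the N-terminal Cys anchor) and
    the calibrated contour length per residue (nm)."""

    name: str
    n_residues: int
    per_residue_length: float

    def __post_init__(self) -> None:
        if self.n_residues <= 0:
            raise ValueError("n_residues must be positive")
        if not (0.3 <= self.per_residue_length <= 0.5):
            raise ValueError(
                f"per_residue_length {self.per_residue_length} outside the "
                "plausible 0.3-0.5 nm/residue range"
            )


#: Built-in peptide definitions: the two wild-type alloforms and the
#: C-terminal substitution mutants share their parent's length/conversion.
PEPTIDES: dict[str, PeptideModel] = {
    "abeta40": PeptideModel("abeta40", 41, 0.41),
    "vpv_abeta40": PeptideModel("vpv_abeta40", 41, 0.41),
    "abeta42": PeptideModel("abeta42", 43, 0.40),
    "vpv_abeta42": PeptideModel("vpv_abeta42", 43, 0.40),
    "pp_abeta42": PeptideModel("pp_abeta42", 43, 0.40),
}


@dataclass
class SegmentProfile:
    """Interaction profile of one peptide: smoothed density of inferred
    interacting-segment boundary residues, with called peaks."""

    peptide: str
    residue_axis: np.ndarray
    density: np.ndarray
    peaks: pd.DataFrame  # columns: position, height, label
    n_events: int
    contour_lengths: np.ndarray
    unstructured: bool = False
    symmetric_dimer_assumed: bool = True


def peptide_extension(contour_length, linker: LinkerModel = LinkerModel()):
    """Stretched non-interacting peptide length (nm): measured contour length
    minus the tether stack and the inter-terminus gap, floored at zero."""
    lc = np.asarray(contour_length, dtype=float)
    ext = np.maximum(lc - linker.linker_total - linker.inter_terminus, 0.0)
    return ext if ext.ndim else float(ext)


def residue_index(extension, peptide: PeptideModel):
    """Interacting-segment boundary (fractional residues from the N-terminus).

    Divides by *twice* the per-residue length because the non-interacting
    N-terminal segments of both monomers stretch in series (symmetric-dimer
    assumption); clamped to [0, n_residues].
    """
    ext = np.asarray(extension, dtype=float)
    if np.any(ext < 0):
        raise ValueError("extension must be nonnegative")
    idx = np.clip(ext / (2.0 * peptide.per_residue_length), 0.0, peptide.n_residues)
    return idx if idx.ndim else float(idx)


def build_profile(contour_lengths: Sequence[float], linker: LinkerModel,
                  peptide: PeptideModel, bandwidth: float = 2.0,
                  min_events: int = 30, grid_step: float = 0.1,
                  peak_prominence_frac: float = 0.1,
                  merge_distance: float = 4.0) -> SegmentProfile:
    """Kernel-smoothed residue-position density with called peaks.

    Each event's contour length is converted to a boundary residue; a
    fixed-bandwidth Gaussian kernel (default 2 residues) is summed on a
    residue grid and normalized to unit area. Peaks are local maxima with
    prominence at least ``peak_prominence_frac`` of the global maximum;
    peaks closer than ``merge_distance`` residues are merged (higher wins).
    A profile with no peak passing prominence is flagged unstructured.
    """
    lc = np.asarray(contour_lengths, dtype=float)
    lc = lc[np.isfinite(lc)]
    if lc.size < min_events:
        raise ValueError(
            f"profile needs >= {min_events} events, got {lc.size}"
        )
    positions = residue_index(peptide_extension(lc, linker), peptide)
    grid = np.arange(0.0, peptide.n_residues + grid_step / 2, grid_step)
    kernel = np.exp(-0.5 * ((grid[:, None] - positions[None, :]) / bandwidth) ** 2)
    density = kernel.sum(axis=1)
    area = np.trapezoid(density, grid)
    if area > 0:
        density = density / area

    # Structure gate: a normalized profile that never rises much above the
    # flat level 1/n_residues carries no cluster structure; calling "peaks"
    # on its sampling wiggles would be noise.
    flat_level = 1.0 / peptide.n_residues
    unstructured = density.max() < 1.5 * flat_level
    merged: list[int] = []
    if not unstructured:
        # interior local maxima with height >= peak_prominence_frac of the
        # global maximum; a prominence floor of 2x the pointwise KDE
        # sampling sd keeps noise wiggles out without suppressing minor
        # clusters that ride on the flanks of larger ones.
        idx, props = find_peaks(density, prominence=0.0)
        keep = []
        for i, prom in zip(idx, props["prominences"]):
            noise_sd = math.sqrt(density[i] / (2.0 * math.sqrt(math.pi) * lc.size * bandwidth))
            if density[i] >= peak_prominence_frac * density.max() and prom >= 2.0 * noise_sd:
                keep.append(i)
        order = sorted(keep, key=lambda i: -density[i])
        for i in order:
            if all(abs(grid[i] - grid[j]) >= merge_distance for j in merged):
                merged.append(i)
        merged.sort()
    peaks = pd.DataFrame(
        {
            "position": [float(grid[i]) for i in merged],
            "height": [float(density[i]) for i in merged],
            "label": [f"peak{k + 1}" for k in range(len(merged))],
        }
    )
    return SegmentProfile(
        peptide=peptide.name, residue_axis=grid, density=density, peaks=peaks,
        n_events=int(lc.size), contour_lengths=lc,
        unstructured=unstructured or peaks.empty,
    )


def compare_profiles(a: SegmentProfile, b: SegmentProfile) -> tuple[float, pd.DataFrame]:
    """Total-variation distance between two profiles plus a peak matching.

    Densities are interpolated onto a common residue axis and renormalized;
    the distance is 0.5 * integral |p - q|, in [0, 1] (0 identical, 1
    disjoint). Peaks of ``a`` are greedily matched to the nearest unused
    peak of ``b``.
    """
    lo = min(a.residue_axis[0], b.residue_axis[0])
    hi = max(a.residue_axis[-1], b.residue_axis[-1])
    grid = np.linspace(lo, hi, 2048)
    pa = np.interp(grid, a.residue_axis, a.density, left=0.0, right=0.0)
    pb = np.interp(grid, b.residue_axis, b.density, left=0.0, right=0.0)
    for p in (pa, pb):
        area = np.trapezoid(p, grid)
        if area > 0:
            p /= area
    tv = 0.5 * float(np.trapezoid(np.abs(pa - pb), grid))

    rows = []
    used: set[int] = set()
    for _, pk in a.peaks.iterrows():
        best, best_d = None, np.inf
        for j, qk in b.peaks.iterrows():
            if j in used:
                continue
            d = abs(pk["position"] - qk["position"])
            if d < best_d:
                best, best_d = j, d
        if best is not None:
            used.add(best)
            rows.append(
                {
                    "peak_a": pk["position"], "peak_b": b.peaks.loc[best, "position"],
                    "distance": best_d,
                }
            )
        else:
            rows.append({"peak_a": pk["position"], "peak_b": np.nan, "distance": np.nan})
    return tv, pd.DataFrame(rows, columns=["peak_a", "peak_b", "distance"])
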