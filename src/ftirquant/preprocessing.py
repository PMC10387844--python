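"""Region baselining, band-reference normalization, resampling, averaging.

An analysis region is a wavenumber interval with two baseline anchor points.
Baselining subtracts the straight line through the trace values at the two
anchors (linear interpolation onto the anchors), which makes every downstream
quantity invariant to an additive affine background. Normalization divides a
baselined trace by the apex intensity of a reference band, making band
ratios comparable across samples with different amounts of deposited
material.

Two default regions are provided:

* ``lipid`` (2800-3020 cm^-1): C-H stretching bands of lipids and proteins,
  reference band CH2 asymmetric (2924 cm^-1); the upper edge leaves the
  olefinic 3006 cm^-1 search window fully inside the region;
* ``fingerprint`` (890-1478 cm^-1): nucleic-acid, glycogen and protein
  bands, reference band PO2- symmetric (1082 cm^-1).

Anchors default to the region edges; "two arbitrarily selected points" is
not a reproducible prescription, so they are explicit configuration here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import CoverageError, NormalizationError, RangeError, ValidationError
from .spectra_io import BandDef, Spectrum, SpectrumGroup, catalog_by_name


@dataclass(frozen=True)
class AnalysisRegion:
    """A contiguous analysis interval with its baseline anchors."""

    region_id: str
    lo: float
    hi: float
    anchor_lo: float
    anchor_hi: float
    norm_band: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(
                f"region {self.region_id!r}: lo must be < hi")
        for a in (self.anchor_lo, self.anchor_hi):
            if not (self.lo <= a <= self.hi):
                raise ValidationError(
                    f"region {self.region_id!r}: anchor {a:g} outside "
                    f"[{self.lo:g}, {self.hi:g}]")
        if not self.anchor_lo < self.anchor_hi:
            raise ValidationError(
                f"region {self.region_id!r}: anchor_lo must be < anchor_hi")


DEFAULT_REGIONS: dict[str, AnalysisRegion] = {
    "lipid": AnalysisRegion("lipid", 2800.0, 3020.0, 2800.0, 3020.0,
                            norm_band="ch2_asym"),
    "fingerprint": AnalysisRegion("fingerprint", 890.0, 1478.0, 890.0, 1478.0,
                                  norm_band="po2_sym"),
}


@dataclass
class ProcessedSpectrum:
    """A region-restricted, baseline-subtracted (optionally normalized) trace."""

    parent: str
    group_label: str
    region: AnalysisRegion
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    normalization_factor: Optional[float] = None
    meta: dict = field(default_factory=dict)

    @property
    def region_id(self) -> str:
        return self.region.region_id


def _interp_at(s_wn: np.ndarray, s_ab: np.ndarray, x: float) -> float:
    return float(np.interp(x, s_wn, s_ab))


def baseline_subtract(s: Spectrum, region: AnalysisRegion) -> ProcessedSpectrum:
    """Subtract the line through the trace values at the region's anchors.

    The anchor values are obtained by linear interpolation of the trace onto
    the anchor positions, so anchors need not fall on grid points. The output
    is restricted to [lo, hi].
    """
    if not s.covers(region.lo, region.hi):
        lo_s, hi_s = s.span
        missing = []
        if lo_s > region.lo:
            missing.append(f"{region.lo:g}-{min(lo_s, region.hi):g}")
        if hi_s < region.hi:
            missing.append(f"{max(hi_s, region.lo):g}-{region.hi:g}")
        raise CoverageError(
            f"spectrum {s.sample_id!r} ({lo_s:g}-{hi_s:g} cm^-1) does not "
            f"cover region {region.region_id!r}; missing {', '.join(missing)}"
            " cm^-1")
    v_lo = _interp_at(s.wavenumbers, s.absorbance, region.anchor_lo)
    v_hi = _interp_at(s.wavenumbers, s.absorbance, region.anchor_hi)
    mask = (s.wavenumbers >= region.lo) & (s.wavenumbers <= region.hi)
    wn = s.wavenumbers[mask].copy()
    slope = (v_hi - v_lo) / (region.anchor_hi - region.anchor_lo)
    line = v_lo + slope * (wn - region.anchor_lo)
    return ProcessedSpectrum(
        parent=s.sample_id,
        group_label=s.group_label,
        region=region,
        wavenumbers=wn,
        absorbance=s.absorbance[mask] - line,
        meta={"anchors": (region.anchor_lo, region.anchor_hi)},
    )


def normalize_to_band(p: ProcessedSpectrum,
                      catalog: Sequence[BandDef],
                      band_name: Optional[str] = None) -> ProcessedSpectrum:
    """Divide a baselined trace by its reference-band apex intensity.

    The reference defaults to the region's ``norm_band``. The reference apex
    in the output equals 1, so normalizing twice is a no-op.
    """
    from .band_quantification import measure_band  # local: avoids cycle

    name = band_name or p.region.norm_band
    if name is None:
        raise ValidationError(
            f"region {p.region_id!r} has no normalization band configured")
    band = catalog_by_name(catalog).get(name)
    if band is None:
        raise ValidationError(f"band {name!r} not in catalog")
    ref = measure_band(p, band)
    if not ref.intensity > 0:
        raise NormalizationError(
            f"reference band {name!r} intensity {ref.intensity:g} is not "
            f"positive in {p.parent!r}; spectrum looks degenerate")
    factor = float(ref.intensity)
    prior = p.normalization_factor or 1.0
    return replace(
        p,
        absorbance=p.absorbance / factor,
        normalization_factor=prior * factor,
        meta={**p.meta, "norm_band": name},
    )


def resample(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation of a spectrum onto a new ascending grid."""
    grid = np.asarray(grid, dtype=float)
    lo_s, hi_s = s.span
    if grid[0] < lo_s or grid[-1] > hi_s:
        raise RangeError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] extends beyond spectrum span "
            f"[{lo_s:g}, {hi_s:g}]; extrapolation is not supported")
    return Spectrum(
        sample_id=s.sample_id,
        group_label=s.group_label,
        wavenumbers=grid.copy(),
        absorbance=np.interp(grid, s.wavenumbers, s.absorbance),
        resolution=s.resolution,
        n_scans=s.n_scans,
        meta={**s.meta, "resampled": True},
    )


def average_group(g: SpectrumGroup, region: AnalysisRegion) -> ProcessedSpectrum:
    """Pointwise mean of baseline-subtracted replicates on a common grid.

    The common grid is the finest replicate grid restricted to the region
    (the one with the most points there); coarser replicates are linearly
    interpolated onto it. Intended for display/export — group statistics are
    computed per replicate, not from the averaged trace.
    """
    processed = [baseline_subtract(s, region) for s in g.replicates]
    grid = max(processed, key=lambda p: p.wavenumbers.size).wavenumbers
    stack = np.vstack([
        np.interp(grid, p.wavenumbers, p.absorbance) for p in processed
    ])
    return ProcessedSpectrum(
        parent=f"mean({g.label}, n={g.n})",
        group_label=g.label,
        region=region,
        wavenumbers=grid.copy(),
        absorbance=stack.mean(axis=0),
        meta={"n_averaged": g.n},
    )
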