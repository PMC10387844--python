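"""Macromolecular indices derived from band measurements.

Each index is a function of apex intensities (or positions) measured on
baselined region traces of one replicate:

* ``lipid_protein_ratio``   — I(2852) / I(2872), CH2 sym over CH3 sym;
* ``chain_length_index``    — I(2924) / I(2958), CH2 asym over CH3 asym,
  an indicator of acyl hydrocarbon chain length;
* ``olefinic_index``        — I(3006) on the CH2-asym-normalized lipid
  trace, i.e. I(3006)/I(2924); tracks lipid unsaturation / peroxidation;
* ``rna_content_1121``      — I(1121) / I(1082), RNA band over the PO2-
  symmetric phosphate reference;
* ``glycogen_996``, ``glycogen_1156``, ``protein_CO_1171`` — fingerprint
  intensities on the PO2-sym-normalized trace;
* ``po2_sym_position``, ``po2_asym_position`` — refined band positions in
  cm^-1 of the phosphate stretches.

Ratios are scale-free, so lipid-region ratios need no explicit
normalization; band intensities reported alone are always referenced to
their region's normalization band. Group comparisons compute the metric per
replicate (mean +/- sample SD), the percent change of group means, and a
two-sample test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import math

import numpy as np
import pandas as pd

from .band_quantification import BandMeasurement, measure_band
from .errors import DegenerateSpectrumError, ValidationError
from .group_stats import (Summary, TestResult, mann_whitney_u, summarize,
                          t_test_unpaired)
from .preprocessing import DEFAULT_REGIONS, AnalysisRegion, baseline_subtract
from .spectra_io import BandDef, DEFAULT_CATALOG, Spectrum, SpectrumGroup


@dataclass
class MetricResult:
    metric: str
    group_label: str
    per_replicate: list[float]
    mean: float
    sd: float
    n: int

    @classmethod
    def from_values(cls, metric: str, group_label: str,
                    values: Sequence[float]) -> "MetricResult":
        s = summarize(values)
        return cls(metric, group_label, [float(v) for v in values],
                   s.mean, s.sd, s.n)


@dataclass
class ComparisonResult:
    metric: str
    control: MetricResult
    treated: MetricResult
    percent_change: float
    difference: float
    direction: str  # increase | decrease | no change
    p_value: float
    test: str
    note: Optional[str] = None


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Signed percent change of the treated mean relative to control."""
    if control_mean == 0:
        raise DegenerateSpectrumError(
            "percent change undefined for a zero control mean")
    return 100.0 * (treated_mean - control_mean) / control_mean


def direction_label(diff: float) -> str:
    if diff > 0:
        return "increase"
    if diff < 0:
        return "decrease"
    return "no change"


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report formatting)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


# ---------------------------------------------------------------------------
# per-replicate measurement
# ---------------------------------------------------------------------------

def measure_replicate(s: Spectrum,
                      catalog: Sequence[BandDef] = DEFAULT_CATALOG,
                      regions: dict[str, AnalysisRegion] | None = None,
                      ) -> dict[str, BandMeasurement]:
    """Baseline each region once and measure every catalog band in it."""
    regions = regions or DEFAULT_REGIONS
    out: dict[str, BandMeasurement] = {}
    for rid, region in regions.items():
        bands = [b for b in catalog if b.region_id == rid]
        if not bands:
            continue
        p = baseline_subtract(s, region)
        for b in bands:
            out[b.name] = measure_band(p, b)
    return out


def _ratio(m: dict[str, BandMeasurement], num: str, den: str) -> float:
    if num not in m or den not in m:
        missing = [k for k in (num, den) if k not in m]
        raise ValidationError(f"missing band measurement(s): {missing}")
    d = m[den].intensity
    if d <= 0:
        raise DegenerateSpectrumError(
            f"reference band {den!r} intensity {d:g} is not positive")
    return m[num].intensity / d


def lipid_protein_ratio(m: dict[str, BandMeasurement]) -> float:
    """CH2 symmetric / CH3 symmetric apex ratio (lipid-to-protein proxy)."""
    return _ratio(m, "ch2_sym", "ch3_sym")


def chain_length_index(m: dict[str, BandMeasurement]) -> float:
    """CH2 asymmetric / CH3 asymmetric apex ratio (acyl chain length)."""
    return _ratio(m, "ch2_asym", "ch3_asym")


def olefinic_index(m: dict[str, BandMeasurement]) -> float:
    """Olefinic =CH apex on the CH2-asym-normalized lipid trace."""
    return _ratio(m, "olefinic", "ch2_asym")


def rna_content(m: dict[str, BandMeasurement]) -> float:
    """RNA 1121 cm^-1 apex over the PO2 symmetric phosphate reference."""
    return _ratio(m, "rna_1121", "po2_sym")


def glycogen_and_protein_bands(m: dict[str, BandMeasurement]
                               ) -> dict[str, float]:
    """996/1156 cm^-1 glycogen and 1171 cm^-1 protein C-O intensities,
    each on the PO2-sym-normalized fingerprint trace."""
    return {
        "glycogen_996": _ratio(m, "glycogen_996", "po2_sym"),
        "glycogen_1156": _ratio(m, "glycogen_1156", "po2_sym"),
        "protein_CO_1171": _ratio(m, "protein_co_1171", "po2_sym"),
    }


METRIC_FUNCS: dict[str, Callable[[dict[str, BandMeasurement]], float]] = {
    "lipid_protein_ratio": lipid_protein_ratio,
    "chain_length_index": chain_length_index,
    "olefinic_index": olefinic_index,
    "rna_content_1121": rna_content,
    "glycogen_996": lambda m: glycogen_and_protein_bands(m)["glycogen_996"],
    "glycogen_1156": lambda m: glycogen_and_protein_bands(m)["glycogen_1156"],
    "protein_CO_1171": lambda m: glycogen_and_protein_bands(m)["protein_CO_1171"],
    "po2_sym_position": lambda m: m["po2_sym"].position,
    "po2_asym_position": lambda m: m["po2_asym"].position,
}

ALL_METRICS: tuple[str, ...] = tuple(METRIC_FUNCS)

# Positions are absolute wavenumbers: the interesting quantity is the shift
# in cm^-1, not a relative change.
POSITION_METRICS = frozenset({"po2_sym_position", "po2_asym_position"})


def evaluate_metric(g: SpectrumGroup, metric: str,
                    catalog: Sequence[BandDef] = DEFAULT_CATALOG,
                    regions: dict[str, AnalysisRegion] | None = None,
                    ) -> MetricResult:
    """Compute one metric for every replicate of a group."""
    if metric not in METRIC_FUNCS:
        raise ValidationError(
            f"unknown metric {metric!r}; supported: {sorted(METRIC_FUNCS)}")
    func = METRIC_FUNCS[metric]
    values = [func(measure_replicate(s, catalog, regions))
              for s in g.replicates]
    return MetricResult.from_values(metric, g.label, values)


def compare_groups(metric: str, control: SpectrumGroup,
                   treated: SpectrumGroup,
                   catalog: Sequence[BandDef] = DEFAULT_CATALOG,
                   regions: dict[str, AnalysisRegion] | None = None,
                   test: str = "mann_whitney") -> ComparisonResult:
    """Full control-vs-treated contrast for one metric.

    Runs the per-replicate pipeline in both groups, then reports percent
    change of group means, the absolute difference, and the two-sided
    p-value from the requested test (exact Mann-Whitney by default,
    't_unpaired' for the unpaired t-test).
    """
    mc = evaluate_metric(control, metric, catalog, regions)
    mt = evaluate_metric(treated, metric, catalog, regions)
    if test == "mann_whitney":
        tr = mann_whitney_u(mc.per_replicate, mt.per_replicate, mode="auto")
    elif test == "t_unpaired":
        tr = t_test_unpaired(mc.per_replicate, mt.per_replicate)
    else:
        raise ValidationError(f"unknown test {test!r}")
    diff = mt.mean - mc.mean
    pct = (float("nan") if metric in POSITION_METRICS and mc.mean == 0
           else percent_change(mc.mean, mt.mean))
    return ComparisonResult(
        metric=metric, control=mc, treated=mt,
        percent_change=pct, difference=diff,
        direction=direction_label(diff),
        p_value=tr.p_two_sided, test=tr.test, note=tr.note,
    )


def compare_all(control: SpectrumGroup, treated: SpectrumGroup,
                metrics: Sequence[str] = ALL_METRICS,
                catalog: Sequence[BandDef] = DEFAULT_CATALOG,
                regions: dict[str, AnalysisRegion] | None = None,
                test: str = "mann_whitney") -> list[ComparisonResult]:
    return [compare_groups(m, control, treated, catalog, regions, test)
            for m in metrics]


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy report: one row per metric, ratios to 4 decimals, percent
    changes to 3 significant figures."""
    rows = []
    for r in results:
        is_pos = r.metric in POSITION_METRICS
        rows.append({
            "metric": r.metric,
            "control_mean": round(r.control.mean, 4 if not is_pos else 2),
            "control_sd": round(r.control.sd, 4)
            if np.isfinite(r.control.sd) else np.nan,
            "treated_mean": round(r.treated.mean, 4 if not is_pos else 2),
            "treated_sd": round(r.treated.sd, 4)
            if np.isfinite(r.treated.sd) else np.nan,
            "percent_change": round_sig(r.percent_change, 3),
            "difference": round(r.difference, 4),
            "direction": r.direction,
            "p_value": round_sig(r.p_value, 4),
            "test": r.test,
            "n_control": r.control.n,
            "n_treated": r.treated.n,
        })
    return pd.DataFrame(rows)
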