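"""Synthetic FTIR spectra and DE-table pairs with planted, recoverable truth.

Spectra are sums of pseudo-Voigt bands (eta * Lorentzian + (1-eta) *
Gaussian, unit apex) on a 4 cm^-1 grid, plus a polynomial baseline (degree
<= 2) and additive Gaussian noise. Band parameters are *planted apex
heights*: the heights the baseline-subtract + parabolic-apex measurement
recovers, not raw component amplitudes. Overlapping band tails and baseline
anchors make the two differ by several percent, so the generator calibrates
component amplitudes by fixed-point iteration against the measurement
definition; a noiseless simulated spectrum then reproduces every planted
apex (and hence every planted ratio) to near machine precision, which is
what makes planted-parameter recovery a meaningful end-to-end check.

Group pairs emulate a control-vs-treated contrast: multiplicative
group effects on selected band apexes, optional band-center shifts,
replicate-to-replicate amplitude scatter (CV) and position jitter. Presets
plant the band heights and shifts of a cisplatin-treatment and an antisense
lncRNA knockdown study on HeLa cells (n = 3 per group).

DE-table pairs plant exact overlap structure: per-table significant-gene
counts, the shared subset, and the sign-concordant (parallel) up/down split,
so set-algebra results downstream are known exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocessing import DEFAULT_REGIONS, AnalysisRegion, baseline_subtract
from .spectra_io import BandDef, DEFAULT_CATALOG, Spectrum, SpectrumGroup

DEFAULT_GRID = np.arange(450.0, 4000.0, 4.0)  # 4 cm^-1 sampling
DEFAULT_ETA = 0.3
FWHM_LIPID = 15.0        # C-H stretching region bands
FWHM_FINGERPRINT = 20.0  # fingerprint region bands

_DEFAULT_CENTERS = {b.name: b.center for b in DEFAULT_CATALOG}
_DEFAULT_FWHM = {
    b.name: (FWHM_LIPID if b.region_id == "lipid" else FWHM_FINGERPRINT)
    for b in DEFAULT_CATALOG
}


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float,
                 eta: float = DEFAULT_ETA) -> np.ndarray:
    """Unit-apex pseudo-Voigt profile: eta*Lorentzian + (1-eta)*Gaussian."""
    u = (np.asarray(x, dtype=float) - center) / fwhm
    gauss = np.exp(-4.0 * np.log(2.0) * u ** 2)
    lorentz = 1.0 / (1.0 + 4.0 * u ** 2)
    return eta * lorentz + (1.0 - eta) * gauss


@dataclass
class SpectrumModel:
    """Parameters of one simulated spectrum (planted apex heights)."""

    band_apexes: dict[str, float]
    centers: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CENTERS))
    fwhm: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FWHM))
    eta: float = DEFAULT_ETA
    baseline: tuple[float, ...] = (0.01, 2e-6)  # c0 + c1*nu (+ c2*nu^2)
    noise_sd: float = 5e-4
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    seed: int = 0
    regions: dict[str, AnalysisRegion] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS))

    def __post_init__(self) -> None:
        if len(self.baseline) > 3:
            raise ValidationError("baseline polynomial degree must be <= 2")
        for name, a in self.band_apexes.items():
            if a < 0:
                raise ValidationError(f"band {name!r}: apex must be >= 0")
            if name not in self.centers:
                raise ValidationError(f"band {name!r}: no center given")
        for name, w in self.fwhm.items():
            if w <= 0:
                raise ValidationError(f"band {name!r}: FWHM must be > 0")


@dataclass
class GroupEffect:
    """Treated-vs-control group differences and replicate variability."""

    amplitude_factors: dict[str, float] = field(default_factory=dict)
    center_shifts: dict[str, float] = field(default_factory=dict)
    replicate_cv: float = 0.0
    position_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name, f in self.amplitude_factors.items():
            if f <= 0:
                raise ValidationError(
                    f"band {name!r}: effect factor must be > 0")


# ---------------------------------------------------------------------------
# amplitude calibration against the measurement definition
# ---------------------------------------------------------------------------

def _region_for(center: float, halfwidth: float,
                regions: dict[str, AnalysisRegion]) -> AnalysisRegion:
    for region in regions.values():
        if region.lo <= center - halfwidth and center + halfwidth <= region.hi:
            return region
    raise ValidationError(
        f"no analysis region covers a band window at {center:g} cm^-1")


def _measured_apexes(grid: np.ndarray, trace: np.ndarray,
                     names: Sequence[str], centers: dict[str, float],
                     regions: dict[str, AnalysisRegion],
                     halfwidth: float = 8.0) -> np.ndarray:
    """Apex height of each band per the pipeline's own measurement."""
    from .band_quantification import measure_band

    s = Spectrum("calibration", "", grid, trace)
    by_region: dict[str, list[str]] = {}
    region_objs: dict[str, AnalysisRegion] = {}
    for n in names:
        region = _region_for(centers[n], halfwidth, regions)
        by_region.setdefault(region.region_id, []).append(n)
        region_objs[region.region_id] = region
    out = {}
    for rid, band_names in by_region.items():
        p = baseline_subtract(s, region_objs[rid])
        for n in band_names:
            bd = BandDef(n, "", centers[n], halfwidth, rid, None)
            out[n] = measure_band(p, bd).intensity
    return np.array([out[n] for n in names])


def _crosstalk_matrix(names: Sequence[str], model: SpectrumModel
                      ) -> np.ndarray:
    """Approximate Jacobian d(measured apex_i)/d(amplitude_j).

    Band j contributes its profile value at band i's center, minus the
    leakage of band j's tails into the region baseline (the anchor line
    evaluated at band i's center). Exact for apexes sampled at the centers;
    a very good Newton preconditioner for the parabola-refined apexes.
    """
    m = np.zeros((len(names), len(names)))
    for i, ni in enumerate(names):
        ci = model.centers[ni]
        region = _region_for(ci, 8.0, model.regions)
        alo, ahi = region.anchor_lo, region.anchor_hi
        w = (ci - alo) / (ahi - alo)
        for j, nj in enumerate(names):
            cj, fw = model.centers[nj], model.fwhm[nj]
            direct = pseudo_voigt(np.array([ci]), cj, fw, model.eta)[0]
            v_lo = pseudo_voigt(np.array([alo]), cj, fw, model.eta)[0]
            v_hi = pseudo_voigt(np.array([ahi]), cj, fw, model.eta)[0]
            m[i, j] = direct - (v_lo + w * (v_hi - v_lo))
    return m


def calibrate_amplitudes(model: SpectrumModel, tol: float = 1e-12,
                         max_iter: int = 60) -> tuple[list[str], np.ndarray]:
    """Component amplitudes whose noiseless measured apexes equal the targets.

    Newton iteration with an analytic cross-talk Jacobian; the residual is
    evaluated with the pipeline's own baseline + parabolic-apex measurement,
    so convergence means the planted apexes are exactly what the pipeline
    recovers on a noiseless spectrum.
    """
    names = list(model.band_apexes)
    t = np.array([model.band_apexes[n] for n in names], dtype=float)
    active = t > 0
    a = np.zeros_like(t)
    if not active.any():
        return names, a
    shapes = np.vstack([
        pseudo_voigt(model.grid, model.centers[n], model.fwhm[n], model.eta)
        for n in names
    ])
    jac = _crosstalk_matrix(names, model)[np.ix_(active, active)]
    scale = t[active].max()
    a[active] = np.linalg.solve(jac, t[active])
    # The measured apex is piecewise smooth in the amplitudes: when the
    # discrete argmax flips to a neighbouring grid point, the parabola
    # vertex jumps slightly. A target falling inside such a jump gap is not
    # exactly attainable; damping plus stall detection then returns the
    # closest attainable spectrum instead of oscillating.
    best_a = a.copy()
    best_err = np.inf
    stale = 0
    for _ in range(max_iter):
        trace = a @ shapes
        meas = _measured_apexes(model.grid, trace, names, model.centers,
                                model.regions)
        resid = t[active] - meas[active]
        err = np.abs(resid).max() / scale
        if err < best_err - tol:
            best_a, best_err, stale = a.copy(), err, 0
        else:
            stale += 1
        if err < tol or stale >= 6:
            break
        damp = 0.5 ** stale
        a[active] = np.maximum(
            a[active] + damp * np.linalg.solve(jac, resid), 0.0)
    return names, best_a


def simulate_spectrum(model: SpectrumModel, sample_id: str = "synthetic",
                      group_label: str = "") -> Spectrum:
    """One spectrum: calibrated band sum + polynomial baseline + noise."""
    names, a = calibrate_amplitudes(model)
    if names:
        shapes = np.vstack([
            pseudo_voigt(model.grid, model.centers[n], model.fwhm[n],
                         model.eta) for n in names
        ])
        trace = a @ shapes
    else:
        trace = np.zeros_like(model.grid)
    baseline = np.zeros_like(model.grid)
    for k, c in enumerate(model.baseline):
        baseline += c * model.grid ** k
    rng = np.random.default_rng(model.seed)
    noise = (rng.normal(0.0, model.noise_sd, model.grid.size)
             if model.noise_sd > 0 else 0.0)
    return Spectrum(
        sample_id=sample_id,
        group_label=group_label,
        wavenumbers=model.grid.copy(),
        absorbance=trace + baseline + noise,
        meta={"synthetic": True, "seed": model.seed,
              "planted_apexes": dict(model.band_apexes),
              "planted_centers": {n: model.centers[n]
                                  for n in model.band_apexes}},
    )


def _jittered_model(base: SpectrumModel, factors: dict[str, float],
                    shifts: dict[str, float], cv: float, jitter_sd: float,
                    rng: np.random.Generator, seed: int) -> SpectrumModel:
    apexes = {}
    for n, t in base.band_apexes.items():
        f = factors.get(n, 1.0)
        rep = 1.0 + cv * rng.standard_normal() if cv > 0 else 1.0
        apexes[n] = t * f * max(rep, 0.05)
    centers = dict(base.centers)
    for n in base.band_apexes:
        c = centers[n] + shifts.get(n, 0.0)
        if jitter_sd > 0:
            c += jitter_sd * rng.standard_normal()
        centers[n] = c
    return replace(base, band_apexes=apexes, centers=centers, seed=seed)


def simulate_group_pair(base: SpectrumModel, effect: GroupEffect,
                        n_per_group: int = 3, seed: int = 0,
                        labels: tuple[str, str] = ("control", "treated"),
                        ) -> tuple[SpectrumGroup, SpectrumGroup]:
    """Control and treated replicate groups from one base model.

    Control replicates jitter the base apexes with the effect's replicate
    CV; treated replicates additionally apply the multiplicative amplitude
    factors and center shifts. All randomness flows from one seeded
    generator, so identical inputs give identical groups.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    groups = []
    for gi, label in enumerate(labels):
        factors = effect.amplitude_factors if gi == 1 else {}
        shifts = effect.center_shifts if gi == 1 else {}
        reps = []
        for r in range(n_per_group):
            child_seed = int(rng.integers(0, 2**31))
            m = _jittered_model(base, factors, shifts, effect.replicate_cv,
                                effect.position_jitter_sd, rng, child_seed)
            reps.append(simulate_spectrum(m, f"{label}_r{r + 1}", label))
        groups.append(SpectrumGroup(label=label, replicates=reps))
    return groups[0], groups[1]


# ---------------------------------------------------------------------------
# presets emulating the two HeLa contrasts
# ---------------------------------------------------------------------------

def _control_apexes(lipid_protein: float, chain_length: float,
                    olefinic: float, rna_ratio: float = 0.9) -> dict[str, float]:
    """Control-group apex heights hitting the requested index values.

    Absolute scales (CH2 asym 0.50, PO2 sym 0.30 absorbance) are arbitrary:
    every reported metric is a ratio or a normalized intensity.
    """
    ch2_asym = 0.50
    ch3_sym = 0.25
    po2_sym = 0.30
    return {
        "ch2_asym": ch2_asym,
        "ch3_asym": ch2_asym / chain_length,
        "ch3_sym": ch3_sym,
        "ch2_sym": ch3_sym * lipid_protein,
        "olefinic": ch2_asym * olefinic,
        "po2_sym": po2_sym,
        "po2_asym": 0.35,
        "rna_1121": po2_sym * rna_ratio,
        "glycogen_1156": 0.20,
        "protein_co_1171": 0.22,
        "glycogen_996": 0.15,
    }


def preset_pair(name: str, seed: int = 0,
                replicate_cv: Optional[float] = None,
                noise_sd: Optional[float] = None,
                ) -> tuple[SpectrumModel, GroupEffect]:
    """Base model and group effect for a named study preset.

    * ``cisplatin``: DMSO control vs 80 uM cisplatin-treated cells;
    * ``knockdown``: negative-control vs antisense-knockdown cells;
    * ``control``: the DMSO control with a null effect (both groups drawn
      from the same distribution).
    """
    if name in ("cisplatin", "control"):
        apexes = _control_apexes(lipid_protein=1.0769, chain_length=1.48,
                                 olefinic=0.01283)
        centers = dict(_DEFAULT_CENTERS)
        centers["po2_asym"] = 1234.46
        if name == "control":
            effect = GroupEffect(replicate_cv=0.04, position_jitter_sd=0.3)
        else:
            cl = 1.6910 / 1.48
            effect = GroupEffect(
                amplitude_factors={
                    "ch2_sym": 1.3018 / 1.0769,
                    "ch2_asym": cl,
                    "olefinic": (0.011987 / 0.01283) * cl,
                    "glycogen_996": 1.0 - 0.0703,
                    "glycogen_1156": 0.85,
                    "protein_co_1171": 1.3129,
                    "rna_1121": 1.0269,
                },
                center_shifts={"po2_asym": 1235.73 - 1234.46},
                replicate_cv=0.04,
                position_jitter_sd=0.3,
            )
    elif name == "knockdown":
        apexes = _control_apexes(lipid_protein=1.076, chain_length=1.5359,
                                 olefinic=0.03181)
        centers = dict(_DEFAULT_CENTERS)
        centers["po2_sym"] = 1080.92
        centers["po2_asym"] = 1234.52
        cl = 1.630 / 1.5359
        effect = GroupEffect(
            amplitude_factors={
                "ch2_sym": 1.3018 / 1.076,
                "ch2_asym": cl,
                "olefinic": (0.00747 / 0.03181) * cl,
                "glycogen_996": 0.02,  # band almost vanishes
                "glycogen_1156": 0.80,
                "protein_co_1171": 1.0966,
                "rna_1121": 1.1668,
            },
            center_shifts={
                "po2_sym": 1083.09 - 1080.92,
                "po2_asym": 1235.47 - 1234.52,
            },
            replicate_cv=0.04,
            position_jitter_sd=0.3,
        )
    else:
        raise ValidationError(
            f"unknown preset {name!r}; choose control, cisplatin, knockdown")
    model = SpectrumModel(band_apexes=apexes, centers=centers, seed=seed)
    if replicate_cv is not None:
        effect = replace(effect, replicate_cv=replicate_cv,
                         position_jitter_sd=0.0 if replicate_cv == 0
                         else effect.position_jitter_sd)
    if noise_sd is not None:
        model = replace(model, noise_sd=noise_sd)
    return model, effect


def planted_truth(name: str) -> dict:
    """The metric values and shifts a preset plants (for manifests/tests)."""
    model, effect = preset_pair(name)
    a = model.band_apexes
    f = effect.amplitude_factors

    def g(band: str) -> float:
        return f.get(band, 1.0)

    control = {
        "lipid_protein_ratio": a["ch2_sym"] / a["ch3_sym"],
        "chain_length_index": a["ch2_asym"] / a["ch3_asym"],
        "olefinic_index": a["olefinic"] / a["ch2_asym"],
        "rna_content_1121": a["rna_1121"] / a["po2_sym"],
        "glycogen_996": a["glycogen_996"] / a["po2_sym"],
        "glycogen_1156": a["glycogen_1156"] / a["po2_sym"],
        "protein_CO_1171": a["protein_co_1171"] / a["po2_sym"],
        "po2_sym_position": model.centers["po2_sym"],
        "po2_asym_position": model.centers["po2_asym"],
    }
    treated = {
        "lipid_protein_ratio": control["lipid_protein_ratio"]
        * g("ch2_sym") / g("ch3_sym"),
        "chain_length_index": control["chain_length_index"]
        * g("ch2_asym") / g("ch3_asym"),
        "olefinic_index": control["olefinic_index"]
        * g("olefinic") / g("ch2_asym"),
        "rna_content_1121": control["rna_content_1121"]
        * g("rna_1121") / g("po2_sym"),
        "glycogen_996": control["glycogen_996"]
        * g("glycogen_996") / g("po2_sym"),
        "glycogen_1156": control["glycogen_1156"]
        * g("glycogen_1156") / g("po2_sym"),
        "protein_CO_1171": control["protein_CO_1171"]
        * g("protein_co_1171") / g("po2_sym"),
        "po2_sym_position": control["po2_sym_position"]
        + effect.center_shifts.get("po2_sym", 0.0),
        "po2_asym_position": control["po2_asym_position"]
        + effect.center_shifts.get("po2_asym", 0.0),
    }
    return {"control": control, "treated": treated}


def simulate_metric_percent_changes(preset: str, metric: str, n_reps: int,
                                    seed: int = 0, n_per_group: int = 3
                                    ) -> np.ndarray:
    """Repeatedly simulate a preset pair and recover one metric's % change.

    Each repetition draws fresh replicate groups (amplitude scatter,
    position jitter, noise) with a seed derived from the master seed, runs
    the full measurement pipeline per replicate, and records
    100*(mean_treated - mean_control)/mean_control. The returned sample
    characterizes the sampling distribution of the recovered change at the
    preset's group size.
    """
    from .metrics import evaluate_metric, percent_change

    model, effect = preset_pair(preset, seed=seed)
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31))
        c, t = simulate_group_pair(model, effect, n_per_group, seed=rep_seed)
        out[i] = percent_change(evaluate_metric(c, metric).mean,
                                evaluate_metric(t, metric).mean)
    return out


# ---------------------------------------------------------------------------
# DE-table pairs with planted overlap structure
# ---------------------------------------------------------------------------

def simulate_deg_pair(n_genes: int, n_sig_1: int, n_sig_2: int,
                      n_shared: int, n_parallel_up: int,
                      n_parallel_down: int, effect_sd: float = 1.0,
                      seed: int = 0,
                      labels: tuple[str, str] = ("study1", "study2"),
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two DE result tables with exact planted overlap counts.

    Shared significant genes split into parallel-up (positive log2fc in
    both), parallel-down (negative in both) and discordant (opposite
    signs). Significant rows get padj drawn strictly below 0.05,
    non-significant rows at or above 0.05.
    """
    n_parallel = n_parallel_up + n_parallel_down
    if not (n_parallel <= n_shared <= min(n_sig_1, n_sig_2) <= n_genes):
        raise ValidationError(
            "need n_parallel_up + n_parallel_down <= n_shared <= "
            "min(n_sig_1, n_sig_2) <= n_genes")
    if n_sig_1 + n_sig_2 - n_shared > n_genes:
        raise ValidationError("significant sets do not fit in n_genes")
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:06d}" for i in range(n_genes)])
    perm = rng.permutation(n_genes)

    shared = genes[perm[:n_shared]]
    only1 = genes[perm[n_shared:n_sig_1]]
    only2 = genes[perm[n_sig_1:n_sig_1 + (n_sig_2 - n_shared)]]

    up = set(shared[:n_parallel_up])
    down = set(shared[n_parallel_up:n_parallel])
    discordant = shared[n_parallel:]

    def magnitudes(k: int) -> np.ndarray:
        return np.abs(rng.normal(0.0, effect_sd, k)) + 0.25

    def build(label: str, sig_only: np.ndarray, table_index: int
              ) -> pd.DataFrame:
        lfc = pd.Series(rng.normal(0.0, 0.2, n_genes), index=genes)
        padj = pd.Series(rng.uniform(0.05, 1.0, n_genes), index=genes)
        sig = np.concatenate([shared, sig_only])
        padj[sig] = rng.uniform(1e-8, 0.0499, sig.size)
        mags = pd.Series(magnitudes(sig.size), index=sig)
        for gid in sig:
            if gid in up:
                sign = 1.0
            elif gid in down:
                sign = -1.0
            elif gid in set(discordant):
                sign = 1.0 if table_index == 0 else -1.0
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc[gid] = sign * mags[gid]
        df = pd.DataFrame({
            "gene_id": genes,
            "log2fc": lfc.to_numpy(),
            "padj": padj.to_numpy(),
            "biotype": "protein_coding",
        })
        df.attrs["label"] = label
        return df

    return build(labels[0], only1, 0), build(labels[1], only2, 1)
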