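"""Reading, writing and validating FTIR spectra and band catalogs.

A spectrum is a wavenumber grid (cm^-1) plus a unitless absorbance trace.
Instruments typically emit traces in descending wavenumber order; everything
downstream assumes ascending storage, so loaders normalize direction and
record the original orientation in ``meta``.

Supported on-disk formats:

* two-column CSV/TSV (wavenumber, absorbance), optional single header line;
* a JCAMP-DX subset: ``##XYPOINTS=(XY..XY)`` and uncompressed
  ``##XYDATA=(X++(Y..Y))`` with ``XUNITS`` in reciprocal centimeters.

Band catalogs (name, assignment, center, search half-width, region,
normalization reference) load from YAML or CSV; a built-in default catalog
covers the C-H stretching and fingerprint bands used by the macromolecular
indices.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import (
    ParseError,
    UnsupportedDialectError,
    ValidationError,
)

WAVENUMBER_MIN = 450.0
WAVENUMBER_MAX = 4000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """One replicate's absorbance trace on an ascending wavenumber grid."""

    sample_id: str
    group_label: str
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    resolution: float = 4.0
    n_scans: int = 20
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise ValidationError("wavenumbers and absorbance must be 1-D")
        if self.wavenumbers.size != self.absorbance.size:
            raise ValidationError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.absorbance.size} absorbance values"
            )
        if self.wavenumbers.size < 2:
            raise ValidationError("a spectrum needs at least two points")
        d = np.diff(self.wavenumbers)
        if np.any(d == 0):
            dup = self.wavenumbers[:-1][d == 0][0]
            raise ValidationError(f"duplicate wavenumber {dup:g} cm^-1")
        if np.all(d < 0):
            # descending input: store ascending, remember orientation
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[::-1].copy()
            self.meta.setdefault("original_order", "descending")
        elif np.all(d > 0):
            self.meta.setdefault("original_order", "ascending")
        else:
            raise ValidationError("wavenumbers must be strictly monotonic")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance contains non-finite values")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValidationError("wavenumbers contain non-finite values")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavenumbers[0] <= lo and hi <= self.wavenumbers[-1]


@dataclass
class SpectrumGroup:
    """Biological replicates sharing one experimental condition."""

    label: str
    replicates: list[Spectrum]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValidationError(f"group {self.label!r} has no replicates")
        for s in self.replicates:
            if s.group_label != self.label:
                raise ValidationError(
                    f"replicate {s.sample_id!r} carries group "
                    f"{s.group_label!r}, expected {self.label!r}"
                )

    @property
    def n(self) -> int:
        return len(self.replicates)


@dataclass(frozen=True)
class BandDef:
    """A named spectral band with its search window and normalization rule."""

    name: str
    assignment: str
    center: float
    window_halfwidth: float = 8.0
    region_id: str = "fingerprint"
    normalization_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.window_halfwidth <= 0:
            raise ValidationError(
                f"band {self.name!r}: window_halfwidth must be > 0"
            )
        if not (WAVENUMBER_MIN <= self.center <= WAVENUMBER_MAX):
            raise ValidationError(
                f"band {self.name!r}: center {self.center:g} cm^-1 outside "
                f"{WAVENUMBER_MIN:g}-{WAVENUMBER_MAX:g} cm^-1"
            )

    @property
    def window(self) -> tuple[float, float]:
        return (self.center - self.window_halfwidth,
                self.center + self.window_halfwidth)


# Standard C-H stretching and fingerprint assignments for cultured cells.
# The PO2 symmetric stretch is catalogued once at 1082 cm^-1; the 8 cm^-1
# search window covers positions reported anywhere between ~1080 and ~1084.
DEFAULT_CATALOG: tuple[BandDef, ...] = (
    BandDef("olefinic", "=CH olefinic stretch, unsaturated fatty acyl chains",
            3006.0, 8.0, "lipid", "ch2_asym"),
    BandDef("ch3_asym", "CH3 asymmetric stretch (mostly protein)",
            2958.0, 8.0, "lipid", None),
    BandDef("ch2_asym", "CH2 asymmetric stretch (mostly lipid acyl chains)",
            2924.0, 8.0, "lipid", None),
    BandDef("ch3_sym", "CH3 symmetric stretch (mostly protein)",
            2872.0, 8.0, "lipid", None),
    BandDef("ch2_sym", "CH2 symmetric stretch (mostly lipid acyl chains)",
            2852.0, 8.0, "lipid", None),
    BandDef("po2_asym", "PO2- asymmetric stretch, nucleic acid backbone",
            1234.0, 8.0, "fingerprint", None),
    BandDef("protein_co_1171", "C-O stretch of proteins / CO-O-C of "
            "cholesterol esters", 1171.0, 8.0, "fingerprint", "po2_sym"),
    BandDef("glycogen_1156", "C-O stretch, glycogen", 1156.0, 8.0,
            "fingerprint", "po2_sym"),
    BandDef("rna_1121", "ribose C-O stretch, RNA", 1121.0, 8.0,
            "fingerprint", "po2_sym"),
    BandDef("po2_sym", "PO2- symmetric stretch, nucleic acid backbone",
            1082.0, 8.0, "fingerprint", None),
    BandDef("glycogen_996", "C-O / C-C stretch, glycogen", 996.0, 8.0,
            "fingerprint", "po2_sym"),
)


def catalog_by_name(catalog: Sequence[BandDef]) -> dict[str, BandDef]:
    return {b.name: b for b in catalog}


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",")]
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    return line.split()


def read_spectrum_csv(path: str | Path, sample_id: str | None = None,
                      group_label: str = "") -> Spectrum:
    """Read a two-column (wavenumber, absorbance) CSV/TSV file.

    A single non-numeric first row is treated as a header. Rows may be
    comma-, tab- or whitespace-separated with '.' as the decimal mark.
    """
    path = Path(path)
    wn: list[float] = []
    ab: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line)
            if len(fields) < 2:
                raise ParseError(f"{path.name}:{lineno}: expected two columns")
            if lineno == 1 and not _NUMERIC_RE.match(fields[0]):
                continue  # header row
            try:
                x, y = float(fields[0]), float(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric row {line!r}"
                ) from None
            wn.append(x)
            ab.append(y)
    if len(wn) < 2:
        raise ParseError(f"{path.name}: fewer than two data rows")
    if len(set(wn)) != len(wn):
        seen: set[float] = set()
        for x in wn:
            if x in seen:
                raise ValidationError(
                    f"{path.name}: duplicate wavenumber {x:g} cm^-1")
            seen.add(x)
    return Spectrum(
        sample_id=sample_id or path.stem,
        group_label=group_label,
        wavenumbers=np.array(wn),
        absorbance=np.array(ab),
        meta={"source": str(path)},
    )


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV with full float precision (round-trip safe)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavenumber", "absorbance"])
        for x, y in zip(spectrum.wavenumbers, spectrum.absorbance):
            writer.writerow([repr(float(x)), repr(float(y))])


def read_group_dir(directory: str | Path, label: str) -> SpectrumGroup:
    """Load every ``*.csv`` / ``*.tsv`` spectrum in a directory as one group."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in {".csv", ".tsv", ".txt"}
    ) if directory.is_dir() else []
    if not paths:
        raise ValidationError(f"no spectrum files found in {directory}")
    reps = [read_spectrum_csv(p, group_label=label) for p in paths]
    return SpectrumGroup(label=label, replicates=reps)


# ---------------------------------------------------------------------------
# JCAMP-DX subset
# ---------------------------------------------------------------------------

_XUNITS_OK = {"1/CM", "CM-1", "CM^-1", "RECIPROCAL CM", "WAVENUMBER (CM-1)"}
_AFFN_LINE_RE = re.compile(r"^[\s+\-.\deE,;]+$")


def _jcamp_records(text: str) -> tuple[dict[str, str], list[tuple[str, list[str]]]]:
    """Split a JCAMP-DX file into header fields and data blocks."""
    header: dict[str, str] = {}
    blocks: list[tuple[str, list[str]]] = []
    current: Optional[tuple[str, list[str]]] = None
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key in ("XYDATA", "XYPOINTS", "PEAKTABLE"):
                current = (key, [])
                blocks.append(current)
                header[key] = value
            else:
                current = None
                header[key] = value
        elif current is not None:
            current[1].append(line.strip())
    return header, blocks


def read_jcamp(path: str | Path) -> Spectrum:
    """Read a JCAMP-DX spectrum (XYPOINTS or uncompressed XYDATA only).

    ``XYDATA=(X++(Y..Y))`` lines are decoded with FIRSTX/DELTAX/XFACTOR/
    YFACTOR per the JCAMP-DX convention; SQZ/DIF/DUP compressed dialects
    raise :class:`UnsupportedDialectError`.
    """
    path = Path(path)
    header, blocks = _jcamp_records(path.read_text())

    xunits = header.get("XUNITS", "").upper()
    if xunits and xunits not in _XUNITS_OK:
        raise UnsupportedDialectError(
            f"{path.name}: unsupported XUNITS {xunits!r}; expected 1/CM")
    if not blocks:
        raise ParseError(f"{path.name}: no XYDATA or XYPOINTS block found")
    kind, lines = blocks[0]

    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))

    if kind in ("XYPOINTS", "PEAKTABLE"):
        xs: list[float] = []
        ys: list[float] = []
        for line in lines:
            for pair in re.split(r"[;]", line):
                pair = pair.strip()
                if not pair:
                    continue
                parts = re.split(r"[,\s]+", pair)
                if len(parts) != 2:
                    raise ParseError(
                        f"{path.name}: malformed XYPOINTS pair {pair!r}")
                xs.append(float(parts[0]) * xfactor)
                ys.append(float(parts[1]) * yfactor)
        wn, ab = np.array(xs), np.array(ys)
    else:  # XYDATA
        form = header.get("XYDATA", "").replace(" ", "").upper()
        if form not in ("(X++(Y..Y))", ""):
            raise UnsupportedDialectError(
                f"{path.name}: unsupported XYDATA form {form!r}")
        firstx = float(header["FIRSTX"])
        deltax = float(header.get("DELTAX", 0) or 0)
        npoints = int(float(header.get("NPOINTS", 0) or 0))
        if not deltax:
            lastx = float(header["LASTX"])
            deltax = (lastx - firstx) / (npoints - 1)
        ys = []
        for line in lines:
            if not _AFFN_LINE_RE.match(line):
                raise UnsupportedDialectError(
                    f"{path.name}: compressed (SQZ/DIF/DUP) XYDATA is not "
                    f"supported: {line!r}")
            vals = [float(v) for v in re.split(r"[,\s]+", line.strip()) if v]
            ys.extend(vals[1:])  # first value on each line is the X check
        ab = np.array(ys) * yfactor
        wn = (firstx + deltax * np.arange(ab.size)) * xfactor
    return Spectrum(
        sample_id=header.get("TITLE", path.stem) or path.stem,
        group_label="",
        wavenumbers=wn,
        absorbance=ab,
        resolution=float(header.get("RESOLUTION", 4.0) or 4.0),
        meta={"source": str(path), "format": "jcamp-dx"},
    )


# ---------------------------------------------------------------------------
# band catalogs
# ---------------------------------------------------------------------------

_CATALOG_FIELDS = ("name", "assignment", "center", "window_halfwidth",
                   "region_id", "normalization_ref")


def load_band_catalog(path: str | Path | None = None) -> list[BandDef]:
    """Load a band catalog from YAML or CSV; the built-in default if no path.

    YAML form: a list of mappings with keys name, assignment, center,
    window_halfwidth, region_id, normalization_ref. CSV uses the same
    column names. Validation (bounds, positive half-widths) happens in
    :class:`BandDef`.
    """
    if path is None:
        return list(DEFAULT_CATALOG)
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        entries = yaml.safe_load(path.read_text())
        if isinstance(entries, dict):
            entries = entries.get("bands", entries)
        if not isinstance(entries, list):
            raise ParseError(f"{path.name}: expected a list of band entries")
    else:
        with open(path) as fh:
            entries = list(csv.DictReader(fh))
    bands = []
    for i, e in enumerate(entries, start=1):
        try:
            ref = e.get("normalization_ref") or None
            if isinstance(ref, str) and not ref.strip():
                ref = None
            bands.append(BandDef(
                name=str(e["name"]),
                assignment=str(e.get("assignment", "")),
                center=float(e["center"]),
                window_halfwidth=float(e.get("window_halfwidth", 8.0) or 8.0),
                region_id=str(e.get("region_id", "fingerprint")),
                normalization_ref=ref,
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(
                f"{path.name}: bad catalog entry {i}: {exc}") from exc
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise ValidationError(f"{path.name}: duplicate band names")
    return bands
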