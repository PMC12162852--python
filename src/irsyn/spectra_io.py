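"""Core spectral data types and readers/writers.

The universal currency of the pipeline is :class:`Spectrum` — a strictly
monotonic wavenumber grid (cm⁻¹) with absorbance values (AU).  Spectra are
stored internally with *descending* wavenumbers (FTIR plotting convention);
readers reorder ascending input and record the original orientation in
``meta``.

Supported on-disk formats: two-column CSV (configurable dialect) and a
minimal single-block JCAMP-DX (XYPOINTS and AFFN XYDATA), the community
standard for infrared exchange.  Cohort tables are plain TSV/CSV read via
pandas.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "KineticsTrace",
    "MeasurementRun",
    "SubjectRecord",
    "DIAGNOSIS_VOCABULARY",
    "MISFOLDING_POSITIVE_DIAGNOSES",
    "derive_group",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectrum_jcampdx",
    "write_spectrum_jcampdx",
    "read_cohort_table",
    "write_cohort_table",
]


class SpectrumValidationError(ValueError):
    """Raised when a wavenumber grid or absorbance vector is invalid."""


class SchemaError(ValueError):
    """Raised when a cohort table misses mandatory columns or vocabulary."""


@dataclass
class Spectrum:
    """An infrared spectrum: wavenumber grid (cm⁻¹) vs absorbance (AU).

    Parameters
    ----------
    wavenumbers
        Strictly monotonic grid in cm⁻¹.  Ascending input is flipped to the
        canonical descending orientation; the original orientation is kept in
        ``meta["original_orientation"]``.
    absorbance
        Same-length vector of absorbance values; must be finite.
    meta
        Free-form key/value metadata (subject id, channel, stage tag,
        ``smoothed`` flag, processing trace, ...).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if nu.ndim != 1 or a.ndim != 1:
            raise SpectrumValidationError("wavenumbers and absorbance must be 1-D")
        if nu.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if nu.size != a.size:
            raise SpectrumValidationError(
                f"length mismatch: {nu.size} wavenumbers vs {a.size} absorbances"
            )
        d = np.diff(nu)
        if np.all(d > 0):
            nu, a = nu[::-1].copy(), a[::-1].copy()
            self.meta.setdefault("original_orientation", "ascending")
        elif np.all(d < 0):
            self.meta.setdefault("original_orientation", "descending")
        else:
            raise SpectrumValidationError("wavenumber grid must be strictly monotonic")
        if not np.all(np.isfinite(nu)) or not np.all(np.isfinite(a)):
            raise SpectrumValidationError("non-finite values in spectrum")
        self.wavenumbers = nu
        self.absorbance = a

    # -- convenience -------------------------------------------------------

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        """(wavenumbers, absorbance) views in ascending wavenumber order."""
        return self.wavenumbers[::-1], self.absorbance[::-1]

    def interp(self, nu: float | np.ndarray) -> float | np.ndarray:
        """Absorbance at ``nu`` by linear interpolation between grid points.

        Fractional wavenumbers (e.g. 1623.5 on a 2 cm⁻¹ grid) are always
        interpolated, never snapped to the nearest grid point.
        """
        x, y = self.ascending
        lo, hi = x[0], x[-1]
        if np.any(np.asarray(nu) < lo) or np.any(np.asarray(nu) > hi):
            raise ValueError(f"wavenumber {nu} outside grid span [{lo}, {hi}]")
        out = np.interp(nu, x, y)
        return float(out) if np.isscalar(nu) else out

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points inside the closed interval [lo, hi]."""
        if lo > hi:
            lo, hi = hi, lo
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)

    def window(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        """(wavenumbers, absorbance) restricted to the closed window."""
        m = self.window_mask(lo, hi)
        if not m.any():
            raise ValueError(f"window [{lo}, {hi}] contains no grid points")
        return self.wavenumbers[m], self.absorbance[m]

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavenumbers.size == other.wavenumbers.size and np.array_equal(
            self.wavenumbers, other.wavenumbers
        )

    def with_absorbance(self, a: np.ndarray, **meta_updates) -> "Spectrum":
        """New Spectrum on the same grid with fresh absorbance and meta."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavenumbers.copy(), np.asarray(a, dtype=float), meta)


@dataclass
class KineticsTrace:
    """Absorbance vs time at one probe wavenumber (binding kinetics).

    Default probe is 1550 cm⁻¹ (Amide-II flank), the standard read-out for
    bound-protein kinetics.
    """

    times: np.ndarray
    absorbance: np.ndarray
    probe_wavenumber: float = 1550.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.size != a.size:
            raise ValueError("times and absorbance must have equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        self.times, self.absorbance = t, a

    def __len__(self) -> int:
        return self.times.size


@dataclass
class MeasurementRun:
    """One subject's acquisition: background and sample-wash spectra plus
    optional kinetics."""

    background: list
    sample_wash: list
    subject_id: str = ""
    channel: str = "ch1"
    reference_channel: bool = False
    kinetics: Optional[KineticsTrace] = None

    def __post_init__(self) -> None:
        if not self.background or not self.sample_wash:
            raise ValueError("a run needs at least one background and one wash spectrum")
        ref = self.background[0]
        for s in list(self.background) + list(self.sample_wash):
            if not ref.same_grid(s):
                raise ValueError("background and sample_wash must share one grid")


DIAGNOSIS_VOCABULARY = frozenset({"PD", "MSA", "CBD", "FTD", "PSP", "control", "other"})
MISFOLDING_POSITIVE_DIAGNOSES = frozenset({"PD", "MSA"})


def derive_group(diagnosis: str) -> str:
    """Map a diagnosis to the analysis group.

    PD and MSA are the synucleinopathies with expected αSyn misfolding and
    form the misfolding-positive group; every other vocabulary entry (CBD,
    FTD, PSP, control, other) is a disease control.
    """
    if diagnosis not in DIAGNOSIS_VOCABULARY:
        raise SchemaError(f"unknown diagnosis {diagnosis!r}")
    return "misfolding_positive" if diagnosis in MISFOLDING_POSITIVE_DIAGNOSES else "control"


@dataclass
class SubjectRecord:
    """Per-subject clinical metadata plus derived spectral read-outs."""

    subject_id: str
    diagnosis: str
    age: float
    sex: str
    q_alb: Optional[float] = None
    features: Optional[object] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        derive_group(self.diagnosis)  # vocabulary check
        if self.sex not in ("F", "M"):
            raise SchemaError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not self.age > 0:
            raise SchemaError(f"age must be positive, got {self.age}")

    @property
    def group(self) -> str:
        return derive_group(self.diagnosis)

    @property
    def is_positive(self) -> bool:
        return self.group == "misfolding_positive"


# ---------------------------------------------------------------------------
# CSV spectra
# ---------------------------------------------------------------------------

_DIALECTS = {
    "comma": {"delimiter": ",", "decimal": "."},
    "semicolon": {"delimiter": ";", "decimal": ","},
}


def read_spectrum_csv(path, dialect: str = "comma") -> Spectrum:
    """Read a two-column (wavenumber, absorbance) CSV file.

    ``dialect="comma"`` is comma-delimited with dot decimal mark (default);
    ``dialect="semicolon"`` is semicolon-delimited with comma decimal mark.
    A single non-numeric header row is tolerated and skipped.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown CSV dialect {dialect!r}")
    delim = _DIALECTS[dialect]["delimiter"]
    dec = _DIALECTS[dialect]["decimal"]
    nus, absb = [], []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {i}: expected 2 columns, got {len(row)}")
            try:
                nu = float(row[0].strip().replace(dec, "."))
                a = float(row[1].strip().replace(dec, "."))
            except ValueError:
                if i == 1:  # header row
                    continue
                raise ValueError(f"{path}: line {i}: non-numeric row {row!r}") from None
            nus.append(nu)
            absb.append(a)
    try:
        s = Spectrum(np.array(nus), np.array(absb))
    except SpectrumValidationError as e:
        raise SpectrumValidationError(f"{path}: {e}") from None
    s.meta["source"] = str(path)
    s.meta["dialect"] = dialect
    return s


def write_spectrum_csv(spectrum: Spectrum, path, dialect: str = "comma") -> None:
    """Write a Spectrum as two-column CSV in the requested dialect."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown CSV dialect {dialect!r}")
    delim = _DIALECTS[dialect]["delimiter"]
    dec = _DIALECTS[dialect]["decimal"]
    with open(path, "w", newline="") as fh:
        for nu, a in zip(spectrum.wavenumbers, spectrum.absorbance):
            line = f"{float(nu)!r}{delim}{float(a)!r}"
            if dec != ".":
                line = line.replace(".", dec)
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------


def _parse_jcamp_labels(text: str) -> tuple[dict, list[tuple[str, str]]]:
    """Split a JCAMP-DX block into {LABEL: value} plus ordered data sections."""
    labels: dict[str, str] = {}
    data_sections: list[tuple[str, str]] = []
    current_label = None
    current_lines: list[str] = []
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()  # strip comments
        if not line.strip():
            continue
        if line.startswith("##"):
            if current_label is not None:
                data_sections.append((current_label, "\n".join(current_lines)))
                current_label, current_lines = None, []
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key in ("XYDATA", "XYPOINTS"):
                current_label = key
            else:
                labels[key] = value
        elif current_label is not None:
            current_lines.append(line)
    if current_label is not None:
        data_sections.append((current_label, "\n".join(current_lines)))
    return labels, data_sections


def read_spectrum_jcampdx(path) -> Spectrum:
    """Read a single-block JCAMP-DX file (XYPOINTS or AFFN XYDATA).

    XFACTOR/YFACTOR are applied; for XYDATA=(X++(Y..Y)) the grid is
    reconstructed from FIRSTX/LASTX/NPOINTS.  Multi-block (compound) files
    are not supported.
    """
    text = Path(path).read_text()
    if text.upper().count("##TITLE") > 1:
        raise ValueError(f"{path}: multi-block JCAMP-DX files are not supported")
    labels, sections = _parse_jcamp_labels(text)
    if not sections:
        raise ValueError(f"{path}: no XYDATA/XYPOINTS section found")
    kind, body = sections[0]
    xfactor = float(labels.get("XFACTOR", 1.0))
    yfactor = float(labels.get("YFACTOR", 1.0))

    if kind == "XYPOINTS":
        nums = [float(t) for chunk in body.replace(";", "\n").splitlines()
                for t in chunk.replace(",", " ").split()]
        if len(nums) % 2:
            raise ValueError(f"{path}: odd number of values in XYPOINTS")
        arr = np.array(nums).reshape(-1, 2)
        nu = arr[:, 0] * xfactor
        a = arr[:, 1] * yfactor
    else:  # AFFN XYDATA (X++(Y..Y))
        for req in ("FIRSTX", "LASTX", "NPOINTS"):
            if req not in labels:
                raise ValueError(f"{path}: missing required label ##{req}=")
        firstx = float(labels["FIRSTX"])
        lastx = float(labels["LASTX"])
        npoints = int(float(labels["NPOINTS"]))
        ys: list[float] = []
        for line in body.splitlines():
            vals = line.replace(",", " ").split()
            if not vals:
                continue
            ys.extend(float(v) for v in vals[1:])  # first value is the X check value
        if len(ys) != npoints:
            raise ValueError(f"{path}: NPOINTS={npoints} but {len(ys)} Y values read")
        nu = np.linspace(firstx, lastx, npoints) * xfactor
        a = np.array(ys) * yfactor

    s = Spectrum(nu, a)
    s.meta["source"] = str(path)
    s.meta["jcamp_title"] = labels.get("TITLE", "")
    return s


def write_spectrum_jcampdx(spectrum: Spectrum, path, title: str = "spectrum",
                           yfactor: float = 1e-9) -> None:
    """Write a Spectrum as AFFN XYDATA JCAMP-DX.

    Y values are stored as integers scaled by ``yfactor`` (default 1e-9 AU
    quantisation, far below instrument noise).
    """
    nu = spectrum.wavenumbers
    a = spectrum.absorbance
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1.0",
        f"##YFACTOR={float(yfactor)!r}",
        f"##FIRSTX={float(nu[0])!r}",
        f"##LASTX={float(nu[-1])!r}",
        f"##NPOINTS={nu.size}",
        "##XYDATA=(X++(Y..Y))",
    ]
    yint = np.round(a / yfactor).astype(np.int64)
    per_line = 6
    for i in range(0, nu.size, per_line):
        chunk = yint[i : i + per_line]
        lines.append(f"{nu[i]:.4f} " + " ".join(str(v) for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = ("subject_id", "diagnosis", "age", "sex")


def read_cohort_table(path, sep: Optional[str] = None) -> list[SubjectRecord]:
    """Read a TSV/CSV cohort table into validated :class:`SubjectRecord` s.

    Mandatory columns: subject_id, diagnosis, age, sex; optional: q_alb.
    The separator is sniffed from the extension unless given explicitly.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        q = row.get("q_alb")
        q_alb = None if q is None or (isinstance(q, float) and np.isnan(q)) else float(q)
        try:
            rec = SubjectRecord(
                subject_id=str(row["subject_id"]),
                diagnosis=str(row["diagnosis"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                q_alb=q_alb,
            )
        except SchemaError as e:
            raise SchemaError(f"{path}: row {i + 2}: {e}") from None
        records.append(rec)
    return records


def write_cohort_table(records: Sequence[SubjectRecord], path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "q_alb": [r.q_alb if r.q_alb is not None else np.nan for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)
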