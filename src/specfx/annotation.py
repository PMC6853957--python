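"""Compound annotation: monoisotopic masses, adduct m/z, ppm matching of
observed LC-MS features to a curated compound library, and cross-mode
compound-level deduplication.

The packaged default library covers the 26 common characteristic peaks of
salt-stressed Apocyni Veneti Folium (12 positive-mode, 14 negative-mode),
with molecular formulas, observed adduct m/z, MS/MS fragment ions, and a
flag for identities confirmed against reference standards. Isomeric pairs
(hyperoside/isoquercitrin; the malonyl-glucoside vs -galactoside) share a
mass, so retention time is a mandatory gate, not optional evidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass

from .exceptions import ConfigurationError, ParseError

PROTON_MASS = 1.00727646  # Da

#: elements accepted in library formulas
ALLOWED_ELEMENTS = {"C", "H", "N", "O", "S", "P"}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

#: default ppm tolerances per ion mode. The positive-mode tolerance is wider
#: because printed positive-mode m/z values in the source library deviate up
#: to ~19 ppm from theory (e.g. chlorogenic acid at 355.0956 vs 355.1024).
DEFAULT_PPM_TOL = {"positive": 25.0, "negative": 10.0}


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a molecular formula over C, H, N, O, S, P.

    Sums most-abundant-isotope masses (pyteomics' NIST values; e.g. 12C
    exactly 12, 1H 1.00782503...).
    """
    if not formula or not formula.strip():
        raise ParseError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula.strip()):
        if m.start() != pos:
            raise ParseError(f"cannot parse formula {formula!r}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in ALLOWED_ELEMENTS:
            raise ParseError(f"unsupported element {elem!r} in {formula!r}")
        n = int(num) if num else 1
        if n <= 0:
            raise ParseError(f"non-positive count for {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + n
    if pos != len(formula.strip()) or not counts:
        raise ParseError(f"cannot parse formula {formula!r}")
    return float(_pt_mass.calculate_mass(composition=counts))


def adduct_mz(mass_da: float, adduct: str) -> float:
    """m/z of a singly charged adduct ion: [M+H]+ or [M-H]-."""
    key = adduct.replace("−", "-").replace(" ", "")
    if key == "[M+H]+":
        return mass_da + PROTON_MASS
    if key == "[M-H]-":
        if mass_da <= PROTON_MASS:
            raise ConfigurationError(f"mass {mass_da} too small for deprotonation")
        return mass_da - PROTON_MASS
    raise ConfigurationError(f"unsupported adduct {adduct!r}")


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass error in parts per million."""
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry: an identified (or Unknown) characteristic peak."""

    peak_id: str
    compound: str
    formula: str | None
    adduct: str
    mz_observed: float
    t_R_min: float
    fragments: tuple[float, ...] = ()
    standard_confirmed: bool = False
    compound_class: str = "unknown"

    def __post_init__(self) -> None:
        if (self.formula is None) != (self.compound == "Unknown"):
            raise ParseError(
                f"{self.peak_id}: formula must be absent iff compound is 'Unknown'"
            )
        if self.mz_observed <= 0:
            raise ParseError(f"{self.peak_id}: observed m/z must be positive")
        if self.mode == "positive" and self.adduct != "[M+H]+":
            raise ParseError(f"{self.peak_id}: adduct {self.adduct} inconsistent with mode")
        if self.mode == "negative" and self.adduct != "[M-H]-":
            raise ParseError(f"{self.peak_id}: adduct {self.adduct} inconsistent with mode")

    @property
    def mode(self) -> str:
        return "positive" if self.peak_id.startswith("P") else "negative"

    @property
    def mz_theoretical(self) -> float | None:
        """Adduct m/z from the formula's monoisotopic mass; None for Unknowns."""
        if self.formula is None:
            return None
        return adduct_mz(monoisotopic_mass(self.formula), self.adduct)


class CompoundLibrary:
    """A list of :class:`CompoundRecord` with peak-id and name lookups."""

    def __init__(self, records: Iterable[CompoundRecord]):
        self.records: list[CompoundRecord] = list(records)
        self._by_id: dict[str, CompoundRecord] = {}
        for rec in self.records:
            if rec.peak_id in self._by_id:
                raise ParseError(f"duplicate peak id {rec.peak_id!r} in library")
            self._by_id[rec.peak_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, peak_id: str) -> bool:
        return peak_id in self._by_id

    def get(self, peak_id: str) -> CompoundRecord:
        try:
            return self._by_id[peak_id]
        except KeyError:
            raise KeyError(f"peak id {peak_id!r} not in library") from None

    def by_compound(self, name: str) -> list[CompoundRecord]:
        return [r for r in self.records if r.compound == name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) | {"mode": r.mode} for r in self.records]).set_index("peak_id")


def load_library(path=None) -> CompoundLibrary:
    """Load a compound library CSV; default: the packaged AVF library."""
    if path is None:
        ref = resources.files("specfx.data") / "avf_compound_library.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        frags = ()
        if isinstance(row.get("fragments"), str) and row["fragments"]:
            frags = tuple(float(x) for x in row["fragments"].split(";"))
        formula = row["formula"] if isinstance(row["formula"], str) and row["formula"] else None
        records.append(
            CompoundRecord(
                peak_id=row["peak_id"],
                compound=row["compound"],
                formula=formula,
                adduct=row["adduct"],
                mz_observed=float(row["mz_observed"]),
                t_R_min=float(row["t_R_min"]),
                fragments=frags,
                standard_confirmed=bool(int(row["standard_confirmed"])),
                compound_class=row["compound_class"],
            )
        )
    return CompoundLibrary(records)


def match_features(
    features: pd.DataFrame,
    library: CompoundLibrary,
    ppm_tol: Mapping[str, float] | float | None = None,
    rt_tol: float = 0.2,
) -> pd.DataFrame:
    """Annotate observed features against a library by m/z and retention time.

    ``features`` needs columns ``mz``, ``t_R_min``, ``mode``. Each feature is
    assigned the library record minimizing |ppm error| among candidates that
    pass both the m/z gate (<= ppm_tol for the feature's mode) and the t_R
    gate (<= rt_tol minutes). Unmatched features are labeled unidentified —
    not an error. Fragment evidence is reported as the count of library
    fragment m/z found within the feature's optional ``fragment_mzs`` list
    (qualitative evidence only, never a gate).
    """
    if ppm_tol is None:
        ppm_tol = dict(DEFAULT_PPM_TOL)
    if isinstance(ppm_tol, (int, float)):
        ppm_tol = {"positive": float(ppm_tol), "negative": float(ppm_tol)}
    if rt_tol <= 0 or any(v <= 0 for v in ppm_tol.values()):
        raise ConfigurationError("tolerances must be positive")

    rows = []
    for idx, feat in features.iterrows():
        mode = feat["mode"]
        best = None
        for rec in library:
            if rec.mode != mode:
                continue
            dppm = ppm_error(float(feat["mz"]), rec.mz_observed)
            drt = abs(float(feat["t_R_min"]) - rec.t_R_min)
            if abs(dppm) <= ppm_tol[mode] and drt <= rt_tol:
                if best is None or abs(dppm) < abs(best[1]):
                    best = (rec, dppm, drt)
        if best is None:
            rows.append(
                {"feature": idx, "peak_id": None, "compound": "unidentified",
                 "ppm_error": np.nan, "rt_error_min": np.nan, "n_fragments_matched": 0}
            )
        else:
            rec, dppm, drt = best
            nfrag = 0
            if "fragment_mzs" in features.columns and isinstance(feat.get("fragment_mzs"), (list, tuple)):
                for lf in rec.fragments:
                    if any(abs(ppm_error(f, lf)) <= ppm_tol[mode] for f in feat["fragment_mzs"]):
                        nfrag += 1
            rows.append(
                {"feature": idx, "peak_id": rec.peak_id, "compound": rec.compound,
                 "ppm_error": dppm, "rt_error_min": drt, "n_fragments_matched": nfrag}
            )
    return pd.DataFrame(rows).set_index("feature")


def dedupe_compounds(peak_ids: Iterable[str], library: CompoundLibrary) -> list[dict]:
    """Collapse peaks naming the same compound into compound-level markers.

    Peaks observed in both ion modes (e.g. chlorogenic acid as its [M+H]+
    and [M-H]- adducts) share a library compound name and merge into one
    marker; peaks named "Unknown" never merge with each other. Output order
    follows first appearance in the (sorted) input. Idempotent and
    order-invariant.
    """
    ids = sorted(set(peak_ids), key=_peak_sort_key)
    for pid in ids:
        if pid not in library:
            raise KeyError(f"peak id {pid!r} not in library")
    markers: list[dict] = []
    by_name: dict[str, dict] = {}
    for pid in ids:
        rec = library.get(pid)
        if rec.compound != "Unknown" and rec.compound in by_name:
            by_name[rec.compound]["member_peaks"].append(pid)
            continue
        marker = {
            "compound": rec.compound if rec.compound != "Unknown" else f"Unknown ({pid})",
            "compound_class": rec.compound_class,
            "member_peaks": [pid],
            "is_unknown": rec.compound == "Unknown",
        }
        markers.append(marker)
        if rec.compound != "Unknown":
            by_name[rec.compound] = marker
    return markers


def _peak_sort_key(pid: str) -> tuple:
    m = re.fullmatch(r"([PN])(\d+)", pid)
    if m:
        return (0 if m.group(1) == "P" else 1, int(m.group(2)))
    return (2, pid)
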