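"""Packaged reference tables for the salt-stressed AVF study.

Besides the compound library (see :mod:`specfx.annotation`), the package
ships the study's reported screening inputs so the marker-selection stages
can be run and checked without raw chromatograms:

* per-indicator grey relational grades and ranks of all 26 common
  characteristic peaks (both ion modes);
* the Pearson correlation matrix between peak areas and the six efficacy
  indicators, with the reported significance stars;
* the reported GCA (17 peaks) and BCA (7 peaks) marker selections. The
  reported GCA list is not exactly the literal top-5-per-indicator output of
  the grade table (that rule yields a 20-peak union also containing P9, P12
  and N5), so it is shipped verbatim for union/dedupe validation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("specfx.data") / name
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def load_gca_grades() -> pd.DataFrame:
    """Reported GCA grades: columns indicator, rank, peak_id, grade.

    Ranks restart at 1 for each (indicator, ion mode) block.
    """
    return _read("avf_gca_grades.csv")


def gca_grade_series() -> dict[str, pd.Series]:
    """Reported grades reshaped for :func:`specfx.fingerprint_activity.screen_gca`:
    a peak -> grade Series per indicator."""
    df = load_gca_grades()
    return {
        ind: sub.set_index("peak_id")["grade"]
        for ind, sub in df.groupby("indicator", sort=False)
    }


def load_pearson_r() -> pd.DataFrame:
    """Reported Pearson r per peak (rows) and indicator (columns);
    'starred' flags the indicator reported significant at p < 0.05."""
    return _read("avf_pearson_r.csv").set_index("peak_id")


def pearson_r_matrix() -> pd.DataFrame:
    """Just the numeric r matrix (peak x indicator)."""
    return load_pearson_r().drop(columns=["starred"])


def load_marker_selection() -> dict[str, set[str]]:
    """Reported marker selections: {'gca': 17 peak ids, 'bca': 7 peak ids}."""
    df = _read("avf_marker_selection.csv")
    return {m: set(sub["peak_id"]) for m, sub in df.groupby("method", sort=False)}
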