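"""Synthetic data emulating a salt-stress fingerprint/efficacy study.

Generates the three inputs the pipeline consumes, with the statistical
structure the analysis assumes:

* a sample x peak area matrix (4 NaCl treatments — 0/100/200/300 mM — times
  3 replicates; 12 positive-mode and 14 negative-mode common characteristic
  peaks taken from the packaged compound library), with multiplicative
  lognormal replicate noise;
* per-sample peak lists with retention-time jitter and decoy peaks that are
  absent from at least one sample, for exercising common-peak detection;
* per-animal efficacy endpoints (11 groups x 6 indicators, n animals each)
  drawn from normals truncated at zero.

The default effect profile encodes the salt-stress narrative the pipeline is
designed to recover: polyphenol-class peaks (flavonoids and phenylpropanoids)
accumulate most under low salt (maximum at 100 mM, declining at 200/300 mM)
while other constituents stay flat, and efficacy endpoints separate the CCl4
model group from treated groups. All randomness flows from a single integer
seed; identical (config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation
from .exceptions import ConfigurationError
from .fingerprint_core import (
    GRADIENT_WINDOW_MIN,
    FingerprintMatrix,
    SamplePeakList,
)
from .pharmacology import INDICATORS, UNITS, EfficacyTable

#: NaCl treatment levels, mM
DEFAULT_TREATMENTS = (0, 100, 200, 300)

#: dose groups of the efficacy study
GROUPS = [
    "control", "model", "silymarin",
    "L0", "L100", "L200", "L300",
    "H0", "H100", "H200", "H300",
]

#: per-treatment area multipliers for polyphenol-class peaks: accumulation
#: peaks under low salt stress and declines under medium/high stress
POLYPHENOL_EFFECT = {0: 1.0, 100: 1.35, 200: 0.60, 300: 0.50}
FLAT_EFFECT = {0: 1.0, 100: 1.0, 200: 1.0, 300: 1.0}

#: classes treated as polyphenols in the default effect profile
POLYPHENOL_CLASSES = {"flavonoid", "phenylpropanoid"}

#: baseline integrated areas by compound class (arbitrary instrument counts;
#: flavonoids dominate the chromatogram)
BASELINE_BY_CLASS = {
    "flavonoid": 300.0,
    "phenylpropanoid": 150.0,
    "organic acid": 120.0,
    "terpenoid": 90.0,
    "quinone": 70.0,
    "unknown": 100.0,
}

#: default efficacy endpoint (mean, SD) per group and indicator. Serum
#: transaminases in U/L; hepatic markers per mg protein. The CCl4 model group
#: is elevated in ALT/AST/MDA and depressed in SOD/CAT/POD; silymarin and
#: high-dose groups recover toward control, with the low-salt (100 mM)
#: high-dose group best.
DEFAULT_EFFICACY: dict[str, dict[str, tuple[float, float]]] = {
    "control":   {"ALT": (25.40, 3.0),  "AST": (24.63, 3.0),  "MDA": (2.1, 0.25), "SOD": (122, 10), "CAT": (40.5, 4.0), "POD": (30.2, 3.0)},
    "model":     {"ALT": (130.67, 12.0), "AST": (99.77, 10.0), "MDA": (6.4, 0.60), "SOD": (61, 6),   "CAT": (20.3, 2.5), "POD": (15.1, 2.0)},
    "silymarin": {"ALT": (54.63, 6.0),  "AST": (39.75, 4.5),  "MDA": (2.8, 0.30), "SOD": (115, 9),  "CAT": (37.0, 3.5), "POD": (33.0, 3.0)},
    "L0":        {"ALT": (92.57, 9.0),  "AST": (68.70, 7.0),  "MDA": (3.9, 0.40), "SOD": (66, 7),   "CAT": (28.0, 3.0), "POD": (17.0, 2.0)},
    "L100":      {"ALT": (96.84, 9.5),  "AST": (68.37, 7.0),  "MDA": (4.2, 0.45), "SOD": (95, 8),   "CAT": (30.0, 3.0), "POD": (22.0, 2.5)},
    "L200":      {"ALT": (103.27, 10.0), "AST": (70.00, 7.0), "MDA": (4.6, 0.50), "SOD": (86, 8),   "CAT": (29.0, 3.0), "POD": (18.0, 2.0)},
    "L300":      {"ALT": (99.10, 9.5),  "AST": (76.11, 7.5),  "MDA": (5.0, 0.50), "SOD": (80, 7),   "CAT": (28.5, 3.0), "POD": (17.5, 2.0)},
    "H0":        {"ALT": (67.90, 7.0),  "AST": (52.00, 5.5),  "MDA": (3.1, 0.35), "SOD": (96, 8),   "CAT": (36.0, 3.5), "POD": (38.0, 3.5)},
    "H100":      {"ALT": (57.50, 6.0),  "AST": (46.00, 5.0),  "MDA": (2.7, 0.30), "SOD": (118, 9),  "CAT": (38.0, 3.5), "POD": (36.0, 3.5)},
    "H200":      {"ALT": (62.70, 6.5),  "AST": (49.50, 5.0),  "MDA": (2.9, 0.30), "SOD": (110, 9),  "CAT": (37.0, 3.5), "POD": (33.0, 3.0)},
    "H300":      {"ALT": (65.30, 6.5),  "AST": (51.00, 5.5),  "MDA": (3.0, 0.35), "SOD": (104, 8),  "CAT": (36.5, 3.5), "POD": (31.0, 3.0)},
}

#: minimum distance between a decoy peak and any other peak, minutes
DECOY_MIN_SEPARATION = 0.3


@dataclass(frozen=True)
class PeakDef:
    """Definition of one generated peak."""

    peak_id: str
    mode: str
    t_R_min: float
    mz: float
    baseline_area: float
    effects: Mapping[int, float]  # treatment mM -> area multiplier


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic study.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal replicate noise applied to peak areas; ``rt_jitter_min`` is the
    half-width of the uniform retention-time jitter in generated peak lists.
    """

    treatments: tuple[int, ...] = DEFAULT_TREATMENTS
    reps_per_treatment: int = 3
    peak_defs: list[PeakDef] = field(default_factory=lambda: default_peak_defs())
    noise_cv: float = 0.10
    n_decoy_peaks: int = 0  # per ion mode
    rt_jitter_min: float = 0.02
    efficacy_defs: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_EFFICACY.items()}
    )
    animals_per_group: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps_per_treatment < 2:
            raise ConfigurationError("reps_per_treatment must be >= 2")
        if self.animals_per_group < 2:
            raise ConfigurationError("animals_per_group must be >= 2")
        if self.noise_cv < 0 or self.rt_jitter_min < 0 or self.n_decoy_peaks < 0:
            raise ConfigurationError("noise_cv, rt_jitter_min, n_decoy_peaks must be >= 0")
        for pd_ in self.peak_defs:
            if pd_.baseline_area <= 0:
                raise ConfigurationError(f"peak {pd_.peak_id}: baseline area must be > 0")
            for t in self.treatments:
                if t not in pd_.effects:
                    raise ConfigurationError(f"peak {pd_.peak_id}: no effect for treatment {t}")
                if pd_.effects[t] <= 0:
                    raise ConfigurationError(f"peak {pd_.peak_id}: multiplier for {t} mM must be > 0")
        for g, defs in self.efficacy_defs.items():
            for ind, (mu, sd) in defs.items():
                if mu <= 0 or sd < 0:
                    raise ConfigurationError(f"efficacy ({g}, {ind}): mean must be > 0, SD >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return [f"T{t}_R{r}" for t in self.treatments for r in range(1, self.reps_per_treatment + 1)]


def default_peak_defs() -> list[PeakDef]:
    """Peak definitions from the packaged compound library: polyphenol-class
    peaks get the low-salt-maximum effect profile, everything else is flat."""
    lib = annotation.load_library()
    defs = []
    for rec in lib:
        effects = POLYPHENOL_EFFECT if rec.compound_class in POLYPHENOL_CLASSES else FLAT_EFFECT
        defs.append(
            PeakDef(
                peak_id=rec.peak_id,
                mode=rec.mode,
                t_R_min=rec.t_R_min,
                mz=rec.mz_observed,
                baseline_area=BASELINE_BY_CLASS[rec.compound_class],
                effects=dict(effects),
            )
        )
    return defs


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # one independent stream per operation so call order never matters
    return np.random.default_rng([config.seed, stream])


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_fingerprints(config: GeneratorConfig) -> FingerprintMatrix:
    """Sample x peak area matrix for all treatments and replicates.

    Expected area of peak j in treatment t is baseline_j x effect_j(t);
    replicates vary by unit-mean multiplicative lognormal noise with
    CV ``noise_cv`` (exactly the expectation when ``noise_cv`` is 0).
    """
    rng = _rng(config, 1)
    sample_ids, treatments = [], []
    for t in config.treatments:
        for r in range(1, config.reps_per_treatment + 1):
            sample_ids.append(f"T{t}_R{r}")
            treatments.append(t)
    n_s, n_p = len(sample_ids), len(config.peak_defs)
    expected = np.empty((n_s, n_p))
    for j, pdef in enumerate(config.peak_defs):
        expected[:, j] = [pdef.baseline_area * pdef.effects[t] for t in treatments]
    areas = expected * _lognormal_noise(rng, config.noise_cv, (n_s, n_p))

    peak_ids = [p.peak_id for p in config.peak_defs]
    sample_meta = pd.DataFrame(
        {"treatment_mM": treatments,
         "replicate": [int(s.split("_R")[1]) for s in sample_ids]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    peak_meta = pd.DataFrame(
        {"mode": [p.mode for p in config.peak_defs],
         "t_R_min": [p.t_R_min for p in config.peak_defs],
         "mz": [p.mz for p in config.peak_defs]},
        index=pd.Index(peak_ids, name="peak_id"),
    )
    return FingerprintMatrix(
        pd.DataFrame(areas, index=sample_meta.index, columns=peak_ids), sample_meta, peak_meta
    )


def generate_sample_peak_lists(config: GeneratorConfig) -> list[SamplePeakList]:
    """Per-sample peak lists: every common peak (t_R jittered within
    +/- ``rt_jitter_min``) plus ``n_decoy_peaks`` decoys per ion mode.

    Each decoy sits at least 0.3 min from every common peak (and every other
    decoy) inside the gradient window and is absent from at least one sample
    by construction, so an all-samples intersection always removes it.
    """
    matrix = generate_fingerprints(config)
    rng = _rng(config, 2)
    lo, hi = GRADIENT_WINDOW_MIN
    modes = sorted({p.mode for p in config.peak_defs})

    # place decoys per mode, rejection-sampling positions inside the gradient
    decoys: list[tuple[str, float, float]] = []  # (mode, t_R, mz)
    for mode in modes:
        taken = [p.t_R_min for p in config.peak_defs if p.mode == mode]
        for d in range(config.n_decoy_peaks):
            for _ in range(1000):
                cand = rng.uniform(lo, hi)
                if all(abs(cand - t) >= DECOY_MIN_SEPARATION for t in taken):
                    taken.append(cand)
                    decoys.append((mode, cand, rng.uniform(100, 1000)))
                    break
            else:
                raise ConfigurationError(
                    f"cannot place decoy {d + 1} in mode {mode}: gradient window too crowded"
                )

    n_samples = len(matrix.sample_ids)
    # each decoy appears in a random proper subset of samples (>=1 absent)
    decoy_presence = []
    for _ in decoys:
        k = int(rng.integers(1, n_samples))  # 1 .. n_samples-1 samples
        present = set(rng.choice(n_samples, size=k, replace=False).tolist())
        decoy_presence.append(present)

    lists = []
    for i, sid in enumerate(matrix.sample_ids):
        rows = []
        for pdef in config.peak_defs:
            jitter = rng.uniform(-config.rt_jitter_min, config.rt_jitter_min) if config.rt_jitter_min else 0.0
            rows.append(
                {"t_R_min": np.clip(pdef.t_R_min + jitter, lo, hi), "mz": pdef.mz,
                 "area": matrix.areas.at[sid, pdef.peak_id], "mode": pdef.mode}
            )
        for (mode, t_r, mz), present in zip(decoys, decoy_presence):
            if i in present:
                rows.append({"t_R_min": t_r, "mz": mz, "area": float(rng.uniform(20, 200)), "mode": mode})
        lists.append(SamplePeakList(sid, pd.DataFrame(rows)))
    return lists


def generate_efficacy(config: GeneratorConfig) -> EfficacyTable:
    """Per-animal endpoint table: ``animals_per_group`` draws per (group,
    indicator) cell from a normal truncated at zero."""
    rng = _rng(config, 3)
    missing = [
        (g, ind)
        for g in GROUPS
        if g in config.efficacy_defs or True
        for ind in INDICATORS
        if g not in config.efficacy_defs or ind not in config.efficacy_defs[g]
    ]
    if missing:
        raise ConfigurationError(f"efficacy_defs missing cells, e.g. {missing[0]}")
    rows = []
    for g in GROUPS:
        for ind in INDICATORS:
            mu, sd = config.efficacy_defs[g][ind]
            vals = rng.normal(mu, sd, size=config.animals_per_group)
            while (vals < 0).any():  # truncate at 0 by resampling
                bad = vals < 0
                vals[bad] = rng.normal(mu, sd, size=int(bad.sum()))
            for a, v in enumerate(vals, start=1):
                rows.append(
                    {"group": g, "animal_id": f"{g}-{a}", "indicator": ind,
                     "value": float(v), "unit": UNITS[ind]}
                )
    return EfficacyTable(pd.DataFrame(rows))


def plant_correlated_peak(
    matrix: FingerprintMatrix,
    indicator_values: Sequence[float],
    r_target: float,
    seed: int = 0,
    peak_id: str | None = None,
    mode: str = "positive",
) -> FingerprintMatrix:
    """Append a peak whose areas track an indicator at a target correlation.

    The planted areas are proportional to ``indicator_values`` plus Gaussian
    noise calibrated so the population Pearson correlation equals
    ``r_target``; at ``r_target = 1`` the peak is an exact proportional copy
    (so after mean normalization it coincides with the indicator sequence,
    which grey relational analysis rewards with grade 1). Rare negative draws
    are clipped to zero.
    """
    if not 0 < r_target <= 1:
        raise ConfigurationError("r_target must be in (0, 1]")
    y = np.asarray(indicator_values, dtype=float)
    if len(y) != len(matrix.sample_ids):
        raise ConfigurationError("indicator_values length must equal the number of samples")
    rng = np.random.default_rng([seed, 4])
    if r_target == 1:
        signal = y.copy()
    else:
        sigma_e = np.std(y, ddof=0) * np.sqrt(1 / r_target**2 - 1)
        signal = y + rng.normal(0, sigma_e, size=len(y))
    scale = 100.0 / np.mean(y) if np.mean(y) > 0 else 1.0
    areas = np.clip(signal * scale, 0, None)

    pid = peak_id or ("P_planted" if mode == "positive" else "N_planted")
    out = matrix.copy()
    out.areas[pid] = areas
    out.peak_meta.loc[pid] = {"mode": mode, "t_R_min": 21.5, "mz": 500.0}
    return FingerprintMatrix(out.areas, out.sample_meta, out.peak_meta)


# ---------------------------------------------------------------------------
# Config I/O

def config_to_yaml(config: GeneratorConfig, path) -> None:
    doc = asdict(config)
    doc["treatments"] = list(config.treatments)
    doc["peak_defs"] = [
        {**asdict(p), "effects": {int(k): float(v) for k, v in p.effects.items()}}
        for p in config.peak_defs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    doc["treatments"] = tuple(doc["treatments"])
    doc["peak_defs"] = [PeakDef(**{**p, "effects": {int(k): v for k, v in p["effects"].items()}}) for p in doc["peak_defs"]]
    doc["efficacy_defs"] = {
        g: {ind: tuple(ms) for ind, ms in defs.items()} for g, defs in doc["efficacy_defs"].items()
    }
    return GeneratorConfig(**doc)
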