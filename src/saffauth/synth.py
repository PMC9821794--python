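"""Synthetic ATR-FTIR saffron spectra.

Emulates the sampling design of a saffron-authentication study: five batches
of fresh (compliant) stigmas, mixtures of fresh and expired stigmas from two
aging vintages at 10/25/40 % (w/w), and pure expired stigmas (100 %), each
measured in replicate.  Spectra are sums of Gaussian absorption bands on the
instrument grid (4000-500 cm^-1, 4 cm^-1 step, pseudo-absorbance scale), with
batch-level band jitter, a multiplicative scatter factor, a linear baseline
and additive detector noise superimposed.

Aging of the expired stigmas is encoded as per-band intensity multipliers:
hydrolysis of crocin/picrocrocin glycosidic and ester bonds depresses the
sugar/ester bands (1051, 1020, 1578 cm^-1, ...) while free aldehydes and
carboxylic acids raise the carbonyl shoulders (1710-1745 cm^-1); moisture loss
lowers the broad O-H band.  The 2018 vintage ages less (expired one year, not
three) and additionally carries a vintage direction of its own (richer
trans-crocin / O-H profile, slightly weaker fingerprint), so that vintage and
aging are distinct spectral axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "Band",
    "DesignGroup",
    "GeneratorConfig",
    "Dataset",
    "default_axis",
    "validate_axis",
    "default_bands",
    "default_design",
    "default_config",
    "pure_profile",
    "mixture_profile",
    "generate_dataset",
    "write_dataset",
]

#: Recognized endpoint conditions of the mixture design.
CONDITIONS = ("fresh", "aged2016", "aged2018")

WN_START = 4000.0
WN_END = 500.0
WN_STEP = 4.0


def default_axis() -> np.ndarray:
    """Instrument wavenumber grid: 4000 -> 500 cm^-1, 4 cm^-1 step (876 points)."""
    return np.arange(WN_START, WN_END - 1e-9, -WN_STEP)


def validate_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("wavenumber axis must be a 1-D array with >= 2 points")
    steps = np.diff(axis)
    if not np.all(steps < 0):
        raise ValueError("wavenumber axis must be strictly decreasing")
    if not np.allclose(steps, steps[0]):
        raise ValueError("wavenumber axis must be an arithmetic grid")
    return axis


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    ``class_multipliers`` scales ``base_amplitude`` per endpoint condition;
    a condition missing from the map defaults to 1.
    """

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    base_amplitude: float  # pseudo-absorbance units
    class_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.base_amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if any(m <= 0 for m in self.class_multipliers.values()):
            raise ValueError("class multipliers must be > 0")

    def amplitude(self, condition: str) -> float:
        return self.base_amplitude * self.class_multipliers.get(condition, 1.0)


@dataclass(frozen=True)
class DesignGroup:
    """One cell of the sampling design: a class/level/vintage with its batches."""

    label: str  # Compliant | Adulterated2016 | Adulterated2018
    alpha: float  # adulterant mass fraction in [0, 1]
    vintage: int  # production year of the adulterant (2020 for compliant)
    batch_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if (self.label == "Compliant") != (self.alpha == 0.0):
            raise ValueError("label Compliant <=> alpha == 0")
        if any(n < 0 for n in self.batch_sizes):
            raise ValueError("batch sizes must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(sum(self.batch_sizes))


@dataclass(frozen=True)
class GeneratorConfig:
    """Bands, design table and artifact magnitudes of the generator."""

    bands: tuple[Band, ...]
    design: tuple[DesignGroup, ...]
    noise_sd: float = 0.005  # additive white noise, absorbance units
    baseline_offset_range: tuple[float, float] = (0.0, 0.05)
    baseline_slope_range: tuple[float, float] = (-2e-5, 2e-5)  # per cm^-1
    scatter_sd: float = 0.05  # multiplicative, ~N(1, sd)
    batch_jitter_sd: float = 0.02  # per-band multiplicative, ~N(1, sd)
    seed: int = 2020

    def __post_init__(self) -> None:
        for name in ("noise_sd", "scatter_sd", "batch_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class Dataset:
    X: np.ndarray  # n x p pseudo-absorbance
    meta: pd.DataFrame  # sample_id, label, alpha, vintage, batch
    axis: np.ndarray  # shared wavenumber axis


# ---------------------------------------------------------------------------
# Default band set
#
# Centers follow the assigned saffron bands (O-H / C-H stretches, carbonyl
# shoulders, conjugated C=C, ester/aromatic region, glycosidic/sugar
# fingerprint, trans/cis =C-H bending).  The direction of the aging changes
# is dictated by the chemistry (sugar/ester/crocin bands down, free carbonyls
# up, O-H down on moisture loss); the magnitudes encode the heavy degradation
# of a spice five years past harvest -- apocarotenoid glycosides largely
# hydrolyzed -- and amplitudes are scaled so the fixed detector-noise floor
# corresponds to a realistic relative noise level.  See docs/methods.md.
# ---------------------------------------------------------------------------

# (center, sigma, base_amplitude, aged-2016 multiplier)
_BAND_TABLE: tuple[tuple[float, float, float, float], ...] = (
    (3500.0, 90.0, 0.48, 0.80),   # broad O-H shoulder
    (3300.0, 140.0, 1.44, 0.78),  # bonded/free O-H stretch (moisture)
    (2924.0, 14.0, 0.56, 0.85),   # C-H asym stretch
    (2854.0, 12.0, 0.36, 0.85),   # C-H sym stretch
    (1745.0, 12.0, 0.40, 2.00),   # C=O esters / free acids (up on aging)
    (1710.0, 14.0, 0.44, 2.20),   # C=O aldehydes (up on aging)
    (1650.0, 18.0, 1.04, 0.70),   # conjugated C=C / amide I
    (1613.0, 12.0, 0.80, 0.75),   # skeletal C-C
    (1578.0, 9.0, 0.48, 0.30),    # conjugated ester C-O (down on aging)
    (1545.0, 10.0, 0.40, 0.55),   # amide II / aromatic C=C
    (1221.0, 14.0, 0.56, 0.50),   # (C=O)-O of crocetin esters
    (1157.0, 12.0, 0.64, 0.60),   # C-O stretch
    (1051.0, 14.0, 1.00, 0.25),   # C-O-C glycosidic (crocins; down strongly)
    (1020.0, 11.0, 0.60, 0.45),   # sugar bending
    (980.0, 10.0, 0.56, 0.65),    # trans =C-H bending (trans-crocins)
    (930.0, 12.0, 0.40, 0.60),    # glycosidic skeletal
    (880.0, 10.0, 0.32, 0.75),    # C=C bending
    (740.0, 12.0, 0.28, 0.55),    # cis =C-H bending (cis-crocins)
)

#: The 2018 stigmas are three years old at analysis against five for 2016.
#: Degradation is fast early and slows down (biphasic, crocin-like kinetics),
#: so each 2018 multiplier is the corresponding 2016 one raised to this power.
AGING_EXPONENT_2018 = 0.75

#: Vintage direction of the 2018 harvest, on top of its aging: stronger
#: O-H / C-H / trans =C-H bands, slightly weaker fingerprint.
_VINTAGE_2018: Mapping[float, float] = {
    3500.0: 1.35,
    3300.0: 1.18,
    2924.0: 1.20,
    2854.0: 1.20,
    980.0: 1.35,
}
_FINGERPRINT_2018_FACTOR = 0.88
_FINGERPRINT_BANDS = (1650.0, 1613.0, 1578.0, 1545.0, 1221.0, 1157.0, 1051.0, 1020.0)


def default_bands() -> tuple[Band, ...]:
    bands = []
    for center, width, amp, m2016 in _BAND_TABLE:
        m2018 = m2016**AGING_EXPONENT_2018
        m2018 *= _VINTAGE_2018.get(center, 1.0)
        if center in _FINGERPRINT_BANDS:
            m2018 *= _FINGERPRINT_2018_FACTOR
        bands.append(
            Band(
                center=center,
                width=width,
                base_amplitude=amp,
                class_multipliers={"fresh": 1.0, "aged2016": m2016, "aged2018": m2018},
            )
        )
    return tuple(bands)


def default_design() -> tuple[DesignGroup, ...]:
    """Study design: 112 compliant + 112 adulterated-2016 + 110 adulterated-2018.

    Compliant saffron comes in five batches (~22 replicate analyses each);
    adulterated material in batches of ~10 replicates, three batches per
    level, two batches of pure expired stigmas per vintage.
    """
    groups = [DesignGroup("Compliant", 0.0, 2020, (22, 22, 22, 23, 23))]
    for vintage, tens in ((2016, {1.0: (10, 10), 0.40: (10, 10, 10), 0.25: (10, 10, 10), 0.10: (11, 11, 10)}),
                          (2018, {1.0: (10, 10), 0.40: (10, 10, 10), 0.25: (10, 10, 10), 0.10: (10, 10, 10)})):
        for alpha, sizes in tens.items():
            groups.append(DesignGroup(f"Adulterated{vintage}", alpha, vintage, sizes))
    return tuple(groups)


def default_config(seed: int = 2020) -> GeneratorConfig:
    return GeneratorConfig(bands=default_bands(), design=default_design(), seed=seed)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _profile_from_amplitudes(
    amplitudes: np.ndarray, bands: Sequence[Band], axis: np.ndarray
) -> np.ndarray:
    out = np.zeros_like(axis, dtype=float)
    for amp, band in zip(amplitudes, bands):
        out += amp * np.exp(-((axis - band.center) ** 2) / (2.0 * band.width**2))
    return out


def pure_profile(
    condition: str, axis: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    """Noise-free spectrum of one endpoint condition (sum of Gaussian bands)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    axis = validate_axis(axis)
    amps = np.array([b.amplitude(condition) for b in config.bands])
    return _profile_from_amplitudes(amps, config.bands, axis)


def mixture_profile(
    alpha: float, vintage: int, axis: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    """Noise-free blend: (1-alpha) fresh + alpha aged, linear in mass fraction."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    aged = {2016: "aged2016", 2018: "aged2018"}.get(int(vintage))
    if aged is None:
        raise ValueError("vintage must be 2016 or 2018")
    fresh = pure_profile("fresh", axis, config)
    return (1.0 - alpha) * fresh + alpha * pure_profile(aged, axis, config)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(
    config: GeneratorConfig, axis: np.ndarray | None = None
) -> Dataset:
    """Draw the full replicate dataset defined by ``config.design``.

    Each batch receives one multiplicative per-band jitter shared by its
    replicates; each replicate spectrum is then
    ``profile * scatter + offset + slope * (nu - nu_min) + noise``.
    Rows are ordered by design group then batch; fully reproducible from
    ``config.seed``.
    """
    axis = validate_axis(default_axis() if axis is None else axis)
    rng = np.random.default_rng(config.seed)
    p = axis.size
    base = np.array([b.base_amplitude for b in config.bands])
    mult = {
        c: np.array([b.class_multipliers.get(c, 1.0) for b in config.bands])
        for c in CONDITIONS
    }
    aged_key = {2016: "aged2016", 2018: "aged2018"}
    lo_off, hi_off = config.baseline_offset_range
    lo_sl, hi_sl = config.baseline_slope_range
    ramp = axis - axis.min()

    rows: list[np.ndarray] = []
    meta: list[dict] = []
    sample_no = 0
    for group in config.design:
        for b_idx, n_rep in enumerate(group.batch_sizes, start=1):
            batch_id = f"{group.label}-a{round(group.alpha * 100):03d}-b{b_idx}"
            jitter = rng.normal(1.0, config.batch_jitter_sd, size=base.size)
            fresh_amp = base * mult["fresh"] * jitter
            profile = _profile_from_amplitudes(fresh_amp, config.bands, axis)
            if group.alpha > 0.0:
                aged_amp = base * mult[aged_key[group.vintage]] * jitter
                aged_prof = _profile_from_amplitudes(aged_amp, config.bands, axis)
                profile = (1.0 - group.alpha) * profile + group.alpha * aged_prof
            for _ in range(n_rep):
                scatter = rng.normal(1.0, config.scatter_sd)
                offset = rng.uniform(lo_off, hi_off)
                slope = rng.uniform(lo_sl, hi_sl)
                noise = rng.normal(0.0, config.noise_sd, size=p)
                rows.append(profile * scatter + offset + slope * ramp + noise)
                sample_no += 1
                meta.append(
                    {
                        "sample_id": f"S{sample_no:04d}",
                        "label": group.label,
                        "alpha": group.alpha,
                        "vintage": group.vintage,
                        "batch": batch_id,
                    }
                )
    X = np.vstack(rows) if rows else np.empty((0, p))
    return Dataset(X=X, meta=pd.DataFrame(meta), axis=axis)


def write_dataset(dataset: Dataset, spectra_csv, metadata_csv) -> None:
    """Write spectra (sample_id + one column per wavenumber) and metadata CSVs."""
    cols = [f"{w:g}" for w in dataset.axis]
    df = pd.DataFrame(dataset.X, columns=cols)
    df.insert(0, "sample_id", dataset.meta["sample_id"].to_numpy())
    df.to_csv(spectra_csv, index=False)
    dataset.meta.to_csv(metadata_csv, index=False)
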