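"""Synthetic FT-MIR-like absorbance spectra with known class structure.

The generator produces cohorts that emulate the mid-IR fingerprint of the
blood low-molecular-weight fraction for three classes:

* **FM** (fibromyalgia): four amide-region bands at 1565, 1588, 1639 and
  1670 cm^-1 (the 1565 cm^-1 glutamate carboxylate band is unique to FM),
* **LC** (Long COVID): three bands at 1581, 1635 and 1670 cm^-1,
* **HC** (healthy controls): a small 1545 cm^-1 band absent from both
  patient groups, plus 1580/1639/1670.

Each spectrum is a sum of FWHM-parameterized Gaussian bands,

    g(x) = h * exp(-4 ln2 (x - c)^2 / w^2),    area = h * w * sqrt(pi / (4 ln2)),

where ``w`` is the full width at half maximum in cm^-1, on top of broad
background bands (lipid ester ~1740, O-H/C-H stretches, phosphodiester and
C-O bands), a per-sample global amplitude factor, a linear baseline drift,
additive white noise, and a class-unrelated structured "nuisance" direction
(a broad 1740 cm^-1 loading scaled by a random per-sample score) that an
orthogonal signal correction filter can learn to remove.

Per-sample biological variability enters through the *relative areas* of the
fingerprint bands; band centers are treated as molecular constants (the
center scatter reported for fitted bands is attributed to estimation noise,
which the downstream deconvolution reproduces on its own).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, GridError
from .io import Spectrum, SpectralDataset

_FOUR_LN2 = 4.0 * np.log(2.0)
#: area of a unit-height, unit-FWHM Gaussian
GAUSS_AREA_FACTOR = float(np.sqrt(np.pi / _FOUR_LN2))


def gaussian(x: np.ndarray, height: float, center: float, fwhm: float) -> np.ndarray:
    """FWHM-parameterized Gaussian profile h*exp(-4 ln2 (x-c)^2 / w^2)."""
    return height * np.exp(-_FOUR_LN2 * (np.asarray(x, float) - center) ** 2 / fwhm**2)


def gaussian_area(height: float, fwhm: float) -> float:
    """Analytic area of the FWHM Gaussian: h * w * sqrt(pi/(4 ln2))."""
    return height * fwhm * GAUSS_AREA_FACTOR


def height_for_area(area: float, fwhm: float) -> float:
    """Peak height giving the requested analytic area at the given FWHM."""
    return area / (fwhm * GAUSS_AREA_FACTOR)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band: center and FWHM in cm^-1, relative area share.

    ``rel_area`` is the band's fraction of the summed area of its band list.
    ``rel_area_sd`` is the per-sample standard deviation of that share
    (biological variation); ``center_sd`` allows optional per-sample center
    wobble and defaults to 0.
    """

    center: float
    fwhm: float
    rel_area: float
    center_sd: float = 0.0
    rel_area_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ConfigError(f"band at {self.center}: fwhm must be > 0")
        if self.rel_area < 0 or self.center_sd < 0 or self.rel_area_sd < 0:
            raise ConfigError(f"band at {self.center}: dispersion/area parameters must be >= 0")


@dataclass(frozen=True)
class NuisanceSpec:
    """Class-unrelated structured variance: unit-norm Gaussian loading at
    ``center``/``fwhm`` multiplied by a per-sample N(0, score_sd) score."""

    center: float = 1740.0
    fwhm: float = 100.0
    score_sd: float = 0.5

    def loading(self, grid: np.ndarray) -> np.ndarray:
        v = gaussian(grid, 1.0, self.center, self.fwhm)
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else v


@dataclass(frozen=True)
class ClassProfile:
    """Forward model of one class: fingerprint bands, background, dispersions."""

    name: str
    bands: tuple[BandSpec, ...]
    background_bands: tuple[BandSpec, ...] = ()
    amplitude_cv: float = 0.1
    baseline_slope_sd: float = 1e-4
    noise_sd: float = 0.002
    nuisance: NuisanceSpec | None = field(default_factory=NuisanceSpec)
    fingerprint_area: float = 10.0  # absorbance * cm^-1 integrated over the band list
    background_area: float = 100.0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigError(f"profile {self.name!r}: band list must be non-empty")
        for val, nm in [
            (self.amplitude_cv, "amplitude_cv"),
            (self.baseline_slope_sd, "baseline_slope_sd"),
            (self.noise_sd, "noise_sd"),
        ]:
            if val < 0:
                raise ConfigError(f"profile {self.name!r}: {nm} must be >= 0")

    def noise_free(self) -> "ClassProfile":
        """Copy with every stochastic term switched off (deterministic render)."""
        return replace(
            self,
            amplitude_cv=0.0,
            baseline_slope_sd=0.0,
            noise_sd=0.0,
            nuisance=None,
            bands=tuple(replace(b, center_sd=0.0, rel_area_sd=0.0) for b in self.bands),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Wavenumber grid and cohort size.

    The default grid covers 1800-1400 cm^-1 at 2 cm^-1 spacing: fine enough
    for the 5/7-point Savitzky-Golay windows to act locally while keeping the
    full amide/fingerprint region of interest plus margin.
    """

    grid_min: float = 1400.0
    grid_max: float = 1800.0
    grid_step: float = 2.0
    n_per_class: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_min >= self.grid_max:
            raise ConfigError("grid_min must be < grid_max")
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be > 0")
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")

    def grid(self) -> np.ndarray:
        """Descending wavenumber grid."""
        n = int(np.floor((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_max - self.grid_step * np.arange(n)


def _normalized(bands: list[tuple], name: str) -> tuple[BandSpec, ...]:
    tot = sum(b[2] for b in bands)
    return tuple(
        BandSpec(center=c, fwhm=w, rel_area=a / tot, center_sd=csd, rel_area_sd=asd)
        for (c, w, a, csd, asd) in bands
    )


#: broad background features of a representative blood-LMF spectrum
#: (O-H stretch, C-H stretches, lipid ester C=O, methyl bending,
#: phosphodiester, C-O); shares of the total background area
_BACKGROUND = tuple(
    BandSpec(center=c, fwhm=w, rel_area=a)
    for c, w, a in [
        (3400.0, 300.0, 0.50),
        (2920.0, 60.0, 0.08),
        (1740.0, 120.0, 0.12),
        (1400.0, 100.0, 0.10),
        (1245.0, 80.0, 0.06),
        (1088.0, 70.0, 0.08),
        (1000.0, 60.0, 0.06),
    ]
)


def default_class_profiles() -> dict[str, ClassProfile]:
    """Reference profiles for FM, LC and HC.

    Fingerprint centers and mean relative areas follow the deconvolution
    consensus for each group (FM: 1565/36.1%, 1588/38.2%, 1639/4.7%,
    1670/21.3%; LC: 1581/70.3%, 1635/9.9%, 1670/23.9%; HC: 1545/4.1% with the
    remainder split 70/10/20 across 1580/1639/1670, mirroring the LC
    pattern).  Relative areas are renormalized to sum to exactly 1 per class.
    Per-sample area shares are drawn with the reported group standard
    deviations; centers are fixed (see module docstring).
    """
    fwhm = 25.0
    fm = [
        (1565.0, fwhm, 0.361, 0.0, 0.181),
        (1588.0, fwhm, 0.382, 0.0, 0.156),
        (1639.0, fwhm, 0.047, 0.0, 0.016),
        (1670.0, fwhm, 0.213, 0.0, 0.075),
    ]
    lc = [
        (1581.0, fwhm, 0.703, 0.0, 0.089),
        (1635.0, fwhm, 0.099, 0.0, 0.092),
        (1670.0, fwhm, 0.239, 0.0, 0.053),
    ]
    rest = 1.0 - 0.041
    hc = [
        (1545.0, fwhm, 0.041, 0.0, 0.020),
        (1580.0, fwhm, rest * 0.7, 0.0, 0.089),
        (1639.0, fwhm, rest * 0.1, 0.0, 0.092),
        (1670.0, fwhm, rest * 0.2, 0.0, 0.053),
    ]
    return {
        name: ClassProfile(name=name, bands=_normalized(b, name), background_bands=_BACKGROUND)
        for name, b in [("FM", fm), ("LC", lc), ("HC", hc)]
    }


def render_spectrum(
    profile: ClassProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "s0",
) -> tuple[Spectrum, pd.DataFrame]:
    """Draw one spectrum from a class profile.

    Returns the spectrum together with a truth table of the realized
    fingerprint band parameters (center, fwhm, area before global scaling)
    for parameter-recovery tests.  Fingerprint bands must lie on the grid;
    background bands outside the grid contribute their tails only.
    """
    grid = config.grid()
    lo, hi = grid.min(), grid.max()
    for b in profile.bands:
        if not (lo <= b.center <= hi):
            raise GridError(
                f"fingerprint band at {b.center} cm^-1 lies outside the "
                f"simulation grid [{lo}, {hi}]; extend the grid or drop the band"
            )

    # realized per-sample band parameters
    centers = np.array([rng.normal(b.center, b.center_sd) if b.center_sd > 0 else b.center
                        for b in profile.bands])
    shares = np.array([rng.normal(b.rel_area, b.rel_area_sd) if b.rel_area_sd > 0 else b.rel_area
                       for b in profile.bands])
    shares = np.clip(shares, 0.005, None)
    shares = shares / shares.sum()

    absorbance = np.zeros_like(grid)
    rows = []
    for b, c, s in zip(profile.bands, centers, shares):
        area = profile.fingerprint_area * s
        absorbance += gaussian(grid, height_for_area(area, b.fwhm), c, b.fwhm)
        rows.append({"sample_id": sample_id, "center": c, "fwhm": b.fwhm,
                     "area": area, "rel_area": s})
    for b in profile.background_bands:
        absorbance += gaussian(
            grid, height_for_area(profile.background_area * b.rel_area, b.fwhm), b.center, b.fwhm
        )

    scale = 1.0
    if profile.amplitude_cv > 0:
        scale = max(rng.normal(1.0, profile.amplitude_cv), 0.1)
    absorbance = scale * absorbance
    if profile.baseline_slope_sd > 0:
        absorbance = absorbance + rng.normal(0.0, profile.baseline_slope_sd) * (grid - grid.mean())
    if profile.nuisance is not None and profile.nuisance.score_sd > 0:
        absorbance = absorbance + rng.normal(0.0, profile.nuisance.score_sd) * profile.nuisance.loading(grid)
    if profile.noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, profile.noise_sd, grid.shape)

    return Spectrum(grid, absorbance, sample_id), pd.DataFrame(rows)


def simulate_cohort(
    profiles: dict[str, ClassProfile] | list[ClassProfile],
    config: SimulationConfig,
) -> SpectralDataset:
    """Simulate ``n_per_class`` spectra per profile; deterministic for a seed.

    Per-sample RNG substreams are spawned from the master seed by counter, so
    the output is bit-identical for a fixed :class:`SimulationConfig` and the
    draw for sample *k* does not depend on how many samples precede it in
    other classes.  The dataset carries a ``truth`` table (one row per
    realized fingerprint band) for recovery tests.
    """
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    spectra: list[Spectrum] = []
    labels: list[str] = []
    truths = []
    counter = 0
    for prof in profiles:
        for i in range(config.n_per_class):
            rng = np.random.default_rng([config.seed, counter])
            sid = f"{prof.name}_{i:03d}"
            sp, truth = render_spectrum(prof, config, rng, sample_id=sid)
            truth.insert(1, "label", prof.name)
            spectra.append(sp)
            labels.append(prof.name)
            truths.append(truth)
            counter += 1
    ds = SpectralDataset.from_spectra(spectra, labels)
    ds.truth = pd.concat(truths, ignore_index=True)
    return ds
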