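"""Synthetic multi-point transmission scans with known ground truth.

No public dataset exists with the acquisition characteristics this
pipeline targets (per-fruit multi-point transmission scans over a 2047
channel visible/NIR grid), so this module generates them: a smooth lamp
envelope attenuated by Beer-Lambert absorption from the analyte (soluble
solids, in °Brix) and from interfering compounds, modulated by per-point
multiplicative scatter, end-point truncation, detector saturation and
additive noise. The informative absorption bands are retained as ground
truth so selection algorithms can be tested for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .scanproc import BackgroundSpectrum, MultiPointScan, Spectrum, WavelengthGrid

ORIENTATIONS = ("O1", "O2")


@dataclass(frozen=True)
class VarietyProfile:
    """Sampling profile for one fruit variety."""

    name: str
    ssc_min: float
    ssc_max: float
    ssc_mean: float
    ssc_sd: float
    n_samples: int
    points_min: int = 17
    points_max: int = 31

    def __post_init__(self):
        if not (self.ssc_min < self.ssc_mean < self.ssc_max):
            raise ValueError("require ssc_min < ssc_mean < ssc_max")
        if self.ssc_sd <= 0:
            raise ValueError("ssc_sd must be positive")
        if not (1 <= self.points_min <= self.points_max):
            raise ValueError("require 1 <= points_min <= points_max")


#: The two variety profiles used throughout the tests (range, mean, SD and
#: sample count of the reference °Brix distributions, plus the observed
#: per-fruit acquisition-point counts).
PROVENCE = VarietyProfile("Provence", 3.8, 8.7, 5.8, 1.1, 92, 17, 31)
JINGCAI = VarietyProfile("JingcaiNo8", 4.5, 9.8, 7.4, 1.2, 96, 20, 29)


@dataclass(frozen=True)
class Band:
    """Gaussian absorption band: center (nm), width (nm), peak absorptivity."""

    center: float
    width: float
    absorptivity: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Forward-model parameters for scan generation."""

    seed: int = 0
    grid: WavelengthGrid = field(default_factory=WavelengthGrid.default)
    source_peak: float = 30000.0
    source_center: float = 820.0
    source_width: float = 190.0
    source_floor: float = 500.0
    ssc_bands: tuple[Band, ...] = (
        Band(730.0, 18.0, 0.055),
        Band(840.0, 25.0, 0.045),
        Band(960.0, 30.0, 0.06),
    )
    interferent_bands: tuple[Band, ...] = (
        Band(620.0, 45.0, 0.25),
        Band(905.0, 55.0, 0.18),
    )
    interferent_conc_range: tuple[float, float] = (0.5, 1.5)
    # per-sample multiplicative jitter on each analyte band's absorptivity
    # (matrix effects); makes every band carry partly independent signal
    band_jitter_sd: float = 0.05
    # whole-fruit multiplicative scatter (size/skin effects); per-point
    # scatter averages out in aggregation, this does not -- SNV removes it
    sample_gain_range: tuple[float, float] = (1.0, 1.0)
    # wavelength-dependent multiplicative scatter: per-sample smooth random
    # log-gain field (fractional amplitude); 0 disables
    smooth_scatter_amp: float = 0.0
    path_factor_o1: float = 1.0
    path_factor_o2: float = 0.75
    scatter_gain_range: tuple[float, float] = (0.85, 1.15)
    end_attenuation: float = 0.3
    saturation_level: float = 65535.0
    saturation_prob: float = 0.05
    noise_sd: float = 60.0
    background_stray_level: float = 50.0
    background_noise_sd: float = 20.0

    def __post_init__(self):
        if not self.path_factor_o2 < self.path_factor_o1:
            raise ValueError("path_factor_o2 must be < path_factor_o1")
        if not 0 < self.end_attenuation < 1:
            raise ValueError("end_attenuation must lie in (0, 1)")
        lo, hi = self.scatter_gain_range
        if not lo <= 1 <= hi:
            raise ValueError("scatter_gain_range must bracket 1")
        lo, hi = self.sample_gain_range
        if not 0 < lo <= 1 <= hi:
            raise ValueError("sample_gain_range must bracket 1 and be positive")
        if self.saturation_level <= 0:
            raise ValueError("saturation_level must be positive")
        if self.noise_sd < 0 or self.background_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def path_factor(self, orientation: str) -> float:
        if orientation == "O1":
            return self.path_factor_o1
        if orientation == "O2":
            return self.path_factor_o2
        raise ValueError(f"unknown orientation {orientation!r}")

    def source_curve(self) -> np.ndarray:
        lam = self.grid.values
        return self.source_floor + self.source_peak * np.exp(
            -(((lam - self.source_center) / self.source_width) ** 2)
        )

    def _band_profile(self, bands: Sequence[Band]) -> np.ndarray:
        """Stacked per-band Gaussian absorptivity profiles (n_bands x P)."""
        lam = self.grid.values
        return np.array(
            [b.absorptivity * np.exp(-0.5 * ((lam - b.center) / b.width) ** 2) for b in bands]
        )

    def ssc_absorptivity(self) -> np.ndarray:
        return self._band_profile(self.ssc_bands).sum(axis=0)

    def interferent_absorptivity(self) -> np.ndarray:
        return self._band_profile(self.interferent_bands)


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    ssc: np.ndarray
    band_centers: tuple[float, ...]
    band_widths: tuple[float, ...]
    interferent_conc: np.ndarray  # n_samples x n_interferents

    def band_windows(self, k: float = 1.5) -> list[tuple[float, float]]:
        """Informative wavelength intervals (center +/- k * width).

        The default k=1.5 marks the region where a Gaussian band retains
        >= 32%% of its peak absorptivity.
        """
        return [(c - k * w, c + k * w) for c, w in zip(self.band_centers, self.band_widths)]


def benchmark_config(orientation: str, seed: int = 7) -> SimulationConfig:
    """Fixture recipe for qualitative model-comparison studies.

    Strong, nearly single-channel analyte bands buried in heavy channel
    noise, whole-fruit multiplicative scatter and a smooth scatter field.
    The O1 variant carries more noise than O2 (longer optical path, more
    tissue traversed), so models on O2 data should evaluate better; the
    scatter makes SNV pay off against RAW; the sparse signal makes
    selected-wavelength models beat full-spectrum ones.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    return SimulationConfig(
        seed=seed,
        ssc_bands=(Band(730.0, 1.0, 1.25), Band(840.0, 1.2, 1.0), Band(960.0, 1.0, 1.5)),
        band_jitter_sd=0.02,
        sample_gain_range=(0.6, 1.4),
        smooth_scatter_amp=0.03,
        noise_sd=3000.0 if orientation == "O2" else 4500.0,
    )


def generate_ssc_values(profile: VarietyProfile, seed: int) -> np.ndarray:
    """Truncated-normal °Brix draw matching the profile's moments and range."""
    rng = np.random.default_rng(seed)
    a = (profile.ssc_min - profile.ssc_mean) / profile.ssc_sd
    b = (profile.ssc_max - profile.ssc_mean) / profile.ssc_sd
    dist = stats.truncnorm(a, b, loc=profile.ssc_mean, scale=profile.ssc_sd)
    return dist.rvs(size=profile.n_samples, random_state=rng)


def generate_background(config: SimulationConfig, seed: int | None = None) -> BackgroundSpectrum:
    """Stray-light floor plus zero-mean channel noise."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = len(config.grid)
    noise = rng.normal(0.0, config.background_noise_sd, p) if config.background_noise_sd > 0 else np.zeros(p)
    intensity = np.maximum(config.background_stray_level + noise, 0.0)
    return BackgroundSpectrum(intensity=intensity, noise_sd=config.background_noise_sd)


def _transmitted(ssc: float, interferent_conc: np.ndarray, orientation: str,
                 config: SimulationConfig, band_jitter: np.ndarray | None = None
                 ) -> np.ndarray:
    """Noise-free transmitted intensity for one fruit (Beer-Lambert)."""
    profiles = config._band_profile(config.ssc_bands)
    factors = np.ones(len(config.ssc_bands))
    if band_jitter is not None:
        factors = factors + np.asarray(band_jitter, dtype=float)
    absorbance = ssc * (factors @ profiles)
    if len(config.interferent_bands):
        absorbance = absorbance + interferent_conc @ config.interferent_absorptivity()
    return config.source_curve() * np.exp(-config.path_factor(orientation) * absorbance)


def _smooth_log_gain(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth random log-gain curve over the grid (scatter baseline wiggle)."""
    lam = config.grid.values
    u = (lam - lam[0]) / (lam[-1] - lam[0])
    c = rng.normal(0.0, 1.0, 4)
    phase = rng.uniform(0.0, 2 * np.pi, 2)
    curve = (c[0] * (u - 0.5) + c[1] * (2 * (u - 0.5)) ** 2 / 2
             + c[2] * np.sin(2 * np.pi * u + phase[0])
             + c[3] * np.sin(4 * np.pi * u + phase[1]))
    return config.smooth_scatter_amp * curve


def generate_scan(
    ssc: float,
    orientation: str,
    profile: VarietyProfile,
    config: SimulationConfig,
    seed: int,
    sample_id: str = "sample",
    interferent_conc: np.ndarray | None = None,
    band_jitter: np.ndarray | None = None,
) -> MultiPointScan:
    """One fruit's K x P multi-point scan.

    K is drawn uniformly from the profile's point range; each point gets an
    independent multiplicative scatter gain; the first and last points are
    attenuated (incomplete end signals); with probability ``saturation_prob``
    one interior point is scaled up until it clips at the saturation level;
    additive Gaussian noise is applied and intensities clipped to
    ``[0, saturation_level]``.
    """
    if not (profile.ssc_min <= ssc <= profile.ssc_max):
        raise ValueError(
            f"ssc={ssc} outside profile range [{profile.ssc_min}, {profile.ssc_max}]"
        )
    rng = np.random.default_rng(seed)
    k = int(rng.integers(profile.points_min, profile.points_max + 1))
    if interferent_conc is None:
        lo, hi = config.interferent_conc_range
        interferent_conc = rng.uniform(lo, hi, len(config.interferent_bands))
    if band_jitter is None:
        band_jitter = (rng.normal(0.0, config.band_jitter_sd, len(config.ssc_bands))
                       if config.band_jitter_sd > 0 else np.zeros(len(config.ssc_bands)))
    base = _transmitted(ssc, np.asarray(interferent_conc, dtype=float), orientation,
                        config, band_jitter)

    sample_gain = rng.uniform(*config.sample_gain_range)
    if config.smooth_scatter_amp > 0:
        base = base * np.exp(_smooth_log_gain(config, rng))
    gains = sample_gain * rng.uniform(*config.scatter_gain_range, size=k)
    atten = np.ones(k)
    if k >= 3:
        atten[0] = config.end_attenuation
        atten[-1] = config.end_attenuation
    points = gains[:, None] * atten[:, None] * base[None, :]

    if k >= 3 and rng.random() < config.saturation_prob:
        idx = int(rng.integers(1, k - 1))
        peak = points[idx].max()
        if peak > 0:
            points[idx] *= 1.05 * config.saturation_level / peak

    if config.noise_sd > 0:
        points = points + rng.normal(0.0, config.noise_sd, points.shape)
    points = np.clip(points, 0.0, config.saturation_level)
    return MultiPointScan(sample_id=sample_id, orientation=orientation, points=points,
                          grid=config.grid)


def generate_dataset(
    profile: VarietyProfile,
    config: SimulationConfig,
    orientation: str,
    out_dir: str | Path | None = None,
) -> tuple[list[MultiPointScan], BackgroundSpectrum, GroundTruth, "pd.DataFrame"]:
    """Full fixture set: scans, background, ground truth and a manifest.

    When ``out_dir`` is given the CSV fixture files are written there
    (one scan CSV per fruit, one background CSV, a manifest CSV and a
    ground-truth JSON).
    """
    import pandas as pd

    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    root = np.random.default_rng(config.seed)
    ssc = generate_ssc_values(profile, seed=int(root.integers(2**31)))
    background = generate_background(config, seed=int(root.integers(2**31)))
    lo, hi = config.interferent_conc_range
    conc = root.uniform(lo, hi, (profile.n_samples, len(config.interferent_bands)))
    jitter = (root.normal(0.0, config.band_jitter_sd,
                          (profile.n_samples, len(config.ssc_bands)))
              if config.band_jitter_sd > 0
              else np.zeros((profile.n_samples, len(config.ssc_bands))))
    scan_seeds = root.integers(2**31, size=profile.n_samples)

    scans = []
    rows = []
    for i in range(profile.n_samples):
        sid = f"{profile.name}_{orientation}_{i:03d}"
        scan = generate_scan(
            float(ssc[i]), orientation, profile, config, seed=int(scan_seeds[i]),
            sample_id=sid, interferent_conc=conc[i], band_jitter=jitter[i],
        )
        scans.append(scan)
        rows.append({
            "sample_id": sid,
            "variety": profile.name,
            "orientation": orientation,
            "ssc_brix": float(ssc[i]),
            "scan_path": f"scans/{sid}.csv",
        })
    truth = GroundTruth(
        ssc=ssc,
        band_centers=tuple(b.center for b in config.ssc_bands),
        band_widths=tuple(b.width for b in config.ssc_bands),
        interferent_conc=conc,
    )
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        _write_fixture_set(Path(out_dir), scans, background, truth, manifest, config)
    return scans, background, truth, manifest


def _write_fixture_set(root, scans, background, truth, manifest, config) -> None:
    import pandas as pd

    try:
        (root / "scans").mkdir(parents=True, exist_ok=True)
        header = [f"{w:.4f}" for w in config.grid.values]
        for scan in scans:
            pd.DataFrame(scan.points, columns=header).to_csv(
                root / "scans" / f"{scan.sample_id}.csv", index=False
            )
        pd.DataFrame(background.intensity[None, :], columns=header).to_csv(
            root / "background.csv", index=False
        )
        manifest.to_csv(root / "manifest.csv", index=False)
        meta = {
            "background_noise_sd": background.noise_sd,
            "saturation_level": config.saturation_level,
            "band_centers": list(truth.band_centers),
            "band_widths": list(truth.band_widths),
            "ssc": [float(v) for v in truth.ssc],
        }
        (root / "ground_truth.json").write_text(json.dumps(meta, indent=1))
    except OSError as exc:
        raise OSError(f"failed writing fixture set under {root}: {exc}") from exc


def noiseless_spectrum(ssc: float, orientation: str, config: SimulationConfig,
                       interferent_conc: np.ndarray | None = None) -> Spectrum:
    """The exact forward-model spectrum (no scatter/noise); useful as truth."""
    if interferent_conc is None:
        interferent_conc = np.zeros(len(config.interferent_bands))
    return Spectrum(
        intensity=_transmitted(ssc, np.asarray(interferent_conc, float), orientation, config),
        grid=config.grid,
        tags=("noiseless",),
    )
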