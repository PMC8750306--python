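"""Synthetic four-species meat spectra with replicate structure.

Real handheld reflectance spectra of muscle tissue are smooth curves riding on
a broad baseline, with Gaussian-like absorption features whose positions are
well known: haem-pigment (myoglobin/haemoglobin) bands near 418, 546 and
578 nm in the visible, a C–H second-overtone band near 1200 nm and the O–H
first-overtone water band near 1450 nm in the NIR.  Species differ mainly in
pigment level (chicken ≪ pork < lamb < beef) and in fat-related C–H band
intensity, which is what the generator encodes.

The noise model mirrors how replicate scans of one physical sample behave:

* a *sample-level* latent draw jitters every band height and the baseline
  once per sample (biological variation between animals/cuts);
* each replicate scan then receives multiplicative scatter ``1 + N(0, m)``,
  an additive offset ``N(0, a)`` and independent channel noise — the classic
  scatter effects that SNV/MSC-type corrections are designed to remove;
* intact (non-ground) samples receive extra *replicate-level* band jitter,
  reproducing the larger within-sample heterogeneity of intact meat compared
  with ground meat.

All randomness flows through one ``numpy.random.Generator`` (PCG64) seeded
from the config, so equal seeds give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .dataset import (
    ScanMeta,
    SpectralDataset,
    WavelengthGrid,
    concatenate_dual_scans,
    nir_grid,
    visnir_grid,
)
from .errors import ConfigError, ValidationError

#: Relative haem-pigment level per species (drives the visible bands).
PIGMENT_LEVEL: dict[str, float] = {"beef": 1.0, "lamb": 0.80, "pork": 0.55, "chicken": 0.30}
#: Relative intramuscular-fat level per species (drives C–H bands).
FAT_LEVEL: dict[str, float] = {"pork": 0.90, "lamb": 0.70, "beef": 0.50, "chicken": 0.35}


@dataclass(frozen=True)
class SpeciesProfile:
    """Deterministic mean spectrum of one species on one sensor block."""

    species: str
    band_centers_nm: tuple[float, ...]
    band_heights: tuple[float, ...]
    band_widths_nm: tuple[float, ...]
    baseline_coeffs: tuple[float, ...]  # polynomial in scaled position u ∈ [0, 1]

    def __post_init__(self) -> None:
        if len(self.band_centers_nm) != len(self.band_heights) or len(
            self.band_centers_nm
        ) != len(self.band_widths_nm):
            raise ConfigError("band centers, heights and widths must align")
        if any(w <= 0 for w in self.band_widths_nm):
            raise ConfigError("band widths must be positive")

    def evaluate(
        self,
        wavelengths_nm: np.ndarray,
        height_factors: np.ndarray | None = None,
        baseline_shift: float = 0.0,
    ) -> np.ndarray:
        """Evaluate the profile on a wavelength axis.

        ``height_factors`` multiplies each band height (sample/replicate
        jitter); ``baseline_shift`` offsets the baseline.
        """
        wl = np.asarray(wavelengths_nm, dtype=float)
        u = (wl - wl.min()) / (wl.max() - wl.min())
        y = np.polynomial.polynomial.polyval(u, np.asarray(self.baseline_coeffs))
        y = y + baseline_shift
        factors = (
            np.ones(len(self.band_heights))
            if height_factors is None
            else np.asarray(height_factors, dtype=float)
        )
        for c, h, w, f in zip(
            self.band_centers_nm, self.band_heights, self.band_widths_nm, factors
        ):
            y = y + h * f * np.exp(-0.5 * ((wl - c) / w) ** 2)
        return y

    @property
    def n_bands(self) -> int:
        return len(self.band_centers_nm)


def species_profile(species: str, sensor: str, block: int = 1) -> SpeciesProfile:
    """Default profile of a species on one sensor (Vis-NIR blocks 1 and 2).

    Vis-NIR block 1 is the visible-emphasis derived spectrum (haem bands at
    418/546/578 nm plus the 970-nm water band); block 2 is the NIR-emphasis
    derived spectrum (C–H band near 930 nm, water at 970 nm, attenuated
    pigment).  The NIR sensor carries the 1200-nm C–H and 1450-nm O–H bands
    shared by all species, differing only in fat-driven heights — a smaller
    between-species contrast than the pigment bands, so NIR data are by
    construction harder to separate than Vis-NIR data.
    """
    if species not in PIGMENT_LEVEL:
        raise ValidationError(f"unknown species {species!r}")
    p = PIGMENT_LEVEL[species]
    f = FAT_LEVEL[species]
    if sensor == "visnir":
        if block == 1:
            return SpeciesProfile(
                species,
                band_centers_nm=(418.0, 546.0, 578.0, 760.0, 970.0),
                band_heights=(0.60 * p, 0.30 * p, 0.28 * p, 0.05 * p, 0.25),
                band_widths_nm=(12.0, 10.0, 10.0, 20.0, 30.0),
                baseline_coeffs=(0.40, 0.20, -0.10),
            )
        if block == 2:
            return SpeciesProfile(
                species,
                band_centers_nm=(546.0, 930.0, 970.0),
                band_heights=(0.20 * p, 0.18 * f, 0.30),
                band_widths_nm=(10.0, 25.0, 30.0),
                baseline_coeffs=(0.35, 0.10, -0.05),
            )
        raise ConfigError(f"visnir has blocks 1 and 2, got {block}")
    if sensor == "nir":
        return SpeciesProfile(
            species,
            band_centers_nm=(1200.0, 1450.0, 1000.0),
            band_heights=(0.15 + 0.10 * f, 0.50 + 0.03 * (1 - f), 0.08),
            band_widths_nm=(40.0, 60.0, 35.0),
            baseline_coeffs=(0.30, 0.15, -0.05),
        )
    raise ValidationError(f"unknown sensor {sensor!r}")


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one simulated acquisition campaign.

    ``n_samples_per_species`` is either one integer (balanced design) or a
    mapping species → count.  Standard deviations are on the arbitrary
    reflectance-intensity scale of the profiles (baseline height ≈ 0.3–0.6):

    * ``sample_latent_sd`` — relative band-height jitter per sample (0.08
      ≈ the animal-to-animal variation that keeps classes overlapping);
    * ``scatter_mult_sd`` / ``scatter_add_sd`` — per-replicate multiplicative
      and additive scatter (path-length and surface effects);
    * ``noise_sd`` — per-channel detector noise;
    * ``intact_extra_replicate_sd`` — extra relative band jitter per replicate
      for intact meat only (sample heterogeneity under the probe window).

    ``equalize_species=True`` gives every species the pork profile — the null
    condition in which no method should find any separation.
    """

    n_samples_per_species: int | Mapping[str, int] = 20
    replicates_per_sample: int = 6
    sensor: str = "visnir"
    form: str = "intact"
    sample_latent_sd: float = 0.08
    scatter_mult_sd: float = 0.08
    scatter_add_sd: float = 0.02
    noise_sd: float = 0.003
    intact_extra_replicate_sd: float = 0.05
    equalize_species: bool = False
    seed: int = 0
    sample_prefix: str = field(default="", repr=False)

    def counts(self) -> dict[str, int]:
        from .dataset import SPECIES

        if isinstance(self.n_samples_per_species, Mapping):
            counts = {s: int(self.n_samples_per_species.get(s, 0)) for s in SPECIES}
        else:
            counts = {s: int(self.n_samples_per_species) for s in SPECIES}
        if any(c <= 0 for c in counts.values()):
            raise ConfigError(f"sample counts must be positive, got {counts}")
        return counts

    def validate(self) -> None:
        if self.replicates_per_sample < 1:
            raise ConfigError("replicates_per_sample must be >= 1")
        for name in (
            "sample_latent_sd",
            "scatter_mult_sd",
            "scatter_add_sd",
            "noise_sd",
            "intact_extra_replicate_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.sensor not in ("visnir", "nir"):
            raise ConfigError(f"unknown sensor {self.sensor!r}")
        if self.form not in ("intact", "ground"):
            raise ConfigError(f"unknown form {self.form!r}")
        self.counts()


def _profiles_for(cfg: SimConfig, species: str) -> list[SpeciesProfile]:
    src = "pork" if cfg.equalize_species else species
    if cfg.sensor == "visnir":
        profs = [species_profile(src, "visnir", 1), species_profile(src, "visnir", 2)]
    else:
        profs = [species_profile(src, "nir")]
    if cfg.equalize_species:
        profs = [replace(p, species=species) for p in profs]
    return profs


def _block_grids(cfg: SimConfig) -> list[np.ndarray]:
    if cfg.sensor == "visnir":
        g = visnir_grid().wavelengths_nm
        return [g[:600], g[600:]]
    return [nir_grid().wavelengths_nm]


def generate_dataset(cfg: SimConfig) -> SpectralDataset:
    """Simulate one acquisition campaign under ``cfg``.

    Rows are ordered species-major, sample-major, replicate-minor.  The same
    seed always produces the identical matrix (PCG64 generator).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.counts()
    grids = _block_grids(cfg)

    block_rows: list[list[np.ndarray]] = [[] for _ in grids]
    meta: list[ScanMeta] = []
    for species in counts:
        profiles = _profiles_for(cfg, species)
        for s in range(counts[species]):
            sid = f"{cfg.sample_prefix}{cfg.sensor}-{species}-{s + 1:03d}"
            # one latent draw per sample: band-height factors + baseline shift
            sample_factors = [
                1.0 + rng.normal(0.0, cfg.sample_latent_sd, size=p.n_bands)
                for p in profiles
            ]
            sample_shift = rng.normal(0.0, 0.02)
            for r in range(1, cfg.replicates_per_sample + 1):
                mult = 1.0 + rng.normal(0.0, cfg.scatter_mult_sd)
                add = rng.normal(0.0, cfg.scatter_add_sd)
                for b, (prof, grid) in enumerate(zip(profiles, grids)):
                    factors = sample_factors[b]
                    if cfg.form == "intact" and cfg.intact_extra_replicate_sd > 0:
                        factors = factors * (
                            1.0
                            + rng.normal(
                                0.0, cfg.intact_extra_replicate_sd, size=prof.n_bands
                            )
                        )
                    y = prof.evaluate(grid, factors, sample_shift)
                    y = mult * y + add + rng.normal(0.0, cfg.noise_sd, size=grid.size)
                    block_rows[b].append(y)
                meta.append(ScanMeta(sid, species, cfg.form, r))

    if cfg.sensor == "visnir":
        return concatenate_dual_scans(
            np.vstack(block_rows[0]), np.vstack(block_rows[1]), grids[0], grids[1], meta
        )
    return SpectralDataset(np.vstack(block_rows[0]), nir_grid(), meta)


#: Per-species sample counts of the two real acquisition campaigns.
VISNIR_SAMPLE_COUNTS: dict[str, int] = {"lamb": 37, "beef": 40, "chicken": 40, "pork": 40}
NIR_SAMPLE_COUNTS: dict[str, int] = {"lamb": 41, "beef": 48, "chicken": 40, "pork": 32}


def paper_shaped_datasets(seed: int = 0) -> tuple[SpectralDataset, SpectralDataset]:
    """Two datasets with the shapes of the real campaigns.

    Vis-NIR: 157 samples (lamb 37, beef 40, chicken 40, pork 40) × 6 replicate
    scans = 942 rows × 1200 channels.  NIR: 161 samples (lamb 41, beef 48,
    chicken 40, pork 32) × 6 = 966 rows × 252 channels.
    """
    vis = generate_dataset(
        SimConfig(n_samples_per_species=VISNIR_SAMPLE_COUNTS, sensor="visnir", seed=seed)
    )
    nir = generate_dataset(
        SimConfig(n_samples_per_species=NIR_SAMPLE_COUNTS, sensor="nir", seed=seed + 1)
    )
    return vis, nir
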