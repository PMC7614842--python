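"""Seeded generators for every input the analysis consumes.

All generators are pure functions of (spec, seed) and return ground truth
alongside the data, so downstream tests are closed-loop: follicle images
with known masks and analytic radial profiles, in-vivo decay tables driven
by the bond-kinetics forward model, BLI sensorgram panels and fluorescent
bead panels with known generating parameters.

The follicle generator emulates confocal slices of clarified lymph nodes:
disk-like FDC networks with either a uniform antigen fill (the day-1
pattern, antigen spread over the whole network) or a centered radial
Gaussian (the day-7/14 pattern, antigen concentrated on central FDCs),
plus additive Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding_fits import simulate_sensorgram
from .bond_kinetics import BondKineticsParams, density_to_mean_nR, mixture_level_at
from .imaging import FollicleImage

__all__ = [
    "FollicleSpec",
    "DecayDatasetSpec",
    "FollicleGroundTruth",
    "gen_follicle_image",
    "gen_decay_dataset",
    "gen_sensorgram_panel",
    "gen_bead_panel",
    "gaussian_annulus_mean",
]


@dataclass(frozen=True)
class FollicleSpec:
    """Geometry and intensity model of one synthetic follicle.

    ``antigen_profile`` is ``"uniform"`` (constant fill inside the disk) or
    ``"gaussian"`` (centered radial Gaussian of width ``sigma_um``).
    """

    center: tuple  # (row, col) pixels
    radius_um: float
    structural_intensity: float = 100.0
    antigen_profile: str = "uniform"
    antigen_amplitude: float = 100.0
    sigma_um: float | None = None
    background: float = 10.0
    noise_sd: float = 10.0

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.antigen_profile not in ("uniform", "gaussian"):
            raise ValueError(f"unknown antigen profile {self.antigen_profile!r}")
        if self.antigen_profile == "gaussian" and not (self.sigma_um or 0) > 0:
            raise ValueError("gaussian profile needs sigma_um > 0")


@dataclass(frozen=True)
class DecayDatasetSpec:
    """Per-animal IC-level observations generated by the forward model."""

    params: BondKineticsParams
    mean_densities: tuple  # molecules/um^2 per group
    days: tuple = (1, 4, 7)
    animals_per_group: int = 5
    noise_sd: float = 0.1  # sd of multiplicative lognormal noise

    def __post_init__(self):
        if any(d <= 0 for d in self.days):
            raise ValueError("days must be positive")
        if self.animals_per_group < 1:
            raise ValueError("animals_per_group must be >= 1")


@dataclass(frozen=True)
class FollicleGroundTruth:
    """True masks and analytic radial means for a generated image."""

    masks: list  # boolean array per follicle, full resolution
    specs: list
    pixel_size: float
    overlapping: bool

    def analytic_annulus_mean(self, follicle: int, r_in_um: float, r_out_um: float) -> float:
        """Mean antigen signal (above background) over an annulus."""
        spec = self.specs[follicle]
        if spec.antigen_profile == "uniform":
            return spec.antigen_amplitude
        return gaussian_annulus_mean(
            spec.antigen_amplitude, spec.sigma_um, r_in_um, r_out_um
        )


def gaussian_annulus_mean(amplitude: float, sigma: float, r_in: float, r_out: float) -> float:
    """Area-weighted mean of ``A exp(-r^2 / 2 sigma^2)`` over an annulus."""
    if r_out <= r_in:
        raise ValueError("need r_out > r_in")
    num = 2.0 * sigma**2 * (np.exp(-(r_in**2) / (2 * sigma**2)) - np.exp(-(r_out**2) / (2 * sigma**2)))
    return amplitude * num / (r_out**2 - r_in**2)


def gen_follicle_image(
    specs,
    frame_shape=(512, 512),
    pixel_size: float = 4.0,
    seed: int = 0,
    structural_name: str = "cd21",
    antigen_name: str = "antigen",
):
    """Render follicles into a two-channel image; returns (image, truth)."""
    specs = list(specs)
    rng = np.random.default_rng(seed)
    rows, cols = np.indices(frame_shape)
    structural = np.zeros(frame_shape)
    antigen = np.zeros(frame_shape)
    masks = []
    for spec in specs:
        r_px = spec.radius_um / pixel_size
        cy, cx = spec.center
        if not (r_px <= cy <= frame_shape[0] - r_px and r_px <= cx <= frame_shape[1] - r_px):
            raise ValueError(f"follicle at {spec.center} does not fit in the frame")
        r_um = np.hypot(rows - cy, cols - cx) * pixel_size
        disk = r_um <= spec.radius_um
        masks.append(disk)
        structural[disk] += spec.structural_intensity
        if spec.antigen_profile == "uniform":
            antigen[disk] += spec.antigen_amplitude
        else:
            antigen[disk] += spec.antigen_amplitude * np.exp(
                -(r_um[disk] ** 2) / (2 * spec.sigma_um**2)
            )
    overlapping = any(
        np.any(masks[i] & masks[j])
        for i in range(len(masks))
        for j in range(i + 1, len(masks))
    )
    bg = specs[0].background if specs else 0.0
    noise = specs[0].noise_sd if specs else 0.0
    structural += bg
    antigen += bg
    if noise > 0:
        structural = structural + rng.normal(0.0, noise, frame_shape)
        antigen = antigen + rng.normal(0.0, noise, frame_shape)
    image = FollicleImage(
        channels={structural_name: structural, antigen_name: antigen},
        structural=structural_name,
        pixel_size=pixel_size,
    )
    truth = FollicleGroundTruth(
        masks=masks, specs=specs, pixel_size=pixel_size, overlapping=overlapping
    )
    return image, truth


def gen_decay_dataset(spec: DecayDatasetSpec, seed: int = 0) -> pd.DataFrame:
    """Observation table ``animal_id, group_density, day, mfi``.

    Each animal's level at each day is the forward-model IC surface level
    ``<S(t)> * <n_R>`` at the group's CR2 density, times multiplicative
    lognormal noise (MFI is positive and its spread grows with signal).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for density in spec.mean_densities:
        mean_nR = density_to_mean_nR(density, spec.params.patch_area)
        levels = mixture_level_at(
            spec.params, mean_nR, np.asarray(spec.days, dtype=float) * 86400.0
        )
        for a in range(spec.animals_per_group):
            for day, level in zip(spec.days, levels):
                noise = (
                    rng.lognormal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 1.0
                )
                rows.append(
                    {
                        "animal_id": f"d{density:g}_a{a}",
                        "group_density": density,
                        "day": day,
                        "mfi": level * noise,
                    }
                )
    return pd.DataFrame(rows)


def gen_sensorgram_panel(
    k_on: float,
    k_off: float,
    R_max: float,
    concentrations,
    t_assoc: float = 120.0,
    t_dissoc: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Sensorgrams over a concentration series with shared kinetics."""
    return [
        simulate_sensorgram(
            k_on, k_off, R_max, c, t_assoc, t_dissoc, noise_sd=noise_sd, seed=seed + i
        )
        for i, c in enumerate(concentrations)
    ]


def gen_bead_panel(
    slope: float,
    intercept: float,
    mfi_levels=(1e2, 1e3, 1e4, 1e5),
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Four-level fluorescent bead panel: returns (mfi, molecule_counts)."""
    rng = np.random.default_rng(seed)
    mfi = np.asarray(mfi_levels, dtype=float)
    counts = slope * mfi + intercept
    if noise_sd > 0:
        counts = counts * rng.lognormal(0.0, noise_sd, size=counts.shape)
    return mfi, counts
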