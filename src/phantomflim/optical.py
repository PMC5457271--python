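"""Diffusion-reflectance forward model and optical-coefficient algebra.

A pencil beam entering a semi-infinite turbid medium produces a surface
reflectance profile that, in the diffusion regime, decays with
source-detector separation rho as

    Gamma(rho) = c1 / rho**2 * exp(-mu_eff * rho)

where ``mu_eff = sqrt(3 * mu_a * mu_s')`` is the effective attenuation
coefficient.  Taking ``ln(rho**2 * Gamma)`` linearises the profile:
slope ``-mu_eff``, intercept ``ln(c1)``.

Units: all lengths are millimetres and all coefficients are per-mm
throughout the package; intensities are arbitrary (counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "OpticalProperties",
    "ReflectanceProfile",
    "DrForwardParams",
    "InsufficientDataError",
    "effective_attenuation",
    "forward_reflectance",
    "log_rho2_transform",
    "read_profile",
    "write_profile",
]


class InsufficientDataError(ValueError):
    """Fewer than two usable reflectance samples remain after exclusion.

    This is the measurement-failure regime: at high absorption every
    detector position falls below the noise floor and no slope exists.
    """


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced-scattering pair for one medium and wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, per mm, >= 0.
    mu_s_prime : float
        Reduced scattering coefficient, per mm, > 0.
    wavelength : float, optional
        Illumination wavelength in nm; metadata only.
    """

    mu_a: float
    mu_s_prime: float
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_a) or self.mu_a < 0:
            raise ValueError(f"mu_a must be finite and >= 0, got {self.mu_a}")
        if not np.isfinite(self.mu_s_prime) or self.mu_s_prime <= 0:
            raise ValueError(
                f"mu_s_prime must be finite and > 0, got {self.mu_s_prime}"
            )

    @property
    def mu_eff(self) -> float:
        """Effective attenuation coefficient sqrt(3 * mu_a * mu_s'), per mm."""
        return effective_attenuation(self)


@dataclass
class ReflectanceProfile:
    """Ordered (rho, Gamma) samples from one diffuse-reflectance scan.

    ``rho`` must be strictly increasing and positive (mm); ``gamma`` holds
    the matching non-negative intensities.  ``noise_floor`` marks the
    intensity below which a sample counts as undetected (dark-count level).
    """

    rho: np.ndarray
    gamma: np.ndarray
    noise_floor: float | None = None
    wavelength: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.rho.ndim != 1 or self.gamma.ndim != 1:
            raise ValueError("rho and gamma must be one-dimensional")
        if self.rho.size != self.gamma.size:
            raise ValueError(
                f"rho and gamma lengths differ: {self.rho.size} vs {self.gamma.size}"
            )
        if self.rho.size < 2:
            raise ValueError("a reflectance profile needs at least 2 samples")
        if np.any(self.rho <= 0):
            raise ValueError("all separations rho must be > 0")
        if np.any(np.diff(self.rho) <= 0):
            raise ValueError("rho must be strictly increasing")
        if np.any(self.gamma < 0):
            raise ValueError("gamma intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.rho.size)


@dataclass(frozen=True)
class DrForwardParams:
    """Amplitude constant c1 (> 0) plus the medium's optical properties."""

    c1: float
    optical: OpticalProperties

    def __post_init__(self) -> None:
        if not np.isfinite(self.c1) or self.c1 <= 0:
            raise ValueError(f"c1 must be finite and > 0, got {self.c1}")

    @property
    def c2(self) -> float:
        """Log-amplitude intercept ln(c1); derived, never stored."""
        return float(np.log(self.c1))


def effective_attenuation(optical: OpticalProperties) -> float:
    """Return the effective attenuation coefficient sqrt(3 mu_a mu_s'), per mm."""
    return float(np.sqrt(3.0 * optical.mu_a * optical.mu_s_prime))


def forward_reflectance(
    params: DrForwardParams,
    rho: Sequence[float] | np.ndarray,
    *,
    noise_floor: float | None = None,
) -> ReflectanceProfile:
    """Evaluate the diffusion forward model on separations ``rho``.

    Gamma(rho) = c1 / rho**2 * exp(-mu_eff * rho); strictly decreasing in
    rho for mu_eff >= 0.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("forward model diverges at rho <= 0")
    mu = effective_attenuation(params.optical)
    gamma = params.c1 / rho**2 * np.exp(-mu * rho)
    return ReflectanceProfile(
        rho=rho,
        gamma=gamma,
        noise_floor=noise_floor,
        wavelength=params.optical.wavelength,
    )


def log_rho2_transform(
    profile: ReflectanceProfile,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Map a profile onto the linearising coordinates y = ln(rho**2 * Gamma).

    Samples with Gamma <= 0 or Gamma <= noise_floor are dropped (not
    clipped: clipping would bias the slope) and counted.

    Returns
    -------
    rho_valid, y, n_excluded : (ndarray, ndarray, int)

    Raises
    ------
    InsufficientDataError
        If fewer than two valid samples remain -- the regime where the
        measurement cannot provide an attenuation value.
    """
    floor = profile.noise_floor if profile.noise_floor is not None else 0.0
    keep = (profile.gamma > 0) & (profile.gamma > floor)
    n_excluded = int(np.count_nonzero(~keep))
    if np.count_nonzero(keep) < 2:
        raise InsufficientDataError(
            f"only {int(np.count_nonzero(keep))} sample(s) above the noise "
            f"floor; at least 2 are needed to extract a slope"
        )
    rho_v = profile.rho[keep]
    y = np.log(rho_v**2 * profile.gamma[keep])
    return rho_v, y, n_excluded


# -- delimited-text I/O ------------------------------------------------------

_HEADER = "rho_mm\tintensity"


def write_profile(profile: ReflectanceProfile, path: str | Path) -> None:
    """Write a profile as 2-column tab-delimited text with '#' metadata lines."""
    path = Path(path)
    lines = []
    if profile.label:
        lines.append(f"# label: {profile.label}")
    if profile.wavelength is not None:
        lines.append(f"# wavelength_nm: {profile.wavelength:g}")
    if profile.noise_floor is not None:
        lines.append(f"# noise_floor: {profile.noise_floor:.10g}")
    lines.append(_HEADER)
    for r, g in zip(profile.rho, profile.gamma):
        lines.append(f"{r:.10g}\t{g:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> ReflectanceProfile:
    """Read a profile written by :func:`write_profile`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rho: list[float] = []
    gamma: list[float] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if line.lower().startswith("rho"):
            continue
        parts = line.replace(",", "\t").split()
        rho.append(float(parts[0]))
        gamma.append(float(parts[1]))
    return ReflectanceProfile(
        rho=np.asarray(rho),
        gamma=np.asarray(gamma),
        noise_floor=float(meta["noise_floor"]) if "noise_floor" in meta else None,
        wavelength=float(meta["wavelength_nm"]) if "wavelength_nm" in meta else None,
        label=meta.get("label", ""),
    )
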