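"""Synthetic phantom and solution measurements for end-to-end validation.

Everything the analysis pipeline consumes can be generated here with
known ground truth: diffuse-reflectance profiles under the 1/rho**2
exponential-attenuation law with Poisson shot noise and a dark-count
detection floor; FLIM image stacks with per-pixel Poisson counting noise
and an optional spatially-correlated log-normal concentration field (the
solidification inhomogeneity seen in real agarose phantoms); and the
volumetric recipes used to pour the phantoms themselves.

Every stochastic operation takes an explicit seed; there is no global
random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import reference
from .decay import AcquisitionSettings, DecayModel, expected_bin_counts
from .fitting import FlimImage, write_flim_image
from .optical import (
    DrForwardParams,
    OpticalProperties,
    ReflectanceProfile,
    forward_reflectance,
    write_profile,
)

__all__ = [
    "PhantomSpec",
    "PhantomRecipe",
    "compute_recipe",
    "default_optical_properties",
    "DEFAULT_RHO_MM",
    "heterogeneity_field",
    "simulate_dr_profile",
    "simulate_flim_image",
    "simulate_interface_image",
    "make_reference_fixture_suite",
]

#: Default source-detector separations: 1.0-6.0 mm in 0.25-mm steps,
#: spanning the diffusive regime of a fibre-illuminated surface scan.
DEFAULT_RHO_MM: np.ndarray = np.arange(1.0, 6.0 + 1e-9, 0.25)

#: Baseline phantom optics (configurable; literature-plausible placeholders,
#: not measured values).  Reduced scattering ~1/mm is Intralipid-like;
#: ink-only absorption is small; gold nanorods add absorption per mg/mL,
#: more strongly at 650 nm (near their plasmon peak) than at 780 nm.
_BASE_MU_S_PRIME = 1.0
_BASE_MU_A_INK = 0.005
_GNR_MU_A_PER_MG_ML = {650.0: 0.5, 780.0: 0.15}


def default_optical_properties(
    au_mg_ml: float = 0.0,
    wavelengths: tuple[float, ...] = reference.DR_WAVELENGTHS_NM,
) -> dict[float, OpticalProperties]:
    """Baseline phantom optics at each wavelength for a given gold load."""
    out = {}
    for wl in wavelengths:
        mu_a = _BASE_MU_A_INK + _GNR_MU_A_PER_MG_ML.get(wl, 0.3) * au_mg_ml
        out[wl] = OpticalProperties(
            mu_a=mu_a, mu_s_prime=_BASE_MU_S_PRIME, wavelength=wl
        )
    return out


@dataclass
class PhantomSpec:
    """Ground-truth description of one simulated phantom or solution.

    heterogeneity_cv is the coefficient of variation of a per-pixel
    concentration multiplier (0 = perfectly homogeneous); grid is the
    scan size in pixels.
    """

    truth_decay: DecayModel
    optical: dict[float, OpticalProperties] = field(
        default_factory=default_optical_properties
    )
    heterogeneity_cv: float = 0.0
    heterogeneity_corr_px: float = 4.0
    grid: tuple[int, int] = (64, 64)
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.heterogeneity_cv < 0:
            raise ValueError("heterogeneity_cv must be >= 0")
        if min(self.grid) < 1:
            raise ValueError("grid dimensions must be >= 1")


# ---------------------------------------------------------------------------
# phantom recipes


@dataclass(frozen=True)
class PhantomRecipe:
    """Volumetric recipe for one poured phantom (all volumes in uL).

    Fixed fractions: Intralipid 10% of total, diluted India ink 3%,
    contrast solution as needed for the target concentration, water to
    volume; agarose at 1 g per 100 mL.
    """

    total_volume: float
    il_volume: float
    ink_volume: float
    contrast_volume: float
    ddw_volume: float
    agarose_mass: float  # mg

    def __post_init__(self) -> None:
        parts = (
            self.il_volume
            + self.ink_volume
            + self.contrast_volume
            + self.ddw_volume
        )
        if abs(parts - self.total_volume) > 1e-9 * max(self.total_volume, 1.0):
            raise ValueError("component volumes must sum to total_volume")


def compute_recipe(
    total_volume: float, target_conc: float, stock_conc: float
) -> PhantomRecipe:
    """Volumes needed to pour ``total_volume`` uL at ``target_conc``.

    ``target_conc`` and ``stock_conc`` share any one concentration unit
    (uM, mg/mL, ...); only their ratio enters.  The contrast solution may
    occupy at most 87% of the total volume (the remainder after the fixed
    Intralipid and ink fractions); beyond that the recipe is infeasible.
    """
    if total_volume <= 0:
        raise ValueError("total_volume must be > 0")
    if not (stock_conc > target_conc > 0):
        raise ValueError("need stock_conc > target_conc > 0")
    contrast = total_volume * target_conc / stock_conc
    il = 0.10 * total_volume
    ink = 0.03 * total_volume
    if contrast > 0.87 * total_volume + 1e-12:
        raise ValueError(
            f"infeasible recipe: contrast volume {contrast:.3g} uL exceeds "
            f"87% of the total volume"
        )
    ddw = total_volume - il - ink - contrast
    agarose_mg = 0.01 * total_volume  # 1 g / 100 mL == 0.01 mg/uL
    return PhantomRecipe(
        total_volume=float(total_volume),
        il_volume=float(il),
        ink_volume=float(ink),
        contrast_volume=float(contrast),
        ddw_volume=float(ddw),
        agarose_mass=float(agarose_mg),
    )


# ---------------------------------------------------------------------------
# diffuse-reflectance simulation


def simulate_dr_profile(
    spec: PhantomSpec,
    wavelength: float,
    rho: np.ndarray | None = None,
    counts_at_rho1: float = 1e6,
    seed: int | None = None,
    noise_floor: float = 10.0,
) -> ReflectanceProfile:
    """Simulate one shot-noise-limited reflectance scan of a phantom.

    The expected profile follows the diffusion forward model, scaled so
    the expectation at the nearest separation equals ``counts_at_rho1``;
    measured samples are Poisson draws.  ``noise_floor`` is the dark-count
    level below which a sample counts as undetected.
    """
    if wavelength not in spec.optical:
        raise ValueError(
            f"no optical properties for wavelength {wavelength} nm "
            f"(have {sorted(spec.optical)})"
        )
    if rho is None:
        rho = DEFAULT_RHO_MM
    rho = np.asarray(rho, dtype=float)
    params = DrForwardParams(c1=1.0, optical=spec.optical[wavelength])
    clean = forward_reflectance(params, rho)
    scale = counts_at_rho1 / clean.gamma[0]
    expected = clean.gamma * scale
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    counts = rng.poisson(expected).astype(float)
    return ReflectanceProfile(
        rho=rho,
        gamma=counts,
        noise_floor=noise_floor,
        wavelength=wavelength,
        label=spec.label,
    )


# ---------------------------------------------------------------------------
# FLIM image simulation


def heterogeneity_field(
    grid: tuple[int, int],
    cv: float,
    corr_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially-smooth log-normal concentration multiplier with mean ~1.

    A white Gaussian field is smoothed over ``corr_px`` pixels,
    re-standardised, and exponentiated with the log-sigma that gives the
    requested coefficient of variation; the log-normal mean correction
    keeps the field mean at 1 so total intensity is CV-invariant.
    """
    if cv == 0:
        return np.ones(grid)
    g = rng.standard_normal(grid)
    if corr_px > 0:
        g = gaussian_filter(g, corr_px, mode="reflect")
    g = (g - g.mean()) / g.std()
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(sigma * g - 0.5 * sigma**2)


def simulate_flim_image(
    spec: PhantomSpec,
    settings: AcquisitionSettings,
    seed: int | None = None,
) -> FlimImage:
    """Simulate a full FLIM acquisition of one phantom/solution.

    Every pixel shares the ground-truth decay; its expected curve is
    scaled by the pixel's concentration multiplier and counts are drawn
    Poisson per bin.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    expected = expected_bin_counts(spec.truth_decay, settings).counts
    mult = heterogeneity_field(
        spec.grid, spec.heterogeneity_cv, spec.heterogeneity_corr_px, rng
    )
    lam = mult[:, :, None] * expected[None, None, :]
    counts = rng.poisson(lam)
    return FlimImage(counts=counts, settings=settings)


def simulate_interface_image(
    left_spec: PhantomSpec,
    right_spec: PhantomSpec,
    settings: AcquisitionSettings,
    seed: int = 0,
) -> FlimImage:
    """Two-region image: left half one decay, right half another.

    Emulates scanning across the interface between two adjoining phantoms
    (e.g. free dye against a nanorod conjugate).
    """
    if left_spec.grid != right_spec.grid:
        raise ValueError("both regions must use the same grid")
    rows, cols = left_spec.grid
    left = simulate_flim_image(left_spec, settings, seed=seed)
    right = simulate_flim_image(right_spec, settings, seed=seed + 1)
    counts = left.counts.copy()
    counts[:, cols // 2 :, :] = right.counts[:, cols // 2 :, :]
    return FlimImage(counts=counts, settings=settings)


# ---------------------------------------------------------------------------
# reference fixture suite


def _mono_spec(tau: float, cv: float, grid, seed, label) -> PhantomSpec:
    return PhantomSpec(
        truth_decay=DecayModel(amplitudes=(1.0,), lifetimes=(tau,)),
        heterogeneity_cv=cv,
        grid=grid,
        seed=seed,
        label=label,
    )


def _biexp_spec(
    a1_pct: float, tau1: float, tau2: float, cv: float, grid, seed, label
) -> PhantomSpec:
    f1 = a1_pct / 100.0
    return PhantomSpec(
        truth_decay=DecayModel(
            amplitudes=(f1, 1.0 - f1),
            lifetimes=(tau1, tau2),
            fixed_mask=(False, True),
        ),
        heterogeneity_cv=cv,
        grid=grid,
        seed=seed,
        label=label,
    )


def make_reference_fixture_suite(
    out_dir: str | Path,
    master_seed: int = 0,
    grid: tuple[int, int] = (16, 16),
    counts_target: float = 1e4,
    rep_rate: float = 50.0,
    n_bins: int = 256,
    phantom_cv: float = 0.1,
) -> dict:
    """Write the full reference measurement suite as files + JSON manifest.

    Contents: one two-component solution image per linker (slow component
    at the free-dye solution lifetime), three phantom-area images per
    linker (slow component at the free-dye phantom lifetime,
    heterogeneity on), the two free-dye images, and reflectance profiles
    for the six-step gold-concentration ladder at both rig wavelengths.
    The manifest records every file's ground truth; a fixed master seed
    makes the suite bit-reproducible.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    settings = AcquisitionSettings(
        rep_rate=rep_rate, n_bins=n_bins, counts_target=counts_target
    )
    seed_seq = np.random.SeedSequence(master_seed)
    seeds = iter(int(s) % (2**31) for s in seed_seq.generate_state(64))
    manifest: dict = {
        "master_seed": master_seed,
        "settings": {
            "rep_rate": rep_rate,
            "n_bins": n_bins,
            "counts_target": counts_target,
        },
        "flim_images": [],
        "dr_profiles": [],
    }

    def _write(spec: PhantomSpec, name: str, kind: str, tau2_fixed: float | None):
        image = simulate_flim_image(spec, settings)
        path = out_dir / f"{name}.tif"
        write_flim_image(image, path)
        entry = {
            "file": path.name,
            "label": spec.label,
            "kind": kind,
            "truth": {
                "amplitudes": list(spec.truth_decay.amplitudes),
                "lifetimes": list(spec.truth_decay.lifetimes),
            },
            "heterogeneity_cv": spec.heterogeneity_cv,
            "seed": spec.seed,
        }
        if tau2_fixed is not None:
            entry["tau2_fixed"] = tau2_fixed
        manifest["flim_images"].append(entry)

    # free-dye anchors
    _write(
        _mono_spec(
            reference.FREE_DYE_SOLUTION_TAU_NS, 0.0, grid, next(seeds),
            "free-dye solution",
        ),
        "free_dye_solution", "free_dye_solution", None,
    )
    _write(
        _mono_spec(
            reference.FREE_DYE_PHANTOM_TAU_NS, phantom_cv, grid, next(seeds),
            "free-dye phantom",
        ),
        "free_dye_phantom", "free_dye_phantom", None,
    )

    # solution-regime conjugates
    for key, row in reference.SOLUTION_ROWS.items():
        spec = _biexp_spec(
            row.a1_pct, row.tau1_ns, reference.FREE_DYE_SOLUTION_TAU_NS,
            0.0, grid, next(seeds), key,
        )
        _write(spec, f"solution_{_slug(key)}", "solution",
               reference.FREE_DYE_SOLUTION_TAU_NS)

    # phantom-regime conjugates, three areas each
    for key, row in reference.PHANTOM_AREA_ROWS.items():
        spec = _biexp_spec(
            row.a1_pct, row.tau1_ns, reference.FREE_DYE_PHANTOM_TAU_NS,
            phantom_cv, grid, next(seeds), key,
        )
        _write(spec, f"phantom_{_slug(key)}", "phantom_area",
               reference.FREE_DYE_PHANTOM_TAU_NS)

    # reflectance ladder: six gold loads x two wavelengths
    for au in reference.AU_CONCENTRATION_LADDER_MG_ML:
        optical = default_optical_properties(au_mg_ml=au)
        for wl in reference.DR_WAVELENGTHS_NM:
            spec = PhantomSpec(
                truth_decay=DecayModel(amplitudes=(1.0,), lifetimes=(1.0,)),
                optical=optical,
                seed=next(seeds),
                label=f"Au {au:g} mg/mL",
            )
            prof = simulate_dr_profile(spec, wl)
            fname = f"dr_au_{str(au).replace('.', 'p')}_wl{int(wl)}.tsv"
            write_profile(prof, out_dir / fname)
            manifest["dr_profiles"].append(
                {
                    "file": fname,
                    "label": spec.label,
                    "wavelength_nm": wl,
                    "au_mg_ml": au,
                    "mu_eff_true": optical[wl].mu_eff,
                    "seed": spec.seed,
                }
            )

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _slug(label: str) -> str:
    return (
        label.replace(" ", "_")
        .replace("(", "")
        .replace(")", "")
        .replace("/", "-")
        .lower()
    )
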