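"""Reference measurement values used as simulation ground truths.

These are published in-lab measurements of fluorescein-conjugated gold
nanorods (GNRs) in solution and in agarose/Intralipid/India-ink tissue
phantoms: the free-dye lifetime anchors, the per-linker two-component fit
parameters (amplitude percentage of the quenched component, its fast
lifetime, and the fit-quality chi-square, each with a per-pixel STD), and
estimated linker end-to-end lengths.  The synthetic generator treats them
as the conditions to emulate; the lifetime-shortening mechanism itself
(plasmonic near-field quenching) is taken as given, never simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FREE_DYE_SOLUTION_TAU_NS",
    "FREE_DYE_SOLUTION_TAU_STD_NS",
    "FREE_DYE_PHANTOM_TAU_NS",
    "FREE_DYE_PHANTOM_TAU_STD_NS",
    "ConjugateRow",
    "SOLUTION_ROWS",
    "PHANTOM_AREA_ROWS",
    "LINKER_LENGTH_NM",
    "AU_CONCENTRATION_LADDER_MG_ML",
    "DR_WAVELENGTHS_NM",
]

#: Pixel-mean lifetime of free fluorescein in aqueous solution (ns) and
#: its per-pixel STD over a mono-exponential FLIM fit.
FREE_DYE_SOLUTION_TAU_NS: float = 3.92
FREE_DYE_SOLUTION_TAU_STD_NS: float = 0.04

#: The same dye embedded in a solid tissue phantom.
FREE_DYE_PHANTOM_TAU_NS: float = 3.74
FREE_DYE_PHANTOM_TAU_STD_NS: float = 0.06


@dataclass(frozen=True)
class ConjugateRow:
    """Two-component fit parameters for one linker (image-level mean/STD)."""

    linker: str
    a1_pct: float
    a1_pct_std: float
    tau1_ns: float
    tau1_std_ns: float
    chi2: float
    chi2_std: float


#: Solution-regime measurements (slow component fixed at the free-dye
#: solution lifetime, 3.92 ns).  Keys are linker labels.
SOLUTION_ROWS: dict[str, ConjugateRow] = {
    row.linker: row
    for row in [
        ConjugateRow("NH2-PEG-SH-5kDa", 81.16, 6.13, 1.15, 0.24, 1.312, 0.535),
        ConjugateRow("NH2-PEG-SH-1kDa", 91.15, 6.52, 0.74, 0.23, 1.461, 0.327),
        ConjugateRow("16-amino-1-hexadecanethiol", 87.02, 3.55, 1.95, 0.13, 1.609, 0.149),
        ConjugateRow("11-amino-1-undecanethiol", 66.13, 13.49, 2.72, 0.28, 1.366, 0.332),
        ConjugateRow("6-amino-1-hexanethiol", 81.03, 6.46, 1.10, 0.17, 1.259, 0.360),
        ConjugateRow("MDDA", 80.84, 6.84, 2.38, 0.18, 1.124, 0.132),
    ]
}

#: Phantom-regime measurements (slow component fixed at 3.74 ns); each
#: phantom was measured in three areas, keyed "<linker> (k)".
PHANTOM_AREA_ROWS: dict[str, ConjugateRow] = {
    row.linker: row
    for row in [
        ConjugateRow("NH2-PEG-SH-5kDa (1)", 81.31, 5.00, 0.81, 0.11, 5.25, 1.02),
        ConjugateRow("NH2-PEG-SH-5kDa (2)", 78.18, 7.57, 0.96, 0.23, 2.86, 0.53),
        ConjugateRow("NH2-PEG-SH-5kDa (3)", 70.10, 10.31, 0.54, 0.21, 2.71, 0.55),
        ConjugateRow("NH2-PEG-SH-1kDa (1)", 65.29, 8.31, 0.58, 0.11, 1.25, 0.13),
        ConjugateRow("NH2-PEG-SH-1kDa (2)", 81.77, 3.72, 0.89, 0.11, 2.75, 0.37),
        ConjugateRow("NH2-PEG-SH-1kDa (3)", 74.38, 3.33, 0.35, 0.11, 1.67, 0.21),
        ConjugateRow("16-amino-1-hexadecanethiol (1)", 78.15, 3.84, 0.69, 0.13, 3.74, 0.70),
        ConjugateRow("16-amino-1-hexadecanethiol (2)", 72.23, 4.48, 0.43, 0.10, 2.12, 0.34),
        ConjugateRow("16-amino-1-hexadecanethiol (3)", 77.46, 8.68, 1.22, 0.31, 2.01, 0.36),
        ConjugateRow("11-amino-1-undecanethiol (1)", 79.80, 3.71, 0.85, 0.08, 7.29, 1.37),
        ConjugateRow("11-amino-1-undecanethiol (2)", 65.91, 3.63, 0.46, 0.08, 3.38, 0.60),
        ConjugateRow("11-amino-1-undecanethiol (3)", 67.60, 6.82, 0.73, 0.16, 4.40, 0.87),
        ConjugateRow("6-amino-1-hexanethiol (1)", 50.15, 18.90, 2.29, 0.67, 1.19, 0.18),
        ConjugateRow("6-amino-1-hexanethiol (2)", 50.99, 13.16, 1.21, 0.57, 1.60, 0.65),
        ConjugateRow("6-amino-1-hexanethiol (3)", 52.15, 10.57, 1.09, 0.41, 1.35, 0.79),
        ConjugateRow("MDDA (1)", 82.41, 9.83, 1.69, 0.25, 1.20, 0.16),
        ConjugateRow("MDDA (2)", 74.63, 9.08, 0.92, 0.19, 3.90, 0.79),
        ConjugateRow("MDDA (3)", 60.76, 3.29, 0.51, 0.10, 1.81, 0.24),
    ]
}

#: Estimated linker end-to-end lengths in nm (metadata only; MDDA envelops
#: the rod rather than tethering at a defined length).
LINKER_LENGTH_NM: dict[str, float | None] = {
    "NH2-PEG-SH-5kDa": 50.0,
    "NH2-PEG-SH-1kDa": 10.0,
    "16-amino-1-hexadecanethiol": 2.5,
    "11-amino-1-undecanethiol": 1.7,
    "6-amino-1-hexanethiol": 0.9,
    "MDDA": None,
}

#: Gold concentrations of the six-step reflectance phantom ladder (mg/mL).
AU_CONCENTRATION_LADDER_MG_ML: tuple[float, ...] = (
    0.05, 0.10, 0.15, 0.20, 0.25, 0.30,
)

#: Laser-diode wavelengths of the reflectance rig (nm).
DR_WAVELENGTHS_NM: tuple[float, float] = (650.0, 780.0)
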