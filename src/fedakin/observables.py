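"""Assay models mapping chemical states to measured quantities and back.

Three bench assays are modelled:

* ferrozine Fe(II): absorbance of the Fe(II)(FZ)3 complex at 562 nm, with a
  correction for the small signal contributed by Fe(III);
* two-wavelength Beer-Lambert deconvolution of aminochrome (475 nm) and the
  Fe(III)-dopamine bis complex (580 nm);
* DPD/HRP hydrogen peroxide by linear calibration at 551 nm.

Measured molar absorptivities: aminochrome eps_475 = 3245 and eps_580 = 439
per M cm; Fe(III)DA2 eps_580 = 3121 per M cm; path length 10 cm.  The
Fe(III)DA2 absorptivity at 475 nm and the ferrozine-complex coefficients are
not part of that measured set and must be supplied by configuration (the
synthetic-data module ships documented fixture values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np

__all__ = [
    "SpectralSystem", "LinearCalibration", "AssayResult", "DegenerateAssayError",
    "fe2_from_ferrozine", "deconvolve_quinones", "forward_absorbance",
    "h2o2_from_dpd",
]


class DegenerateAssayError(ValueError):
    """Assay algebra is singular (equal absorptivities, zero slope, ...)."""


class AssayResult(NamedTuple):
    """Inverted concentration plus a flag set when clipping was applied."""

    value: float
    flagged: bool


@dataclass(frozen=True)
class SpectralSystem:
    """Molar absorptivities (per M cm) and cuvette path length (cm).

    ``eps_FeIIIDA2_475`` has no published value and is therefore required
    explicitly.  The ferrozine coefficients likewise come from configuration.
    """

    eps_FeIIIDA2_475: float
    path_length: float = 10.0
    eps_DAC_475: float = 3245.0
    eps_DAC_580: float = 439.0
    eps_FeIIIDA2_580: float = 3121.0
    eps_FeIIFZ_562_fromFeII: float | None = None
    eps_FeIIFZ_562_fromFeIII: float | None = None

    def __post_init__(self):
        if self.path_length <= 0:
            raise ValueError("path length must be positive")
        for name in ("eps_DAC_475", "eps_DAC_580",
                     "eps_FeIIIDA2_475", "eps_FeIIIDA2_580"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(np.linalg.det(self.matrix())) < 1e-12:
            raise DegenerateAssayError("475/580 nm deconvolution matrix is singular")

    def matrix(self) -> np.ndarray:
        """2x2 system A = M @ (C_DAC, C_FeIIIDA2) * l, rows = (475, 580)."""
        return np.array([
            [self.eps_DAC_475, self.eps_FeIIIDA2_475],
            [self.eps_DAC_580, self.eps_FeIIIDA2_580],
        ]) * self.path_length


@dataclass(frozen=True)
class LinearCalibration:
    """Absorbance = slope * concentration + intercept over ``valid_range``."""

    slope: float                      # absorbance per M
    intercept: float = 0.0
    valid_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self):
        if self.slope <= 0:
            raise DegenerateAssayError("calibration slope must be positive")


def fe2_from_ferrozine(A562: float, FeT: float, sys: SpectralSystem) -> AssayResult:
    """Invert the ferrozine assay for total Fe(II).

    [Fe(II)] = (A562 - eps_FeIII * FeT * l) / ((eps_FeII - eps_FeIII) * l),
    clipped to [0, FeT] with the flag set when clipping occurred.
    """
    if FeT < 0:
        raise ValueError("total iron must be >= 0")
    eII, eIII = sys.eps_FeIIFZ_562_fromFeII, sys.eps_FeIIFZ_562_fromFeIII
    if eII is None or eIII is None:
        raise DegenerateAssayError("ferrozine absorptivities are not configured")
    if eII == eIII:
        raise DegenerateAssayError("equal ferrozine absorptivities: assay degenerate")
    l = sys.path_length
    raw = (A562 - eIII * FeT * l) / ((eII - eIII) * l)
    clipped = min(max(raw, 0.0), FeT)
    return AssayResult(clipped, clipped != raw)


def forward_absorbance(state: Mapping[str, float], sys: SpectralSystem) -> tuple[float, float]:
    """Beer-Lambert absorbances (A475, A580) of a DAC + Fe(III)DA2 mixture."""
    c_dac = float(state.get("DAC", 0.0))
    c_fe = float(state.get("FeIIIDA2", 0.0))
    if c_dac < 0 or c_fe < 0:
        raise ValueError("concentrations must be >= 0")
    a = sys.matrix() @ np.array([c_dac, c_fe])
    return float(a[0]), float(a[1])


def deconvolve_quinones(A475: float, A580: float, sys: SpectralSystem,
                        method: str = "sequential") -> tuple[AssayResult, AssayResult]:
    """Solve the two-wavelength Beer-Lambert system for (DAC, Fe(III)DA2).

    ``method='sequential'`` follows the assay's measurement order: the bis
    complex is pivoted out of the 580 nm equation first (aminochrome's small
    580 nm absorptivity, 439 per M cm, entering through the elimination
    step), then aminochrome comes from the 475 nm residual.  This is exact
    Gaussian elimination, so it agrees with ``method='joint'`` (a dense
    linear solve) to rounding error.  Negative solutions are clipped to zero
    and flagged.
    """
    M = sys.matrix()
    if method == "joint":
        c_dac, c_fe = np.linalg.solve(M, np.array([A475, A580]))
    elif method == "sequential":
        # Pivot on the 580 row: express C_FeIIIDA2 from A580, substitute into
        # the 475 equation, solve for C_DAC, back-substitute.
        (e_dac_475, e_fe_475), (e_dac_580, e_fe_580) = M
        if e_fe_580 == 0:
            raise DegenerateAssayError("zero 580 nm absorptivity for Fe(III)DA2")
        denom = e_dac_475 - e_fe_475 * e_dac_580 / e_fe_580
        if denom == 0:
            raise DegenerateAssayError("deconvolution system is singular")
        c_dac = (A475 - e_fe_475 * A580 / e_fe_580) / denom
        c_fe = (A580 - e_dac_580 * c_dac) / e_fe_580
    else:
        raise ValueError(f"unknown method {method!r}")
    out = []
    for c in (c_dac, c_fe):
        clipped = max(float(c), 0.0)
        out.append(AssayResult(clipped, clipped != c))
    return out[0], out[1]


def h2o2_from_dpd(A551: float, cal: LinearCalibration) -> AssayResult:
    """Invert the DPD/HRP 551 nm line; flags extrapolation and clips negatives."""
    value = (A551 - cal.intercept) / cal.slope
    lo, hi = cal.valid_range
    flagged = not (lo <= value <= hi)
    if value < 0:
        return AssayResult(0.0, True)
    return AssayResult(float(value), flagged)


# --------------------------------------------------------------------------
# Observable channels: what each assay reads off the chemical state.
# Ferrozine responds to both inorganic and complexed Fe(II).

OBSERVABLE_SPECIES: dict[str, tuple[str, ...]] = {
    "FeII_ferrozine": ("FeII", "FeIIDA"),
    "H2O2": ("H2O2",),
    "DAC": ("DAC",),
    "FeIIIDA2": ("FeIIIDA2",),
}


def predict_observable(traj, name: str, times_s) -> np.ndarray:
    """Noise-free observable (molar) from a trajectory at given times."""
    if name not in OBSERVABLE_SPECIES:
        raise KeyError(f"unknown observable {name!r}")
    total = sum(traj[s] for s in OBSERVABLE_SPECIES[name])
    return np.interp(np.asarray(times_s, dtype=float), traj.times, total)
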