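"""Dispersive electrical properties of head tissues.

Each tissue carries tabulated conductivity and relative permittivity
over the stimulation band [50, 7500] Hz, interpolated log-linearly in
frequency.  The built-in table holds representative low-frequency
literature values for a five-tissue head (skin, skull, CSF, grey and
white matter); all values are overridable through the tissue-table CSV,
since published low-frequency dielectric data vary considerably between
sources.  The ischemic lesion is modelled as edema: conductivity fixed
at 1.7 S/m with the permittivity of grey matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

BAND_HZ = (50.0, 7500.0)
EDEMA_CONDUCTIVITY = 1.7  # S/m, frequency independent

# Canonical label assignment used by the layered-head generator.
AIR, SKIN, SKULL, CSF, GREY, WHITE, LESION = 0, 1, 2, 3, 4, 5, 6
LABEL_NAMES = {
    AIR: "air",
    SKIN: "skin",
    SKULL: "skull",
    CSF: "csf",
    GREY: "grey",
    WHITE: "white",
    LESION: "lesion",
}
NAME_LABELS = {v: k for k, v in LABEL_NAMES.items()}

__all__ = [
    "TissueProperties",
    "edema_properties",
    "default_tissue_table",
    "EPS0",
    "EDEMA_CONDUCTIVITY",
    "AIR",
    "SKIN",
    "SKULL",
    "CSF",
    "GREY",
    "WHITE",
    "LESION",
    "LABEL_NAMES",
    "NAME_LABELS",
]


@dataclass(frozen=True)
class TissueProperties:
    """Tabulated sigma(f) and eps_r(f) for one tissue."""

    name: str
    frequencies_hz: np.ndarray
    conductivity_S_per_m: np.ndarray
    relative_permittivity: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        s = np.asarray(self.conductivity_S_per_m, dtype=float)
        e = np.asarray(self.relative_permittivity, dtype=float)
        if not (len(f) == len(s) == len(e)) or len(f) < 1:
            raise ConfigurationError(f"{self.name}: mismatched property tables")
        if np.any(np.diff(f) <= 0):
            raise ConfigurationError(f"{self.name}: frequencies must increase")
        if np.any(s < 0):
            raise ConfigurationError(f"{self.name}: negative conductivity")
        if np.any(e < 0):
            raise ConfigurationError(f"{self.name}: negative permittivity")
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "conductivity_S_per_m", s)
        object.__setattr__(self, "relative_permittivity", e)

    def covers_band(self, f_min: float = BAND_HZ[0], f_max: float = BAND_HZ[1]) -> bool:
        return self.frequencies_hz[0] <= f_min and self.frequencies_hz[-1] >= f_max

    def _interp(self, table: np.ndarray, frequency_hz: float) -> float:
        # Log-linear: linear in log(f); constant extrapolation at the
        # ends (and below the table, covering the omega -> 0 limit).
        f = max(float(frequency_hz), self.frequencies_hz[0])
        return float(
            np.interp(np.log(f), np.log(self.frequencies_hz), table)
        )

    def sigma_at(self, frequency_hz: float) -> float:
        """Conductivity (S/m) at a frequency, log-linear interpolation."""
        return self._interp(self.conductivity_S_per_m, frequency_hz)

    def eps_r_at(self, frequency_hz: float) -> float:
        """Relative permittivity at a frequency, log-linear interpolation."""
        return self._interp(self.relative_permittivity, frequency_hz)

    def complex_conductivity(self, frequency_hz: float,
                             include_displacement: bool = True) -> complex:
        """sigma* = sigma + j 2 pi f eps0 eps_r at a frequency."""
        sigma = self.sigma_at(frequency_hz)
        if not include_displacement:
            return complex(sigma, 0.0)
        omega = 2.0 * np.pi * frequency_hz
        return complex(sigma, omega * EPS0 * self.eps_r_at(frequency_hz))


def edema_properties(grey_matter: TissueProperties) -> TissueProperties:
    """Edema: sigma = 1.7 S/m at all frequencies, eps_r of grey matter."""
    if not grey_matter.covers_band():
        raise ConfigurationError("grey-matter table does not cover the band")
    return TissueProperties(
        name="lesion",
        frequencies_hz=grey_matter.frequencies_hz.copy(),
        conductivity_S_per_m=np.full_like(
            grey_matter.conductivity_S_per_m, EDEMA_CONDUCTIVITY
        ),
        relative_permittivity=grey_matter.relative_permittivity.copy(),
    )


def _log_spaced_table(name, sigma_lo, sigma_hi, eps_lo, eps_hi, n=8):
    f = np.geomspace(BAND_HZ[0], BAND_HZ[1], n)
    sigma = np.geomspace(sigma_lo, sigma_hi, n) if sigma_lo != sigma_hi \
        else np.full(n, sigma_lo)
    eps = np.geomspace(eps_lo, eps_hi, n) if eps_lo != eps_hi \
        else np.full(n, eps_lo)
    return TissueProperties(name, f, sigma, eps)


def default_tissue_table() -> dict:
    """Built-in five-tissue table plus edema, keyed by label id.

    Values are representative of the low-frequency dielectric
    literature for these tissues over [50, 7500] Hz; permittivities are
    large at these frequencies but contribute only a modest
    displacement-current correction (kept via the complex
    conductivity).
    """
    grey = _log_spaced_table("grey", 0.075, 0.105, 4.0e6, 7.0e4)
    table = {
        SKIN: _log_spaced_table("skin", 0.10, 0.10, 1.1e6, 2.0e4),
        SKULL: _log_spaced_table("skull", 0.020, 0.021, 5.5e3, 1.2e3),
        CSF: _log_spaced_table("csf", 2.0, 2.0, 109.0, 109.0),
        GREY: grey,
        WHITE: _log_spaced_table("white", 0.053, 0.078, 2.2e6, 4.5e4),
        LESION: edema_properties(grey),
    }
    return table


def max_displacement_ratio(table: dict, frequencies_hz) -> float:
    """max over tissues and frequencies of (omega eps0 eps_r) / sigma.

    Diagnostic for the quasistatic assumption: well below 1 means
    conduction dominates displacement currents.
    """
    worst = 0.0
    for props in table.values():
        for f in np.atleast_1d(frequencies_hz):
            sigma = props.sigma_at(f)
            if sigma <= 0:
                continue
            ratio = 2.0 * np.pi * f * EPS0 * props.eps_r_at(f) / sigma
            worst = max(worst, ratio)
    return worst
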