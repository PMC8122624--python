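"""Frequency-band registry shared by all spectral and connectivity features."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"bad band {self.name}: [{self.f_lo}, {self.f_hi})")

    def frequencies(self, step: float = 1.0):
        """1-Hz grid over the half-open band interval [f_lo, f_hi)."""
        import numpy as np

        return np.arange(self.f_lo, self.f_hi, step)


#: The eight band-power features.
POWER_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("low_beta", 13.0, 20.0),
    BandDefinition("high_beta", 20.0, 30.0),
    BandDefinition("low_gamma", 30.0, 45.0),
    BandDefinition("gamma", 60.0, 90.0),
    BandDefinition("high_gamma", 100.0, 200.0),
)

BAND_REGISTRY: dict[str, BandDefinition] = {b.name: b for b in POWER_BANDS}

#: Phase-amplitude coupling bands: theta-range phase, high-gamma-range amplitude.
PAC_PHASE_BAND = BandDefinition("pac_phase", 3.0, 7.0)
PAC_AMP_BAND = BandDefinition("pac_amplitude", 70.0, 130.0)

#: Instantaneous-amplitude band (delta) and instantaneous-frequency band.
IA_BAND = BAND_REGISTRY["delta"]
IF_BAND = BandDefinition("theta_alpha", 4.0, 14.0)

#: Bands used for the directed (PDC) and phase-locking (PLI) connectivity
#: features; "beta" maps to the low-beta band.
CONNECTIVITY_BANDS = ("delta", "theta", "alpha", "low_beta")


def get_band(name: str) -> BandDefinition:
    try:
        return BAND_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; registered: {sorted(BAND_REGISTRY)}"
        ) from None
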