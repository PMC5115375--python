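"""Dual-channel fluorescence readout and threshold decoding.

FAM reports beacon opening (1.0 open, a small residual leak closed); NMM
reports G-quadruplex assembly, normalized so 1.0 equals one quadruplex
equivalent -- a state assembling two quadruplexes reads 2.0. Bits are
decoded against a fixed threshold of 0.4 shared by every circuit, under
either the positive convention (high signal = 1) or the negative one
(inverted). Normalization is structural (counts), not fitted to spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import SystemState

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ChannelReadout:
    """Normalized FAM and NMM intensities for one resolved state."""

    fam_norm: float
    nmm_norm: float


@dataclass(frozen=True)
class DecodeConfig:
    threshold: float = 0.4
    strict: bool = True  # bit = 1 iff intensity strictly above threshold
    convention: str = POSITIVE

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.convention not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown convention {self.convention!r}")


@dataclass(frozen=True)
class NoiseConfig:
    """Multiplicative Gaussian noise emulating replicate fluorescence reads."""

    fam_leak: float = 0.10
    sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


DEFAULT_FAM_LEAK = 0.10


def channel_intensities(
    state: SystemState,
    noise_config: NoiseConfig | None = None,
    fam_leak: float = DEFAULT_FAM_LEAK,
    rng: np.random.Generator | None = None,
) -> ChannelReadout:
    """Map a resolved state to normalized (FAM, NMM) intensities.

    Noiseless (default): FAM is 1.0 when the beacon is open, else the leak
    fraction; NMM equals the integer quadruplex count. When ``noise_config``
    is given, both channels are perturbed multiplicatively (seeded) and
    clipped at zero.
    """
    if noise_config is not None:
        fam_leak = noise_config.fam_leak
    fam = 1.0 if state.beacon_open else fam_leak
    nmm = float(state.g4_count)
    if noise_config is not None and noise_config.sd > 0:
        if rng is None:
            rng = np.random.default_rng(noise_config.seed)
        factors = 1.0 + noise_config.sd * rng.standard_normal(2)
        fam = max(0.0, fam * factors[0])
        nmm = max(0.0, nmm * factors[1])
    return ChannelReadout(fam_norm=fam, nmm_norm=nmm)


def decode_bit(intensity: float, config: DecodeConfig = DecodeConfig()) -> int:
    """Threshold an intensity into a bit under the configured convention."""
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if config.strict:
        high = intensity > config.threshold
    else:
        high = intensity >= config.threshold
    bit = int(high)
    if config.convention == NEGATIVE:
        bit = 1 - bit
    return bit


def is_ambiguous(intensity: float, config: DecodeConfig = DecodeConfig()) -> bool:
    """Flag an intensity sitting exactly at the threshold (non-strict mode)."""
    return (not config.strict) and intensity == config.threshold


def decode_margin(intensity: float, config: DecodeConfig = DecodeConfig()) -> float:
    """Distance of an intensity from the decision threshold."""
    return abs(intensity - config.threshold)
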