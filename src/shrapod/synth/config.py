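"""Configuration for the synthetic ultrasound phantom generator."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


def _default_echogenicity() -> dict[str, float]:
    # Mean linear echo amplitudes per tissue class, before speckle and
    # log compression (arbitrary units in [0, ~1.5]).
    return {
        "fat": 0.55,
        "muscle": 0.38,
        "bone": 0.95,
        "vessel_lumen": 0.03,
        "artery_rim": 0.85,
        "vein_rim": 0.60,
        "nerve": 0.33,
        "shrapnel": 1.50,
    }


@dataclass
class PhantomConfig:
    """Geometry, echogenicity and noise model of the simulated phantom.

    The phantom emulates a transverse (out-of-plane) ultrasound view of
    a two-layer fat/muscle thigh phantom with a bone, a circular artery
    (8 mm), an oval vein (6.5 mm minor axis), a nerve bundle lateral to
    the artery, and optionally a bright metallic shrapnel rod (2.5 mm
    diameter, 2-10 mm length).

    ``px_per_mm`` fixes the pixel scale; the default 9.4 px/mm makes the
    8 mm artery span ~75 px, the reference size used by the triage gate.
    """

    image_size: int = 512
    px_per_mm: float = 9.4
    shrapnel_prob: float = 0.6
    shrapnel_len_mm: tuple[float, float] = (2.0, 10.0)
    shrapnel_diam_mm: float = 2.5
    artery_diam_mm: float = 8.0
    vein_minor_mm: float = 6.5
    nerve_diam_mm: float = 6.5
    bone_diam_mm: float = 26.0
    layer_boundary_frac: float = 0.30
    echogenicity: dict[str, float] = field(default_factory=_default_echogenicity)
    #: Multiplicative speckle contrast (Rayleigh-like); 0 disables noise.
    speckle_scale: float = 1.0
    #: Gain of the log compression applied to the echo amplitude.
    log_gain: float = 60.0
    #: Retries when placing shrapnel clear of the neurovascular bundle.
    max_placement_retries: int = 50
    #: Cast shadow below the shrapnel rod (off: not part of the baseline
    #: appearance model).
    shrapnel_shadow: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "image_size": self.image_size,
            "px_per_mm": self.px_per_mm,
            "shrapnel_diam_mm": self.shrapnel_diam_mm,
            "artery_diam_mm": self.artery_diam_mm,
            "vein_minor_mm": self.vein_minor_mm,
            "nerve_diam_mm": self.nerve_diam_mm,
            "bone_diam_mm": self.bone_diam_mm,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        lo, hi = self.shrapnel_len_mm
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid shrapnel length range {self.shrapnel_len_mm}")
        if not 0.0 <= self.shrapnel_prob <= 1.0:
            raise ValueError("shrapnel_prob must lie in [0, 1]")
        if not 0.0 < self.layer_boundary_frac < 1.0:
            raise ValueError("layer_boundary_frac must lie in (0, 1)")
        if self.px_per_mm * self.artery_diam_mm >= self.image_size:
            raise ValueError("artery does not fit in the frame at this pixel scale")

    def mm(self, millimetres: float) -> float:
        """Convert a physical length to pixels."""
        return millimetres * self.px_per_mm

    def with_(self, **kwargs) -> "PhantomConfig":
        return replace(self, **kwargs)

    @classmethod
    def desk(cls, **kwargs) -> "PhantomConfig":
        """Reduced 256 px profile (half pixel scale) for CPU-scale runs."""
        defaults = dict(image_size=256, px_per_mm=4.7)
        defaults.update(kwargs)
        return cls(**defaults)
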