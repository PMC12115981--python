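"""Built-in reference data: measured peak-voltage tables and the
reference virtual board used throughout the test-bench runs.

The two peak-voltage tables are A-scan decode results from real pine
boards: eight sound-wood points on the front faces, and eleven points
on the back faces including one knot and two pits.  They anchor the
classifier calibration (sound wood clusters tightly near 0.64 V; a knot
drops to 0.282 V; pits rise to ~0.85 V).
"""

from __future__ import annotations

from dataclasses import dataclass

from .channel import DefectRegion, Medium, Specimen

__all__ = ["Fixture", "table_fixtures", "reference_specimen",
           "comparison_specimen"]


@dataclass(frozen=True)
class Fixture:
    """Named list of (label, peak voltage in volts) measurements."""

    name: str
    points: tuple

    def __post_init__(self):
        for label, v in self.points:
            if v <= 0:
                raise ValueError("peak voltages must be positive")
            if label not in ("sound", "knot", "pit"):
                raise ValueError(f"unknown label {label!r}")

    @property
    def voltages(self) -> tuple:
        return tuple(v for _, v in self.points)


_TABLE1 = (0.651, 0.636, 0.641, 0.637, 0.654, 0.639, 0.651, 0.648)
_TABLE2_SOUND = (0.648, 0.651, 0.647, 0.646, 0.643, 0.641, 0.648, 0.656)
_TABLE2_DEFECTS = (("knot", 0.282), ("pit", 0.845), ("pit", 0.857))


def table_fixtures() -> list[Fixture]:
    """The two measured peak-voltage tables.

    ``front-sound-8`` holds the eight front-face sound points;
    ``back-11`` holds eight back-face sound points plus Knot A
    (0.282 V), Pit A (0.845 V) and Pit B (0.857 V).
    """
    t1 = Fixture(
        name="front-sound-8",
        points=tuple(("sound", v) for v in _TABLE1),
    )
    t2 = Fixture(
        name="back-11",
        points=tuple(("sound", v) for v in _TABLE2_SOUND)
        + _TABLE2_DEFECTS,
    )
    return [t1, t2]


def reference_specimen() -> Specimen:
    """The reference two-defect virtual board.

    A 6 cm × 6 cm, 1 cm thick pine board carrying one circular knot
    (radius 8 mm, impedance ×2, 6 dB scattering loss) centered at
    (1.8 cm, 1.8 cm) and one circular pit (radius 6 mm, local thickness
    60% of nominal) centered at (4.2 cm, 4.2 cm).  Deterministic; all
    acceptance-style runs image this board.
    """
    knot = DefectRegion(
        shape="circle",
        center=(0.018, 0.018),
        size=0.008,
        label="knot",
        impedance_multiplier=2.0,
        scatter_loss_db=6.0,
    )
    pit = DefectRegion(
        shape="circle",
        center=(0.042, 0.042),
        size=0.006,
        label="pit",
        thickness_fraction=0.6,
    )
    return Specimen(
        nominal_thickness=0.01,
        width=0.06,
        height=0.06,
        defects=(knot, pit),
    )


def comparison_specimen() -> Specimen:
    """The thicker, more attenuating board for method comparisons.

    Same lateral geometry and defects as :func:`reference_specimen`
    but 1.5 cm thick with attenuation raised to 700 dB/m at 75 kHz —
    a penetration-limited regime in which a coded excitation with
    compression gain still images the board while a short uncoded
    pulse of the same drive voltage becomes noise-limited.
    """
    ref = reference_specimen()
    base = Medium(
        impedance=ref.base.impedance,
        sound_speed=ref.base.sound_speed,
        attenuation_coeff=700.0,
        attenuation_exponent=ref.base.attenuation_exponent,
    )
    return Specimen(
        nominal_thickness=0.015,
        width=ref.width,
        height=ref.height,
        base=base,
        defects=ref.defects,
    )
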