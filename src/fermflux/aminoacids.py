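"""Nitrogen-source reference table.

Yeast assimilable nitrogen (YAN) comprises ammonium and 18 amino acids;
proline is excluded because it is not catabolised anaerobically. Each entry
records the number of nitrogen atoms per molecule (``nn``) and the molecular
weight (``mw``, g/mol), which convert mass-based uptake rates into a
nitrogen-equivalent growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass

#: molar mass of atomic nitrogen (g/mol), the prefactor of the
#: nitrogen-equivalent growth-rate sum.
NITROGEN_MW = 14.0067


@dataclass(frozen=True)
class AminoAcidSpec:
    """Nitrogen content of one assimilable nitrogen source."""

    name: str
    nn: int  # nitrogen atoms per molecule
    mw: float  # molecular weight, g/mol

    def __post_init__(self) -> None:
        if self.nn < 1:
            raise ValueError(f"{self.name}: nn must be >= 1, got {self.nn}")
        if self.mw <= 0:
            raise ValueError(f"{self.name}: mw must be > 0, got {self.mw}")

    @property
    def nitrogen_fraction(self) -> float:
        """Mass fraction of nitrogen, NITROGEN_MW * nn / mw."""
        return NITROGEN_MW * self.nn / self.mw


#: the 18 assimilated amino acids, in canonical state-vector order.
AMINO_ACIDS = (
    AminoAcidSpec("Ala", 1, 89.09),
    AminoAcidSpec("Arg", 4, 174.2),
    AminoAcidSpec("Asp", 1, 133.10),
    AminoAcidSpec("Cys", 1, 121.16),
    AminoAcidSpec("Glu", 1, 147.13),
    AminoAcidSpec("Gln", 2, 146.15),
    AminoAcidSpec("Gly", 1, 75.07),
    AminoAcidSpec("His", 3, 155.15),
    AminoAcidSpec("Ile", 1, 131.17),
    AminoAcidSpec("Leu", 1, 131.17),
    AminoAcidSpec("Lys", 2, 146.19),
    AminoAcidSpec("Met", 1, 149.21),
    AminoAcidSpec("Phe", 1, 165.19),
    AminoAcidSpec("Ser", 1, 105.09),
    AminoAcidSpec("Thr", 1, 119.12),
    AminoAcidSpec("Tyr", 1, 181.19),
    AminoAcidSpec("Trp", 2, 204.23),
    AminoAcidSpec("Val", 1, 117.15),
)

#: ammonium is supplied as NH4Cl in synthetic must.
AMMONIUM = AminoAcidSpec("NH4Cl", 1, 53.49)

NITROGEN_SOURCES = {spec.name: spec for spec in AMINO_ACIDS + (AMMONIUM,)}

AMINO_ACID_NAMES = tuple(spec.name for spec in AMINO_ACIDS)


def nitrogen_spec(name: str) -> AminoAcidSpec:
    """Look up a nitrogen source by name; raises KeyError for unknown keys."""
    try:
        return NITROGEN_SOURCES[name]
    except KeyError:
        raise KeyError(
            f"unknown nitrogen source {name!r}; known: {sorted(NITROGEN_SOURCES)}"
        ) from None
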