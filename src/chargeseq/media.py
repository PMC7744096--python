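"""Amino-acid concentrations in culture media.

Amino-acid-limitation experiments are phrased as fractions of the standard
high-glucose DMEM formulation ("5% AA" = every amino acid at 5% of its
standard concentration).  This helper recomputes molar concentrations from
the published mg/L formulation and molar masses of the supplied salts, so
statements like "5% AA supplies 200 uM glutamine and 10 uM methionine"
are derived rather than hard-coded.
"""

from __future__ import annotations

# Standard high-glucose DMEM amino acids: (mg/L, molar mass g/mol of the
# form supplied).  Salt/hydrate forms follow the catalog formulation
# (e.g. L-arginine hydrochloride, L-tyrosine disodium dihydrate).
DMEM_FORMULATION: dict[str, tuple[float, float]] = {
    "Gly": (30.0, 75.07),
    "Arg": (84.0, 210.66),   # L-arginine·HCl
    "Cys2": (63.0, 313.22),  # L-cystine·2HCl
    "Gln": (584.0, 146.15),
    "His": (42.0, 209.63),   # L-histidine·HCl·H2O
    "Ile": (105.0, 131.17),
    "Leu": (105.0, 131.17),
    "Lys": (146.0, 182.65),  # L-lysine·HCl
    "Met": (30.0, 149.21),
    "Phe": (66.0, 165.19),
    "Ser": (42.0, 105.09),
    "Thr": (95.0, 119.12),
    "Trp": (16.0, 204.23),
    "Tyr": (104.0, 261.25),  # L-tyrosine·2Na·2H2O
    "Val": (94.0, 117.15),
}


class MediaError(KeyError):
    pass


def amino_acid_concentration_um(amino_acid: str, fraction: float = 1.0) -> float:
    """Concentration (uM) of an amino acid in DMEM scaled to ``fraction``.

    ``fraction=1.0`` is the standard formulation; ``fraction=0.05`` is the
    "5% AA" medium.  Concentration = mg/L / molar mass * 1000 * fraction.
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    try:
        mg_per_l, mw = DMEM_FORMULATION[amino_acid]
    except KeyError:
        raise MediaError(
            f"{amino_acid!r} not in the DMEM formulation table"
        ) from None
    return mg_per_l / mw * 1000.0 * fraction


def formulation_table(fraction: float = 1.0) -> dict[str, float]:
    """All amino-acid concentrations (uM) at the given fraction of DMEM."""
    return {
        aa: amino_acid_concentration_um(aa, fraction) for aa in DMEM_FORMULATION
    }
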