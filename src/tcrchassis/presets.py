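"""Residue-selection presets for the B7 TCR–Tax/HLA-A2 system.

All residue numbers refer to the *sequentially renumbered* structure
(1..N per chain, insertion codes collapsed), matching how selections
for this system are conventionally quoted: β-sheet triad cores of the
variable domains, constant-domain cores and hinge residues for the BOC,
CDR3 base residues, the MHC β-sheet floor strands, and the terminal
restraint residues with their extension settings.

Chain identifiers default to the crystal-structure layout of PDB entry
1BD2 (A = MHC heavy chain, B = β2-microglobulin, C = Tax peptide,
D = TCRα, E = TCRβ) and can be remapped for differently labelled files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .system import DomainMap, SelectionSpec

__all__ = ["B7Preset", "b7_preset", "EXTENSION_SETTINGS_A", "LOADS_PN", "SAVING_INTERVAL_NS", "ANALYSIS_INTERVAL_NS"]

#: Extension settings (Å) between the terminal restraint potentials.
EXTENSION_SETTINGS_A = {"none": None, "low": 173.7, "high": 190.0}

#: Mean applied loads (pN) over the 500–1000 ns analysis interval.
LOADS_PN = {"low": 9.01, "high": 14.5}

#: Coordinate saving interval (ns) of the production runs.
SAVING_INTERVAL_NS = 0.02

#: Standard averaging interval (ns).
ANALYSIS_INTERVAL_NS = (500.0, 1000.0)


@dataclass
class B7Preset:
    """Named selections and restraint bookkeeping for the B7 system."""

    mhc_chain: str = "A"
    b2m_chain: str = "B"
    peptide_chain: str = "C"
    alpha_chain: str = "D"
    beta_chain: str = "E"
    selections: dict = field(default_factory=dict)
    restrained_residues: dict = field(default_factory=dict)
    spring_constant: float = 1.0
    extensions: dict = field(default_factory=lambda: dict(EXTENSION_SETTINGS_A))
    loads: dict = field(default_factory=lambda: dict(LOADS_PN))

    def extension_difference(self, high: str = "high", low: str = "low") -> float:
        """Difference (Å) between two extension settings, e.g. 16.3 Å
        between the high- and low-load simulations."""
        return round(self.extensions[high] - self.extensions[low], 6)


def b7_preset(
    mhc_chain: str = "A",
    b2m_chain: str = "B",
    peptide_chain: str = "C",
    alpha_chain: str = "D",
    beta_chain: str = "E",
) -> B7Preset:
    """Build the B7 selection preset (renumbered residue numbering)."""
    a, b, m, p = alpha_chain, beta_chain, mhc_chain, peptide_chain
    sel = {
        # β-sheet cores of the variable domains (triad assignment)
        "Valpha": SelectionSpec("Valpha", a, ((19, 24), (32, 37), (71, 76), (87, 92)), "CA"),
        "Vbeta": SelectionSpec("Vbeta", b, ((20, 25), (32, 37), (73, 78), (89, 94)), "CA"),
        # constant-domain cores (BOC beads)
        "Calpha": SelectionSpec("Calpha", a, ((118, 123), (132, 137), (153, 158), (171, 176)), "CA"),
        "Cbeta": SelectionSpec("Cbeta", b, ((143, 148), (157, 162), (190, 195), (208, 213)), "CA"),
        # hinge residues
        "Halpha": SelectionSpec("Halpha", a, (114,), "CA"),
        "Hbeta": SelectionSpec("Hbeta", b, (116, 117), "CA"),
        # CDR3 base residues (E93/K97 on α, S94/E102 on β)
        "cdr3_alpha": SelectionSpec("cdr3_alpha", a, (93, 97), "CA"),
        "cdr3_beta": SelectionSpec("cdr3_beta", b, (94, 102), "CA"),
        # central four strands of the MHC β-sheet floor (5 Cα each)
        "mhc_floor": SelectionSpec("mhc_floor", m, ((6, 10), (23, 27), (96, 100), (113, 117)), "CA"),
    }
    restrained = {
        "mhc": (m, 284),    # I284
        "tcr_alpha": (a, 218),  # T218
        "tcr_beta": (b, 259),   # A259
    }
    return B7Preset(
        mhc_chain=m, b2m_chain=b2m_chain, peptide_chain=p,
        alpha_chain=a, beta_chain=b,
        selections=sel, restrained_residues=restrained,
    )
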