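"""Built-in definitions for the TIR1 auxin receptor.

The pocket of TIR1 (PDB 2P1M, the unbound structure; the ligand-bound forms
are 2P1P/2P1Q) is lined by 43-44 residues in seven non-sequential
leucine-rich-repeat loop segments.  Phe-351 sits at the pocket mouth and
Arg-403 at the bottom; their separation defines the pocket depth
(about 16.5 Å).  The engagement niche and the selectivity-filter residue
sets are the ones implicated in the descent mechanism of active auxins.

These presets assume the crystallographic chain naming of the 2P1M entry
(TIR1 is chain B; the co-expressed adaptor ASK1, chain A, is excised during
preparation and waters are stripped; the structural cofactor InsP6 is kept).
"""

from __future__ import annotations

from .analysis import NicheDefinition
from .geometry import PocketDefinition
from .structures import ResidueRef, Structure

__all__ = [
    "TIR1_LINING_RANGES",
    "tir1_pocket_definition",
    "tir1_niche_definition",
    "TIR1_FILTER_RESIDUES",
    "find_tir1_chain",
]

#: the seven contiguous residue ranges lining the TIR1 pocket
TIR1_LINING_RANGES = [
    (77, 84),
    (344, 354),
    (377, 381),
    (403, 410),
    (436, 441),
    (462, 465),
    (489, 490),
]

#: engagement-niche residues (back wall of the pocket, near the mouth)
TIR1_NICHE_RESIDUES = [
    ("LYS", 410),
    ("SER", 440),
    ("GLY", 441),
    ("ALA", 464),
    ("PHE", 465),
]

#: the selectivity-filter residue set
TIR1_FILTER_RESIDUES = [
    ("CYS", 405),
    ("SER", 438),
    ("LEU", 439),
    ("SER", 462),
    ("ARG", 489),
]


def tir1_pocket_definition(chain: str = "B") -> PocketDefinition:
    """Pocket definition for TIR1: seven lining ranges, Phe-351 mouth,
    Arg-403 bottom."""
    return PocketDefinition(
        lining_ranges=[(chain, lo, hi) for lo, hi in TIR1_LINING_RANGES],
        mouth_ref=ResidueRef(chain, 351, "PHE"),
        bottom_ref=ResidueRef(chain, 403, "ARG"),
    )


def tir1_niche_definition(chain: str = "B",
                          engagement_cutoff: float = 4.0) -> NicheDefinition:
    return NicheDefinition(
        residues=[ResidueRef(chain, seq, name)
                  for name, seq in TIR1_NICHE_RESIDUES],
        engagement_cutoff=engagement_cutoff,
    )


def find_tir1_chain(receptor: Structure) -> str:
    """Identify the TIR1 chain as the one carrying Phe-351 and Arg-403."""
    chains = sorted({a.chain for a in receptor.atoms})
    for chain in chains:
        try:
            ResidueRef(chain, 351, "PHE").resolve(receptor)
            ResidueRef(chain, 403, "ARG").resolve(receptor)
            return chain
        except KeyError:
            continue
    raise KeyError(
        "no chain carries both Phe-351 and Arg-403; is this a TIR1 structure?"
    )
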