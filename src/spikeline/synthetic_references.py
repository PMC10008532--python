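"""Synthetic stand-in 16S reference fragments for the default mock community.

The default spike-in pair is *Imtechella halotolerans* (gram-negative,
6.0e7 16S copies per manufacturer dose from 2e7 cells) and *Allobacillus
halotolerans* (gram-positive, 1.4e8 copies per dose from 2e7 cells).

The sequences below are SYNTHETIC: deterministic, uniformly random ~253 nt
V4-length fragments generated from a fixed seed, not the GenBank records of
the real taxa. Every operation in this package compares SVs against
whichever reference sequences it is given, so internally consistent
stand-ins are sufficient for simulation and testing; users analysing real
data should supply the published reference sequences as a FASTA file.
"""

from __future__ import annotations

import numpy as np

from .model import MCReference

__all__ = [
    "IH_COPIES_PER_DOSE",
    "AH_COPIES_PER_DOSE",
    "CELLS_PER_DOSE",
    "default_references",
    "synthetic_fragment",
]

# Manufacturer-stated composition of one 20 µl dose of the spike-in control.
IH_COPIES_PER_DOSE = 6.0e7
AH_COPIES_PER_DOSE = 1.4e8
CELLS_PER_DOSE = 2.0e7

_BASES = np.array(list("ACGT"))


def synthetic_fragment(seed: int, length: int = 253) -> str:
    """Deterministic uniform-random nucleotide fragment (synthetic stand-in)."""
    rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def default_references() -> list[MCReference]:
    """The default mock-community pair with synthetic stand-in sequences."""
    return [
        MCReference(
            name="Imtechella halotolerans",
            gram="negative",
            sequence=synthetic_fragment(11_711_81),
            copies_per_dose=IH_COPIES_PER_DOSE,
            cells_per_dose=CELLS_PER_DOSE,
        ),
        MCReference(
            name="Allobacillus halotolerans",
            gram="positive",
            sequence=synthetic_fragment(11_660_71),
            copies_per_dose=AH_COPIES_PER_DOSE,
            cells_per_dose=CELLS_PER_DOSE,
        ),
    ]
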