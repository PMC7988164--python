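"""Monoisotopic mass constants shared across the package.

Residue masses are taken from pyteomics (Unimod/IUPAC monoisotopic values);
everything downstream (precursor m/z, fragment ladders, glycan additions)
is plain additive arithmetic on top of these.
"""

from pyteomics import mass as _pmass

#: Monoisotopic residue masses for the 20 standard amino acids, Da.
RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

#: Monoisotopic mass of water, Da (peptide termini).
WATER = 18.0105646863

#: Mass of a proton, Da (charge carrier in positive-mode ESI).
PROTON = 1.007276

#: Immonium ion offset: residue mass - CO + H - H2 ... empirically
#: immonium m/z = residue mass - 26.98763 (loss of CO, gain of H, minus e).
IMMONIUM_OFFSET = -26.98763

#: Carbon monoxide, Da (b -> a ion conversion).
CO = 27.99491

#: Neutral-loss masses, Da.
LOSS_SO3 = 79.95682
LOSS_CO2 = 43.98983

#: Monoisotopic residue masses of common monosaccharides, Da
#: (mass added when the residue condenses onto a glycan/peptide).
MONOSACCHARIDE_MASS: dict[str, float] = {
    "Hex": 162.05282,     # hexose (Glc/Gal/Man)
    "HexNAc": 203.07937,  # N-acetylhexosamine (GlcNAc/GalNAc)
    "Fuc": 146.05791,     # deoxyhexose / fucose
    "NeuAc": 291.09542,   # N-acetylneuraminic acid (human sialic acid)
    "NeuGc": 307.09033,   # N-glycolylneuraminic acid (non-human sialic acid)
    "Xyl": 132.04226,     # pentose / xylose
}

#: Order in which monosaccharides are re-attached when generating
#: glycopeptide Y ions: the core HexNAc is retained closest to the peptide,
#: then Hex, then the distal residues.
Y_ION_ATTACH_ORDER = ("HexNAc", "Hex", "NeuAc", "NeuGc", "Fuc", "Xyl")
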