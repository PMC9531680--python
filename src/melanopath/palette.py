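"""Tissue-class codes and fixed color palettes.

Class codes index both segmentation masks and the indexed-PNG palette used on
disk.  Render colors are the fixed synthetic-stain palette: an H&E-like look
(purple nuclei, pink stroma) and the SOX10-like red-brown used by the virtual
staining oracle.
"""

from __future__ import annotations

# segmentation class codes (indexed-PNG palette order)
UL, BG, COR, EP, DE, DMN, EPN = 0, 1, 2, 3, 4, 5, 6

CLASS_NAMES = {UL: "UL", BG: "BG", COR: "COR", EP: "EP", DE: "DE",
               DMN: "DMN", EPN: "EPN"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}
N_CLASSES = 7

# mask visualization palette (one RGB triple per class code)
MASK_PALETTE: dict[int, tuple[int, int, int]] = {
    UL: (0, 0, 0),
    BG: (128, 128, 128),
    COR: (255, 192, 203),
    EP: (0, 0, 255),
    DE: (255, 255, 0),
    DMN: (144, 238, 144),
    EPN: (0, 100, 0),
}

# synthetic H&E render colors
TISSUE_COLORS: dict[int, tuple[int, int, int]] = {
    BG: (245, 245, 245),
    COR: (241, 203, 212),
    EP: (203, 153, 201),
    DE: (231, 172, 188),
    DMN: (147, 108, 178),
    EPN: (124, 92, 163),
}
MELANOCYTE_COLOR = (82, 44, 148)     # distinct blue-purple nucleus
MITOSIS_COLOR = (60, 38, 82)         # dark hyperchromatic base
NORMAL_NUCLEUS_COLOR = (152, 104, 158)

# deterministic SOX10-like recolor target
SOX10_COLOR = (150, 60, 30)
FILL_WHITE = (255, 255, 255)
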