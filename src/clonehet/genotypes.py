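"""Diploid genotype classes shared across the package.

All genotype calls are reduced to five classes relative to a reference
genome: homozygous reference (REF), heterozygous (HET), homozygous
alternative (ALT), anything else that is still a diploid call (OTHER,
e.g. two distinct non-reference alleles), and no-call (MISSING).
Internally a genotype matrix stores the classes as small integer codes.
"""

from __future__ import annotations

import numpy as np

REF = "REF"
HET = "HET"
ALT = "ALT"
OTHER = "OTHER"
MISSING = "MISSING"

#: Canonical class order; the integer code of a class is its index here.
CLASSES: tuple[str, ...] = (REF, HET, ALT, OTHER, MISSING)

CODE: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}
NAMES: np.ndarray = np.array(CLASSES, dtype=object)


def to_codes(values) -> np.ndarray:
    """Map an array-like of class names to int8 codes."""
    arr = np.asarray(values, dtype=object)
    out = np.empty(arr.shape, dtype=np.int8)
    flat_in, flat_out = arr.ravel(), out.ravel()
    for i, v in enumerate(flat_in):
        try:
            flat_out[i] = CODE[v]
        except KeyError:
            raise ValueError(f"unknown genotype class {v!r}") from None
    return out


def to_names(codes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_codes`."""
    return NAMES[np.asarray(codes, dtype=np.int64)]
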