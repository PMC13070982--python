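"""Methyl labelling schemes.

A labelling scheme declares which methyl groups of which residue types are
[1H,13C]-labelled (hence NMR-visible) in an otherwise deuterated protein.
Ile contributes only the delta-1 methyl, Met the epsilon, Ala the beta and
Thr the gamma-2 methyl; Leu and Val carry two prochiral methyls of which a
stereospecific precursor labels exactly one (proS: Leu delta-2 / Val
gamma-2; proR: Leu delta-1 / Val gamma-1) while non-stereospecific
labelling activates both.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum


class Stereo(str, Enum):
    """Prochiral selection for the two Leu/Val methyls."""

    PROS = "proS"
    PROR = "proR"
    NONSTEREO = "nonstereo"


#: methyl carbon atom names per residue (PDB nomenclature), in (proR, proS)
#: order for the prochiral pairs.
METHYL_ATOMS: dict[str, tuple[str, ...]] = {
    "M": ("CE",),
    "I": ("CD1",),
    "L": ("CD1", "CD2"),  # delta1 (proR), delta2 (proS)
    "V": ("CG1", "CG2"),  # gamma1 (proR), gamma2 (proS)
    "A": ("CB",),
    "T": ("CG2",),
}

THREE_TO_ONE = {
    "MET": "M",
    "ILE": "I",
    "LEU": "L",
    "VAL": "V",
    "ALA": "A",
    "THR": "T",
}

#: Greek-letter style position names for the methyl carbons, for labels.
ATOM_POSITION = {
    "CE": "e",
    "CD1": "d1",
    "CD2": "d2",
    "CG1": "g1",
    "CG2": "g2",
    "CB": "b",
}

_TOKEN_RE = re.compile(r"([MILVAT])(proS|proR)?")


@dataclass(frozen=True)
class LabellingScheme:
    """Set of active methyl positions, keyed by one-letter residue type.

    Parameters
    ----------
    name:
        The scheme token, e.g. ``"MILproSVproSAT"`` or ``"ILV"``.
    selectors:
        Mapping residue letter -> tuple of active methyl carbon atom names.
    stereo:
        Mapping residue letter (only ``L``/``V``) -> :class:`Stereo`.
    """

    name: str
    selectors: dict[str, tuple[str, ...]] = field(hash=False)
    stereo: dict[str, Stereo] = field(hash=False)

    @classmethod
    def from_token(cls, token: str) -> "LabellingScheme":
        """Parse a scheme token such as ``MILproSVproSAT`` or ``ILVA``.

        Each residue letter may appear once; ``L`` and ``V`` accept an
        optional ``proS``/``proR`` suffix (absence means non-stereospecific).
        """
        selectors: dict[str, tuple[str, ...]] = {}
        stereo: dict[str, Stereo] = {}
        pos = 0
        while pos < len(token):
            m = _TOKEN_RE.match(token, pos)
            if m is None:
                raise ValueError(
                    f"cannot parse labelling scheme {token!r} at {token[pos:]!r}"
                )
            letter, suffix = m.group(1), m.group(2)
            if letter in selectors:
                raise ValueError(f"residue {letter} listed twice in {token!r}")
            if suffix and letter not in ("L", "V"):
                raise ValueError(f"{letter} has no prochiral methyls ({token!r})")
            if letter in ("L", "V"):
                st = Stereo.NONSTEREO if suffix is None else Stereo(suffix)
                stereo[letter] = st
                pro_r, pro_s = METHYL_ATOMS[letter]
                selectors[letter] = {
                    Stereo.PROR: (pro_r,),
                    Stereo.PROS: (pro_s,),
                    Stereo.NONSTEREO: (pro_r, pro_s),
                }[st]
            else:
                selectors[letter] = METHYL_ATOMS[letter]
            pos = m.end()
        if not selectors:
            raise ValueError("empty labelling scheme")
        return cls(name=token, selectors=selectors, stereo=stereo)

    @property
    def residues(self) -> frozenset[str]:
        """Active residue types (one-letter codes)."""
        return frozenset(self.selectors)

    def atoms_for(self, restype: str) -> tuple[str, ...]:
        """Active methyl carbon atom names for a residue type ('' if inactive)."""
        return self.selectors.get(restype, ())

    def is_nonstereo(self, restype: str) -> bool:
        """True if both prochiral methyls of ``restype`` are labelled."""
        return self.stereo.get(restype) == Stereo.NONSTEREO

    def n_methyls_per_residue(self, restype: str) -> int:
        return len(self.selectors.get(restype, ()))
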