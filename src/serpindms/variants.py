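"""Single amino-acid substitution identities and their notation.

A variant is a substitution in the mature protein: 1-based position, wild-type
residue, substituted residue, both from the standard 20-letter alphabet (no
stop symbol).  Both one-letter ("I91L") and three-letter ("Ile91Leu") notations
are parsed; one-letter is canonical on output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ParseError

#: Standard 20 amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

N_SUBSTITUTIONS_PER_SITE = len(AMINO_ACIDS) - 1  # 19

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k.capitalize() for k, v in THREE_TO_ONE.items()}

_ONE_LETTER = re.compile(r"^([A-Y])(\d+)([A-Y])$")
_THREE_LETTER = re.compile(r"^([A-Za-z]{3})(\d+)([A-Za-z]{3})$")


@dataclass(frozen=True, order=True)
class Variant:
    """One single amino-acid substitution.

    Parameters
    ----------
    position : int
        1-based index into the mature protein sequence.
    wt_aa, alt_aa : str
        One-letter wild-type and substituted residues; ``alt_aa != wt_aa``.
    """

    position: int
    wt_aa: str
    alt_aa: str

    def __post_init__(self):
        if self.wt_aa not in THREE_TO_ONE.values():
            raise ParseError(f"unknown wild-type residue {self.wt_aa!r}")
        if self.alt_aa not in THREE_TO_ONE.values():
            raise ParseError(f"unknown substituted residue {self.alt_aa!r}")
        if self.alt_aa == self.wt_aa:
            raise ParseError(
                f"substitution must differ from wild type at position {self.position}"
            )
        if self.position < 1:
            raise ParseError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.alt_aa}"

    @property
    def long_form(self) -> str:
        """Three-letter notation, e.g. ``Ile91Leu``."""
        return f"{ONE_TO_THREE[self.wt_aa]}{self.position}{ONE_TO_THREE[self.alt_aa]}"


def parse_variant(text: str) -> Variant:
    """Parse ``I91L`` or ``Ile91Leu`` into a :class:`Variant`.

    Raises
    ------
    ParseError
        If the notation is unrecognized or the residues are invalid.
    """
    s = str(text).strip()
    m = _ONE_LETTER.match(s)
    if m:
        wt, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        return Variant(pos, wt, alt)
    m = _THREE_LETTER.match(s)
    if m:
        wt3, alt3 = m.group(1).upper(), m.group(3).upper()
        if wt3 not in THREE_TO_ONE or alt3 not in THREE_TO_ONE:
            raise ParseError(f"unknown residue code in {text!r}")
        return Variant(int(m.group(2)), THREE_TO_ONE[wt3], THREE_TO_ONE[alt3])
    raise ParseError(f"unrecognized variant notation {text!r}")


def substitution_space(length: int) -> int:
    """Number of possible single substitutions for a protein of given length
    (19 per site)."""
    if length < 1:
        raise ParseError(f"protein length must be >= 1, got {length}")
    return N_SUBSTITUTIONS_PER_SITE * length
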