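"""Packaged domain templates and their helix-coordinate annotations.

The package ships a small set of artificial, self-contained template
sequences rather than database entries.  Three are globins carrying the
classical helix-coordinate labels of the myoglobin fold (positions named
by helix letter and index, e.g. ``B10``, ``F8``, with ``CD1``/``FG4`` in
the inter-helical corners):

``GLB3F``, ``GLB3S``
    150-residue 3/3 alpha-helical globins standing for the F
    (flavohemoglobin-related) and S (sensor) families.  Both carry the
    full 36-position checklist; their sequences are otherwise unrelated
    (~14% identity) so family assignment by best template is
    well-conditioned.
``GLB2``
    116-residue truncated 2/2 fold globin (T family) whose vestigial A
    and E helices carry no labels.

The remaining templates are the non-globin building blocks of the
architectures seen in fungal globin chimeras: ``CQX2`` (FAD-binding) and
``CQX3`` (NAD(P)-binding) halves of the ferredoxin-reductase-like moiety
of flavohemoglobins (sized so GLB3F+CQX2+CQX3 totals 396 residues, the
length of the E. coli flavohemoglobin), an ``LRR`` block of tandem
leucine-rich-repeat 11-mers (LxxLxLxxN/CxL), and a ``SIG`` signal
peptide (basic n-region followed by a hydrophobic core).

All coordinates are 1-based and inclusive throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional

#: Residues counted as hydrophobic in the fold checklist.
HYDROPHOBIC = frozenset("AVLIMFWYC")

#: The 20 standard amino acids.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Canonical ordering of helix-coordinate labels along the fold.  Used to
# validate that annotation indices increase in helix order.
LABEL_ORDER = (
    "A8", "A11", "A12", "A15",
    "B6", "B9", "B10", "B13", "B14",
    "C4", "CD1",
    "E4", "E7", "E8", "E11", "E12", "E15", "E18", "E19",
    "F1", "F4", "F8", "FG4",
    "G5", "G8", "G11", "G12", "G13", "G15", "G16",
    "H7", "H8", "H11", "H12", "H15", "H19",
)


class TemplateError(ValueError):
    """Raised when a template violates its structural invariants."""


@dataclass(frozen=True)
class DomainTemplate:
    """A named template sequence with optional helix-coordinate labels.

    Parameters
    ----------
    name
        Template identifier (e.g. ``"GLB3F"``, ``"CQX2"``).
    sequence
        Amino-acid string.
    annotations
        Mapping from coordinate label to 1-based index into ``sequence``.
        Only globin templates carry annotations.
    family_tag
        ``"F"``, ``"S"`` or ``"T"`` for globin templates, ``None``
        otherwise.
    """

    name: str
    sequence: str
    annotations: Mapping[str, int] = field(default_factory=dict)
    family_tag: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "annotations", MappingProxyType(dict(self.annotations)))
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise TemplateError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - set(STANDARD_AA) - {"X"}
        if bad:
            raise TemplateError(f"{self.name}: non-amino-acid characters {sorted(bad)}")
        for label, idx in self.annotations.items():
            if not 1 <= idx <= n:
                raise TemplateError(f"{self.name}: label {label} index {idx} outside 1..{n}")
        ordered = [self.annotations[l] for l in LABEL_ORDER if l in self.annotations]
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise TemplateError(f"{self.name}: annotation indices not increasing in helix order")
        if self.family_tag is not None:
            if self.family_tag not in ("F", "S", "T"):
                raise TemplateError(f"{self.name}: family_tag {self.family_tag!r}")
            f8 = self.annotations.get("F8")
            if f8 is None or self.sequence[f8 - 1] != "H":
                raise TemplateError(f"{self.name}: globin template must have His at F8")

    @property
    def is_globin(self) -> bool:
        return self.family_tag is not None

    def residue_at(self, label: str) -> str:
        """Residue at an annotated coordinate label (1-based lookup)."""
        return self.sequence[self.annotations[label] - 1]


# --- annotation layouts ------------------------------------------------

# 3/3 fold, 150 residues: helices A(4-19) B(25-40) C(44-50) CD(51-58)
# E(59-78) F(85-93) FG(94-99) G(100-118) H(124-143).
_ANN_33 = {
    "A8": 11, "A11": 14, "A12": 15, "A15": 18,
    "B6": 30, "B9": 33, "B10": 34, "B13": 37, "B14": 38,
    "C4": 47, "CD1": 51,
    "E4": 62, "E7": 65, "E8": 66, "E11": 69, "E12": 70, "E15": 73,
    "E18": 76, "E19": 77,
    "F1": 85, "F4": 88, "F8": 92, "FG4": 97,
    "G5": 104, "G8": 107, "G11": 110, "G12": 111, "G13": 112,
    "G15": 114, "G16": 115,
    "H7": 130, "H8": 131, "H11": 134, "H12": 135, "H15": 138, "H19": 142,
}

# 2/2 fold, 116 residues: vestigial A and E helices carry no labels.
_ANN_22 = {
    "B6": 11, "B9": 14, "B10": 15, "B13": 18, "B14": 19,
    "C4": 28, "CD1": 32,
    "F1": 50, "F4": 53, "F8": 57, "FG4": 62,
    "G5": 69, "G8": 72, "G11": 75, "G12": 76, "G13": 77, "G15": 79,
    "G16": 80,
    "H7": 95, "H8": 96, "H11": 99, "H12": 100, "H15": 103, "H19": 107,
}

# --- packaged sequences ------------------------------------------------
# Fixed artificial sequences: hydrophobic residues at every checklist
# position, His at F8, polar-biased elsewhere.

_GLB3F_SEQ = (
    "MSTNEENSSKVNECVNDYTGEEKTDQRADCDRCWPNLLQKSQDNKAYHHKIEQTTPPSPK"
    "NMKRFMDEYMKPFQDAFDENGPEDYQSIHDQHKGATFGNRSSKLDPAEAIWLPVLANNHE"
    "ETDAKDGENIMEDWVTGMNQDWQSKPHDNN"
)
_GLB3S_SEQ = (
    "MKPPHEHTEKLPKFIKNWNNKKHETQNKPIPQIMEPWLATSEPTGTMQDALRQHGRENDN"
    "GLGSLMQHMWKRMTNVMEPRKANAWAGWRDDHSDQQMSGGANPLEPCSKIMIPYWHQRSK"
    "DEGQEGGEEVLEDVYRAMGGKIEKGKHHHT"
)
_GLB2_SEQ = (
    "MGKPQEHHEEYDTYMKPYWKAKTGDNQINKHYNHAHESDGHAASDKNPHATQCENSHAGR"
    "KLNSKTHNVDHCRNFYVSMVDRNADDEKSEDPEALYAEFIKAYPRQYKNGEDPEKR"
)
_CQX2_SEQ = (
    "MHNLSHRNDKCIWAVLRDHDYEKVITANKAIKAKGEVIIKEHGSSICHRHGYISCARHHY"
    "ISRFCWIPLASAFIERWKMPYECPHDKIKRMKQPGDASEA"
)
_CQX3_SEQ = (
    "MVHRRAHYFSKMQCFHGTYQETHYSNQFHGWTPMAQPIVTRLIKMYFLLKLTTMLYIWQC"
    "DSTWLKFRTQERHHFMWRQKNCNCVQCYHEIVEGYSMTDMRIVVHTPRWHASPYQAFHYE"
    "TSLKAPNIEHWIKTMAKTKTSRMWDP"
)
# Six tandem copies of the LRR 11-mer consensus LxxLxLxxN/CxL.  The
# consensus positions (L1, L4, L6, N9, L11 of each repeat) are annotated
# so the mutation model can conserve them, as they are in real LRR
# proteins; the x positions are free to diverge.
_LRR_SEQ = "LSALDLSGNKL" * 6
_LRR_ANN = {
    f"r{k + 1}{label}": k * 11 + offset
    for k in range(6)
    for label, offset in (("L1", 1), ("L4", 4), ("L6", 6), ("N9", 9), ("L11", 11))
}
# Basic n-region then a hydrophobic core, ~20 residues.
_SIG_SEQ = "MKKLLSLALLLVLAATSAQA"

GLB3F = DomainTemplate("GLB3F", _GLB3F_SEQ, _ANN_33, family_tag="F")
GLB3S = DomainTemplate("GLB3S", _GLB3S_SEQ, _ANN_33, family_tag="S")
GLB2 = DomainTemplate("GLB2", _GLB2_SEQ, _ANN_22, family_tag="T")
CQX2 = DomainTemplate("CQX2", _CQX2_SEQ)
CQX3 = DomainTemplate("CQX3", _CQX3_SEQ)
LRR = DomainTemplate("LRR", _LRR_SEQ, _LRR_ANN)
SIG = DomainTemplate("SIG", _SIG_SEQ)

#: Default registry of packaged templates, keyed by name.  ``GLB3`` is an
#: alias for the F-family 3/3 template.
DEFAULT_TEMPLATES: Mapping[str, DomainTemplate] = MappingProxyType({
    "GLB3F": GLB3F,
    "GLB3S": GLB3S,
    "GLB3": GLB3F,
    "GLB2": GLB2,
    "CQX2": CQX2,
    "CQX3": CQX3,
    "LRR": LRR,
    "SIG": SIG,
})

#: The globin templates used for family assignment, one per family.
GLOBIN_TEMPLATES = (GLB3F, GLB3S, GLB2)


def get_template(name: str) -> DomainTemplate:
    try:
        return DEFAULT_TEMPLATES[name]
    except KeyError:
        raise KeyError(f"unknown template {name!r}; known: {sorted(set(DEFAULT_TEMPLATES))}")
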