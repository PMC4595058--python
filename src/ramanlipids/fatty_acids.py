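"""Fatty-acid standards: shorthand parsing, structural arithmetic, registry.

The ratiometric Raman method is calibrated against pure free fatty acids
written in the usual ``C<carbons>:<double bonds>`` shorthand (e.g. ``C18:1``
for oleic acid).  For a straight-chain, methylene-interrupted, all-*cis*
free fatty acid the number of aliphatic CH2 groups follows directly from
the shorthand:

    N_CH2 = n_carbons - 2 - 2 * n_double_bonds

(the terminal CH3 and the carboxyl carbon are excluded; each C=C removes
two CH2 groups).  N_CH2 normalizes the C=C count into the chain-length-
corrected unsaturation N_C=C/N_CH2 used throughout the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = [
    "FattyAcid",
    "parse_fatty_acid",
    "unsaturation_ratio",
    "standard_registry",
    "write_registry",
    "read_registry",
    "COMMON_NAMES",
]

_CODE_RE = re.compile(r"^C(\d+):(\d+)$")

#: Atomic masses (g/mol) used for the molecular weight of C_n H_(2n-2d) O2.
_M_C, _M_H, _M_O2 = 12.011, 1.008, 31.998

#: Trivial names for the default panel, for nicer reporting only.
COMMON_NAMES = {
    "C12:0": "lauric",
    "C14:0": "myristic",
    "C16:0": "palmitic",
    "C16:1": "palmitoleic",
    "C18:0": "stearic",
    "C18:1": "oleic",
    "C18:2": "linoleic",
    "C18:3": "alpha-linolenic",
    "C20:4": "arachidonic",
    "C20:5": "eicosapentaenoic",
    "C22:6": "docosahexaenoic",
}

#: Default calibration panel: eleven even-numbered fatty acids common in
#: microalgal lipid extracts, spanning 0-6 C=C bonds.  Melting points in
#: degrees Celsius from standard chemistry references.
_DEFAULT_PANEL: list[tuple[str, float]] = [
    ("C12:0", 43.8),
    ("C14:0", 53.9),
    ("C16:0", 62.9),
    ("C16:1", 0.5),
    ("C18:0", 69.3),
    ("C18:1", 13.4),
    ("C18:2", -6.9),
    ("C18:3", -11.3),
    ("C20:4", -49.5),
    ("C20:5", -53.5),
    ("C22:6", -44.0),
]


@dataclass(frozen=True)
class FattyAcid:
    """A straight-chain free fatty acid standard.

    Derived fields (``n_ch2``, ``molecular_weight``) are computed in
    ``__post_init__`` and must not be supplied.
    """

    name: str
    n_carbons: int
    n_double_bonds: int
    melting_point: float
    n_ch2: int = field(init=False)
    molecular_weight: float = field(init=False)

    def __post_init__(self) -> None:
        n, d = self.n_carbons, self.n_double_bonds
        if n < 4:
            raise ValidationError(f"{self.name}: need at least 4 carbons, got {n}")
        if d < 0 or d > (n - 2) // 2:
            raise ValidationError(
                f"{self.name}: {d} double bonds exceeds structural maximum "
                f"{(n - 2) // 2} for {n} carbons"
            )
        n_ch2 = n - 2 - 2 * d
        if n_ch2 < 0:
            raise ValidationError(f"{self.name}: negative CH2 count")
        object.__setattr__(self, "n_ch2", n_ch2)
        mw = _M_C * n + _M_H * (2 * n - 2 * d) + _M_O2
        object.__setattr__(self, "molecular_weight", round(mw, 3))

    @property
    def code(self) -> str:
        return f"C{self.n_carbons}:{self.n_double_bonds}"


def parse_fatty_acid(code: str, melting_point: float) -> FattyAcid:
    """Parse ``C<carbons>:<double bonds>`` shorthand into a :class:`FattyAcid`.

    Parameters
    ----------
    code : str
        Shorthand such as ``"C18:1"``.
    melting_point : float
        Literature melting point in degrees Celsius.

    Raises
    ------
    ValidationError
        On malformed codes or structurally impossible double-bond counts.
    """
    m = _CODE_RE.match(code.strip())
    if m is None:
        raise ValidationError(f"malformed fatty-acid code {code!r}; expected C<n>:<d>")
    n, d = int(m.group(1)), int(m.group(2))
    return FattyAcid(name=code.strip(), n_carbons=n, n_double_bonds=d,
                     melting_point=float(melting_point))


def unsaturation_ratio(fa: FattyAcid) -> float:
    """Chain-length-normalized unsaturation N_C=C/N_CH2.

    Raises
    ------
    ValidationError
        If the acid has no CH2 groups (ratio undefined).
    """
    if fa.n_ch2 == 0:
        raise ValidationError(f"{fa.name}: N_C=C/N_CH2 undefined (no CH2 groups)")
    return fa.n_double_bonds / fa.n_ch2


def standard_registry() -> list[FattyAcid]:
    """The default 11-standard calibration panel.

    Sorted by decreasing unsaturation (double-bond count, then carbon count),
    matching the conventional presentation of standard spectra from most to
    least unsaturated.
    """
    panel = [parse_fatty_acid(code, mp) for code, mp in _DEFAULT_PANEL]
    panel.sort(key=lambda fa: (-fa.n_double_bonds, -fa.n_carbons))
    return panel


def write_registry(path, registry: list[FattyAcid]) -> None:
    """Serialize a registry to delimited text (columns: code, melting_point_C)."""
    with open(path, "w") as fh:
        fh.write("# fatty-acid standard registry\n")
        fh.write("# code\tmelting_point_C\n")
        for fa in registry:
            fh.write(f"{fa.code}\t{fa.melting_point:g}\n")


def read_registry(path) -> list[FattyAcid]:
    """Read a registry written by :func:`write_registry`; '#' lines are comments."""
    out: list[FattyAcid] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"registry line {lineno}: expected 2 columns")
            out.append(parse_fatty_acid(parts[0], float(parts[1])))
    return out
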