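"""Per-residue free-energy scales for membrane-insertion propensity.

The default scale is the whole-residue water-to-octanol minus
water-to-bilayer-interface transfer free energy of Wimley and White, with
the sign reversed so that large values mean high insertion propensity:
aliphatic hydrophobics (I, V, L) score positive while charged residues
(D, E, K, R) score negative.  Histidine uses the protonated-side-chain
values of the component scales (the alternative published alongside the
neutral form); this choice reproduces published reference computations on
His-containing TM segments exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Whole-residue water -> n-octanol transfer free energies (kcal/mol).
WW_OCTANOL: Mapping[str, float] = {
    "A": 0.50, "R": 1.81, "N": 0.85, "D": 3.64, "C": -0.02,
    "Q": 0.77, "E": 3.63, "G": 1.15, "H": 2.33, "I": -1.12,
    "L": -1.25, "K": 2.80, "M": -0.67, "F": -1.71, "P": 0.14,
    "S": 0.46, "T": 0.25, "W": -2.09, "Y": -0.71, "V": -0.46,
}

#: Whole-residue water -> POPC bilayer interface transfer free energies (kcal/mol).
WW_INTERFACE: Mapping[str, float] = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.96, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue value table over the 20 standard amino acids.

    Lookup of a nonstandard symbol (B, Z, X, U, O, J, ...) returns 0.0 so
    that such positions contribute nothing to window sums; callers that
    care emit a warning (see :func:`tmclass.measures.hydrophobicity`).
    """

    name: str
    values: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.values)
        extra = set(self.values) - set(STANDARD_RESIDUES)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def __getitem__(self, residue: str) -> float:
        return self.values.get(residue, 0.0)

    def is_standard(self, residue: str) -> bool:
        return residue in self.values

    def to_tsv(self, path: str | Path) -> None:
        """Export as a two-column (residue, value) tab-separated table."""
        lines = [f"{aa}\t{self.values[aa]!r}" for aa in STANDARD_RESIDUES]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "ResidueScale":
        values: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            values[fields[0].strip().upper()] = float(fields[1])
        return cls(name=name or Path(path).stem, values=values)


def default_scale() -> ResidueScale:
    """Sign-reversed octanol-minus-interface scale, -(dG_oct - dG_if).

    High values coincide with high membrane-insertion propensity.
    """
    values = {aa: -(WW_OCTANOL[aa] - WW_INTERFACE[aa]) for aa in STANDARD_RESIDUES}
    return ResidueScale(name="rev_octanol_minus_interface", values=values)
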