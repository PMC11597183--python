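"""Parsing and formatting of receptor point-mutation codes.

Mutation codes follow the GPCR convention of a wild-type residue letter,
a sequence position, an optional Ballesteros–Weinstein generic number, and
a mutant residue letter — e.g. ``A293(7.35)T``.  Three input spellings are
accepted (``A293T``, ``A293(7.35)T``, ``A293^7.35^T``); the canonical
output form uses parentheses, since superscripts do not survive plain-text
files.  The literal string ``WT`` denotes the wild-type receptor.

Positions follow the UniProt P21453 (S1PR1) sequence numbering.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = ["VariantSpec", "parse_variant", "format_variant", "load_snp_table"]

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_CODE_RE = re.compile(
    r"^(?P<wt>[A-Za-z])(?P<pos>\d+)"
    r"(?:\((?P<bw_paren>\d+\.\d+)\)|\^(?P<bw_caret>\d+\.\d+)\^)?"
    r"(?P<mut>[A-Za-z])$"
)


@dataclass(frozen=True)
class VariantSpec:
    """A single amino-acid substitution in the receptor binding site."""

    wt_residue: str
    position: int
    mut_residue: str
    bw_number: Optional[str] = None
    rsid: Optional[str] = None
    frequency: Optional[float] = None
    impact_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.is_wildtype:
            return
        for name in ("wt_residue", "mut_residue"):
            aa = getattr(self, name)
            if aa not in _AMINO_ACIDS:
                raise ValueError(f"{name} {aa!r} is not a canonical amino-acid letter")
        if self.wt_residue == self.mut_residue:
            raise ValueError(
                f"silent substitution {self.wt_residue}{self.position}{self.mut_residue}: "
                "wild-type and mutant residues are identical"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.bw_number is not None and not re.fullmatch(r"\d+\.\d+", self.bw_number):
            raise ValueError(f"malformed Ballesteros–Weinstein number {self.bw_number!r}")
        if self.frequency is not None and not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency must lie in [0, 1], got {self.frequency}")

    @property
    def is_wildtype(self) -> bool:
        return self.wt_residue == "" and self.position == 0

    @classmethod
    def wildtype(cls) -> "VariantSpec":
        """Sentinel record for the unmutated receptor."""
        return cls(wt_residue="", position=0, mut_residue="")


def parse_variant(code: str) -> VariantSpec:
    """Parse a mutation code such as ``F205L``, ``F205(5.42)L`` or
    ``F205^5.42^L``; the literal ``WT`` yields the wild-type sentinel."""
    code = code.strip()
    if code == "WT":
        return VariantSpec.wildtype()
    m = _CODE_RE.match(code)
    if m is None:
        raise ValueError(f"malformed variant code {code!r}")
    wt, mut = m.group("wt").upper(), m.group("mut").upper()
    for token, name in ((wt, "wild-type"), (mut, "mutant")):
        if token not in _AMINO_ACIDS:
            raise ValueError(
                f"non-canonical {name} amino-acid letter {token!r} in {code!r}"
            )
    return VariantSpec(
        wt_residue=wt,
        position=int(m.group("pos")),
        mut_residue=mut,
        bw_number=m.group("bw_paren") or m.group("bw_caret"),
    )


def format_variant(spec: VariantSpec) -> str:
    """Canonical plain-text form: ``F205(5.42)L``, or ``WT``."""
    if spec.is_wildtype:
        return "WT"
    bw = f"({spec.bw_number})" if spec.bw_number else ""
    return f"{spec.wt_residue}{spec.position}{bw}{spec.mut_residue}"


def load_snp_table(path) -> list[VariantSpec]:
    """Load a SNP table CSV with columns rsid, variant_code, frequency, impact.

    Duplicate substitutions (same position and mutant residue) and
    frequencies outside [0, 1] are rejected.
    """
    df = pd.read_csv(path)
    required = {"rsid", "variant_code", "frequency", "impact"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    specs: list[VariantSpec] = []
    seen: set[tuple[int, str]] = set()
    for row in df.itertuples(index=False):
        base = parse_variant(str(row.variant_code))
        freq = float(row.frequency)
        if math.isnan(freq):
            freq = None
        spec = VariantSpec(
            wt_residue=base.wt_residue,
            position=base.position,
            mut_residue=base.mut_residue,
            bw_number=base.bw_number,
            rsid=str(row.rsid),
            frequency=freq,
            impact_label=str(row.impact),
        )
        key = (spec.position, spec.mut_residue)
        if key in seen:
            raise ValueError(f"duplicate variant {format_variant(spec)} in SNP table")
        seen.add(key)
        specs.append(spec)
    return specs
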