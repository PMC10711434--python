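"""Atom identifiers shared by the contact-map and structure layers."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AtomId:
    """Identifies one atom by chain, residue and atom name.

    `serial` (1-based engine atom number) and `element` are optional
    annotations filled in when the identifier is resolved against a
    structure; they do not take part in identity comparisons of the
    (chain, resnum, name) key.
    """

    chain: str
    resname: str
    resnum: int
    name: str
    serial: int | None = None
    element: str | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        """The unique (chain, residue number, atom name) triplet."""
        return (self.chain, self.resnum, self.name)

    def same_atom(self, other: "AtomId") -> bool:
        return self.key == other.key

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chain}/{self.resname}{self.resnum}/{self.name}"
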