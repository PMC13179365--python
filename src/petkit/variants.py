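"""Point-mutation bookkeeping for engineered enzyme variants.

Mutations are written in the conventional ``<wt><position><new>`` one-letter
notation (e.g. ``L93F``). A variant is a named, position-disjoint set of
mutations relative to a fixed wild-type numbering; reversions are expressed
by removing or replacing the parental mutation, never by stacking two
mutations at one position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Side-chain formal charges at pH 8: Asp/Glu deprotonated, Lys/Arg
#: protonated, His neutral (pKa ~ 6), Cys/Tyr neutral. Termini excluded.
SIDE_CHAIN_CHARGE_PH8: Mapping[str, int] = {
    "D": -1,
    "E": -1,
    "K": +1,
    "R": +1,
}

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True, order=True)
class Mutation:
    """A single point substitution, 1-based position in wild-type numbering."""

    wt_residue: str
    position: int
    new_residue: str

    def __post_init__(self) -> None:
        for res in (self.wt_residue, self.new_residue):
            if res not in AMINO_ACIDS:
                raise DataError(f"unknown amino-acid code {res!r}")
        if self.position < 1:
            raise DataError(f"position must be >= 1, got {self.position}")
        if self.wt_residue == self.new_residue:
            raise DataError(
                f"silent mutation {self.wt_residue}{self.position}"
                f"{self.new_residue}: wt and new residue are identical"
            )

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.new_residue}"

    def inverse(self) -> "Mutation":
        """The reversion of this mutation (new -> wt at the same position)."""
        return Mutation(self.new_residue, self.position, self.wt_residue)


def parse_mutation(token: str) -> Mutation:
    """Parse a ``<wt><pos><new>`` token such as ``"L93F"``.

    Raises
    ------
    DataError
        If the token is malformed or denotes a silent mutation.
    """
    match = _MUTATION_RE.match(token.strip())
    if match is None:
        raise DataError(f"malformed mutation token {token!r}")
    wt, pos, new = match.groups()
    return Mutation(wt.upper(), int(pos), new.upper())


@dataclass
class VariantSpec:
    """A named variant: an ordered, position-disjoint set of mutations."""

    name: str
    mutations: tuple[Mutation, ...]
    parent: str | None = None
    round: int = 0

    def __post_init__(self) -> None:
        self.mutations = tuple(self.mutations)
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            dupes = sorted({p for p in positions if positions.count(p) > 1})
            raise DataError(f"duplicate mutation positions: {dupes}")
        if not 0 <= self.round <= 4:
            raise DataError(f"engineering round must be in 0..4, got {self.round}")

    @classmethod
    def from_tokens(
        cls,
        name: str,
        tokens: Iterable[str],
        parent: str | None = None,
        round: int = 0,
    ) -> "VariantSpec":
        return cls(name, tuple(parse_mutation(t) for t in tokens), parent, round)

    def inverse(self) -> "VariantSpec":
        """The full reversion variant (every mutation inverted)."""
        return VariantSpec(
            f"{self.name}-reverted",
            tuple(m.inverse() for m in self.mutations),
            parent=self.name,
            round=self.round,
        )

    def __str__(self) -> str:
        return f"{self.name}[{'/'.join(str(m) for m in self.mutations)}]"


@dataclass
class ChargeModel:
    """Per-residue side-chain formal charge map at a fixed pH."""

    pH: float = 8.0
    charges: Mapping[str, int] = field(default_factory=lambda: dict(SIDE_CHAIN_CHARGE_PH8))

    def __post_init__(self) -> None:
        for res, q in self.charges.items():
            if q not in (-1, 0, 1):
                raise DataError(f"formal charge for {res} must be -1, 0 or +1, got {q}")

    def charge(self, residue: str) -> int:
        return self.charges.get(residue, 0)


def apply_mutations(sequence: str, variant: VariantSpec) -> str:
    """Apply a variant's mutations to a one-letter amino-acid sequence.

    Every mutation's wild-type residue must match the sequence at its
    (1-based) position; mismatches raise :class:`DataError` naming the
    position and the expected/found residues.
    """
    seq = list(sequence)
    for m in variant.mutations:
        if m.position > len(seq):
            raise DataError(
                f"{m}: position {m.position} beyond sequence length {len(seq)}"
            )
        found = seq[m.position - 1]
        if found != m.wt_residue:
            raise DataError(
                f"{m}: expected {m.wt_residue} at position {m.position}, found {found}"
            )
        seq[m.position - 1] = m.new_residue
    return "".join(seq)


def net_charge_delta(variant: VariantSpec, model: ChargeModel | None = None) -> int:
    """Sum of charge(new) - charge(wt) over the variant's mutations."""
    if model is None:
        model = ChargeModel()
    return sum(model.charge(m.new_residue) - model.charge(m.wt_residue) for m in variant.mutations)


def load_variant_table(path=None) -> dict[str, VariantSpec]:
    """Load a variant table CSV (columns name,parent,round,mutations).

    ``mutations`` holds semicolon-separated tokens; an empty field denotes
    the wild type. Without *path* the packaged reference table is used.
    """
    if path is None:
        with resources.files("petkit.data").joinpath("variants.csv").open() as fh:
            df = pd.read_csv(fh, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    required = {"name", "parent", "round", "mutations"}
    if not required.issubset(df.columns):
        raise DataError(f"variant table must have columns {sorted(required)}")
    table: dict[str, VariantSpec] = {}
    for row in df.itertuples(index=False):
        tokens = [] if pd.isna(row.mutations) or not row.mutations else row.mutations.split(";")
        parent = None if pd.isna(row.parent) or not row.parent else row.parent
        spec = VariantSpec.from_tokens(row.name, tokens, parent=parent, round=int(row.round))
        if spec.name in table:
            raise DataError(f"duplicate variant name {spec.name!r}")
        table[spec.name] = spec
    return table
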