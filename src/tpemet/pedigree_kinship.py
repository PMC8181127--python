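"""Pedigree validation/ordering and the additive (numerator) relationship matrix.

The relationship matrix is built with the tabular method: for individual ``i``
with parents ``p`` and ``q`` (listed earlier),

* ``a_ii = 1 + 0.5 * a_pq`` (term dropped when a parent is unknown),
* ``a_ij = 0.5 * (a_jp + a_jq)`` for any earlier ``j``.

Unknown parents are treated as unrelated, non-inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "RelationshipMatrix",
    "order_pedigree",
    "build_A",
]

UNKNOWN = "0"


class PedigreeError(ValueError):
    """Cycles, missing references or malformed pedigree rows."""


@dataclass(frozen=True)
class RelationshipMatrix:
    """Additive relationship matrix over an ordered list of individuals."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match the number of ids")

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.ids)}

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = self.index
        missing = [g for g in ids if g not in idx]
        if missing:
            raise PedigreeError(f"individual(s) not in pedigree: {missing[:10]}")
        sel = np.array([idx[g] for g in ids])
        return self.values[np.ix_(sel, sel)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.ids))
        df.insert(0, "id", list(self.ids))
        return df


def _normalise(ped: pd.DataFrame) -> pd.DataFrame:
    required = ["id", "parent1", "parent2"]
    missing = [c for c in required if c not in ped.columns]
    if missing:
        raise PedigreeError(f"pedigree lacks column(s): {', '.join(missing)}")
    out = ped.loc[:, required].astype(str)
    out = out.replace({"parent1": {"nan": UNKNOWN, "": UNKNOWN}, "parent2": {"nan": UNKNOWN, "": UNKNOWN}})
    if out["id"].duplicated().any():
        dups = out.loc[out["id"].duplicated(), "id"].tolist()
        raise PedigreeError(f"duplicate individual id(s): {dups[:10]}")
    if (out["id"] == UNKNOWN).any():
        raise PedigreeError(f"'{UNKNOWN}' is reserved for unknown parents")
    return out


def order_pedigree(raw: pd.DataFrame) -> pd.DataFrame:
    """Topologically order a pedigree so every parent precedes its offspring.

    Raises
    ------
    PedigreeError
        If a referenced parent is absent or the parent relation is cyclic;
        for a cycle the offending individuals are listed.
    """
    ped = _normalise(raw)
    ids = set(ped["id"])
    for col in ("parent1", "parent2"):
        bad = set(ped[col]) - ids - {UNKNOWN}
        if bad:
            raise PedigreeError(f"referenced parent(s) not declared: {sorted(bad)[:10]}")

    parents = {
        row.id: [p for p in (row.parent1, row.parent2) if p != UNKNOWN]
        for row in ped.itertuples()
    }
    # Kahn's algorithm; stable with respect to input order.
    remaining = dict(parents)
    placed: list[str] = []
    placed_set: set[str] = set()
    order_hint = list(ped["id"])
    while remaining:
        ready = [g for g in order_hint if g in remaining and all(p in placed_set for p in remaining[g])]
        if not ready:
            cycle = sorted(remaining)
            raise PedigreeError(f"pedigree contains a cycle among: {cycle[:10]}")
        for g in ready:
            placed.append(g)
            placed_set.add(g)
            del remaining[g]
    return ped.set_index("id").loc[placed].reset_index()


def build_A(ped: pd.DataFrame, ordered: bool = False) -> RelationshipMatrix:
    """Build the additive relationship matrix by the tabular method.

    Parameters
    ----------
    ped
        Pedigree with columns id, parent1, parent2 ('0' = unknown).
    ordered
        Skip the topological sort when the input is already ordered.
    """
    ped = ped if ordered else order_pedigree(ped)
    ped = _normalise(ped)
    ids = list(ped["id"])
    idx = {g: i for i, g in enumerate(ids)}
    p1 = np.array([idx.get(p, -1) for p in ped["parent1"]])
    p2 = np.array([idx.get(p, -1) for p in ped["parent2"]])
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        a, b = p1[i], p2[i]
        if a >= 0 and b >= 0:
            A[i, i] = 1.0 + 0.5 * A[a, b]
        else:
            A[i, i] = 1.0
        if i == 0:
            continue
        contrib = np.zeros(i)
        if a >= 0:
            contrib += A[:i, a]
        if b >= 0:
            contrib += A[:i, b]
        A[:i, i] = A[i, :i] = 0.5 * contrib
    return RelationshipMatrix(ids=tuple(ids), values=A)
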