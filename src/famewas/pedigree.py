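"""Pedigree parsing, validation, and kinship computation.

A pedigree is an ordered collection of individuals with parent links; the
pairwise kinship coefficient phi(i, j) — the probability that a random
allele drawn from i is identical by descent with a random allele drawn
from j — provides the genetic covariance kernel of the polygenic model.
The additive genetic covariance between relatives is 2*phi*sigma2_a, so
the matrix stored here is phi itself and the factor 2 is applied by the
variance-component fitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "kinship_matrix",
]

MISSING_PARENT = {"0", "", "NA", "na", "nan", None}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or unparseable files."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders.  Individuals
    with exactly one known parent are rejected during validation rather
    than silently completed with a dummy founder.
    """

    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """Validated collection of individuals in stable (file) order."""

    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {ind.individual_id: k for k, ind in enumerate(self.individuals)}
        if len(self._index) != len(self.individuals):
            seen: set[str] = set()
            for ind in self.individuals:
                if ind.individual_id in seen:
                    raise PedigreeError(f"duplicate individual id: {ind.individual_id!r}")
                seen.add(ind.individual_id)
        self._validate()

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[self._index[individual_id]]

    def _validate(self) -> None:
        for ind in self.individuals:
            has_f = ind.father_id is not None
            has_m = ind.mother_id is not None
            if has_f != has_m:
                raise PedigreeError(
                    f"{ind.individual_id!r} has exactly one known parent; "
                    "both or neither must be specified"
                )
            for pid, role in ((ind.father_id, "father"), (ind.mother_id, "mother")):
                if pid is None:
                    continue
                if pid not in self._index:
                    raise PedigreeError(
                        f"{ind.individual_id!r} references unknown {role} {pid!r}"
                    )
                parent = self.individuals[self._index[pid]]
                if parent.family_id != ind.family_id:
                    raise PedigreeError(
                        f"{ind.individual_id!r} ({ind.family_id}) references {role} "
                        f"{pid!r} from a different family ({parent.family_id})"
                    )
        self.topological_order()  # raises on cycles / self-ancestry

    def topological_order(self) -> list[str]:
        """Ids ordered so every parent precedes its children.

        Raises :class:`PedigreeError` listing a cycle if parent links are
        not acyclic (e.g. an individual that is its own ancestor).
        """
        order: list[str] = []
        state: dict[str, int] = {}  # 0 unvisited / 1 in progress / 2 done
        stack_trace: list[str] = []

        def visit(iid: str) -> None:
            st = state.get(iid, 0)
            if st == 2:
                return
            if st == 1:
                cycle_start = stack_trace.index(iid)
                cycle = stack_trace[cycle_start:] + [iid]
                raise PedigreeError(f"pedigree cycle: {' -> '.join(cycle)}")
            state[iid] = 1
            stack_trace.append(iid)
            ind = self.individuals[self._index[iid]]
            if ind.father_id is not None:
                visit(ind.father_id)
                visit(ind.mother_id)
            stack_trace.pop()
            state[iid] = 2
            order.append(iid)

        for ind in self.individuals:
            visit(ind.individual_id)
        return order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "famid": [i.family_id for i in self.individuals],
                "id": [i.individual_id for i in self.individuals],
                "father": [i.father_id or "0" for i in self.individuals],
                "mother": [i.mother_id or "0" for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
            }
        )

    def write(self, path) -> None:
        """Write a whitespace-delimited PED-like file (famid id father mother sex)."""
        df = self.to_frame()
        df["sex"] = df["sex"].map({"male": "1", "female": "2"})
        df.to_csv(path, sep=" ", header=False, index=False)


@dataclass
class KinshipMatrix:
    """Kinship coefficients in pedigree order.

    ``phi`` is symmetric with diagonal 0.5 for non-inbred individuals;
    off-diagonal entries are zero for pairs without common ancestors.
    """

    ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("phi shape does not match number of ids")

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return KinshipMatrix(list(ids), self.phi[np.ix_(idx, idx)])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (id1, id2, phi) over the upper triangle incl. diagonal."""
        n = len(self.ids)
        iu = np.triu_indices(n)
        return pd.DataFrame(
            {
                "id1": [self.ids[i] for i in iu[0]],
                "id2": [self.ids[j] for j in iu[1]],
                "phi": self.phi[iu],
            }
        )

    def write_long(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    def write_dense(self, path) -> None:
        pd.DataFrame(self.phi, index=self.ids, columns=self.ids).to_csv(path)


def _parse_sex(token: str) -> str:
    t = token.strip().lower()
    if t in {"1", "m", "male"}:
        return "male"
    if t in {"2", "f", "female"}:
        return "female"
    raise PedigreeError(f"unrecognized sex code {token!r}")


def read_pedigree(path, dialect: str = "ped_like") -> Pedigree:
    """Read a PED-like text file: columns famid id father mother sex.

    Whitespace- or comma-delimited; missing parents coded "0" or empty.
    File order is preserved as the pedigree order.
    """
    if dialect != "ped_like":
        raise ValueError(f"unknown dialect {dialect!r}")
    individuals: list[Individual] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t.strip() for t in (line.split(",") if "," in line else line.split())]
            if len(tokens) < 5:
                raise PedigreeError(f"{path}:{lineno}: expected 5 columns, got {len(tokens)}")
            famid, iid, fid, mid, sex = tokens[:5]
            if iid in seen:
                raise PedigreeError(f"{path}:{lineno}: duplicate individual id {iid!r}")
            seen.add(iid)
            individuals.append(
                Individual(
                    individual_id=iid,
                    family_id=famid,
                    father_id=None if fid in MISSING_PARENT else fid,
                    mother_id=None if mid in MISSING_PARENT else mid,
                    sex=_parse_sex(sex),
                )
            )
    return Pedigree(individuals)


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Recursive (tabular) kinship over the whole pedigree.

    Processing individuals in topological order guarantees that when row i
    is filled, no earlier individual is a descendant of i, so
    phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2 and
    phi(i, i) = (1 + phi(father_i, mother_i)) / 2; founders are pairwise
    unrelated with phi = 0 and diagonal 0.5.
    """
    order = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for i, iid in enumerate(order):
        ind = ped[iid]
        if ind.is_founder:
            phi[i, i] = 0.5
        else:
            f, m = pos[ind.father_id], pos[ind.mother_id]
            row = 0.5 * (phi[f, :i] + phi[m, :i])
            phi[i, :i] = row
            phi[:i, i] = row
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
    # back to file order
    file_idx = np.array([pos[iid] for iid in ped.ids])
    phi = phi[np.ix_(file_idx, file_idx)]
    return KinshipMatrix(ped.ids, phi)
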