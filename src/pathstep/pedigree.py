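"""Pedigree representation and FAM-style I/O.

A pedigree is a directed acyclic graph of parent links within families.
Individuals whose parents are both missing are founders.  The class
validates the structure (unique ids, acyclicity, parents in the same
family) and stores individuals in topological order so that every parent
precedes its children — the order the kinship recursion and the gene-drop
simulator both require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import pandas as pd

__all__ = ["Individual", "Pedigree", "PedigreeError", "build_pedigree"]

MISSING_PARENT = {None, "", "0", "nan", "NA"}

SEX_CODES = {"1": "male", "2": "female", "0": "unknown",
             "male": "male", "female": "female", "unknown": "unknown",
             "M": "male", "F": "female"}


class PedigreeError(ValueError):
    """Structural or validation problem in a pedigree."""


@dataclass(frozen=True)
class Individual:
    iid: str
    fid: str
    father: str | None
    mother: str | None
    sex: str = "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


def _norm_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return None if s in MISSING_PARENT else s


class Pedigree:
    """Validated pedigree with individuals in topological order.

    Parameters
    ----------
    members : list of Individual
        Must already be topologically sorted (parents before children).
        Use :meth:`build` to construct from raw records.
    """

    def __init__(self, members: list[Individual]):
        self.members = list(members)
        self._index = {m.iid: i for i, m in enumerate(self.members)}
        if len(self._index) != len(self.members):
            raise PedigreeError("duplicate individual ids in pedigree")

    # -- construction -------------------------------------------------

    @classmethod
    def build(cls, records) -> "Pedigree":
        """Build a validated pedigree from parent-link records.

        ``records`` is an iterable of mappings/tuples or a DataFrame with
        columns (family_id, individual_id, father_id, mother_id, sex).
        Referenced parents that have no record of their own are created
        as founders, with a warning.  A cycle (an individual that is its
        own ancestor) raises :class:`PedigreeError` naming the cycle.
        """
        raw = _coerce_records(records)
        if not raw:
            raise PedigreeError("pedigree records are empty")

        seen: dict[str, Individual] = {}
        for rec in raw:
            if rec.iid in seen:
                raise PedigreeError(f"duplicate individual id {rec.iid!r}")
            seen[rec.iid] = rec

        # materialise referenced-but-absent parents as founders
        for rec in list(seen.values()):
            for parent, sex in ((rec.father, "male"), (rec.mother, "female")):
                if parent is not None and parent not in seen:
                    warnings.warn(
                        f"parent {parent!r} of {rec.iid!r} has no record; "
                        "added as founder", stacklevel=2)
                    seen[parent] = Individual(parent, rec.fid, None, None, sex)

        for rec in seen.values():
            for parent in (rec.father, rec.mother):
                if parent is not None and seen[parent].fid != rec.fid:
                    raise PedigreeError(
                        f"parent {parent!r} of {rec.iid!r} belongs to family "
                        f"{seen[parent].fid!r}, not {rec.fid!r}")

        ordered = _topological_order(seen)
        return cls(ordered)

    @classmethod
    def from_fam(cls, path) -> "Pedigree":
        """Read a whitespace-delimited FAM-style file.

        Columns: family_id, individual_id, father_id, mother_id, sex,
        [phenotype...].  "0" or empty denotes a missing parent.
        """
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                         comment="#")
        if df.shape[1] < 4:
            raise PedigreeError(f"{path}: FAM file needs >= 4 columns")
        df = df.iloc[:, :5] if df.shape[1] >= 5 else df.assign(sex="0")
        df.columns = ["family_id", "individual_id", "father_id",
                      "mother_id", "sex"][: df.shape[1]]
        return cls.build(df)

    def to_fam(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            for m in self.members:
                sex = {"male": "1", "female": "2"}.get(m.sex, "0")
                fh.write(f"{m.fid}\t{m.iid}\t{m.father or '0'}"
                         f"\t{m.mother or '0'}\t{sex}\n")

    # -- accessors -----------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [m.iid for m in self.members]

    @property
    def n(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return self.n

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def __getitem__(self, iid: str) -> Individual:
        return self.members[self._index[iid]]

    @property
    def families(self) -> list[str]:
        out, seen = [], set()
        for m in self.members:
            if m.fid not in seen:
                seen.add(m.fid)
                out.append(m.fid)
        return out

    def family_members(self, fid: str) -> list[Individual]:
        return [m for m in self.members if m.fid == fid]

    @property
    def founder_mask(self):
        import numpy as np
        return np.array([m.is_founder for m in self.members])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "family_id": [m.fid for m in self.members],
            "individual_id": [m.iid for m in self.members],
            "father_id": [m.father for m in self.members],
            "mother_id": [m.mother for m in self.members],
            "sex": [m.sex for m in self.members],
        })


def build_pedigree(records) -> Pedigree:
    """Functional alias for :meth:`Pedigree.build`."""
    return Pedigree.build(records)


# ----------------------------------------------------------------------


def _coerce_records(records) -> list[Individual]:
    if isinstance(records, Pedigree):
        return list(records.members)
    if isinstance(records, pd.DataFrame):
        rows = records.to_dict("records")
    else:
        rows = list(records)
    out = []
    for row in rows:
        if isinstance(row, Individual):
            out.append(row)
            continue
        if isinstance(row, dict):
            fid = str(row.get("family_id", row.get("fid", "FAM1")))
            iid = str(row["individual_id"] if "individual_id" in row
                      else row["iid"])
            father = _norm_parent(row.get("father_id", row.get("father")))
            mother = _norm_parent(row.get("mother_id", row.get("mother")))
            sex = SEX_CODES.get(str(row.get("sex", "0")).strip(), "unknown")
        else:  # tuple-like: (individual_id, family_id, father, mother[, sex])
            iid, fid = str(row[0]), str(row[1])
            father, mother = _norm_parent(row[2]), _norm_parent(row[3])
            sex = SEX_CODES.get(str(row[4]).strip(), "unknown") \
                if len(row) > 4 else "unknown"
        out.append(Individual(iid, fid, father, mother, sex))
    return out


def _topological_order(seen: dict[str, Individual]) -> list[Individual]:
    """Kahn's algorithm; raises PedigreeError naming any cycle."""
    children: dict[str, list[str]] = {iid: [] for iid in seen}
    indeg = {iid: 0 for iid in seen}
    for rec in seen.values():
        for parent in (rec.father, rec.mother):
            if parent is not None:
                children[parent].append(rec.iid)
                indeg[rec.iid] += 1
    queue = [iid for iid, d in indeg.items() if d == 0]
    order: list[Individual] = []
    while queue:
        iid = queue.pop(0)
        order.append(seen[iid])
        for child in children[iid]:
            indeg[child] -= 1
            if indeg[child] == 0:
                queue.append(child)
    if len(order) != len(seen):
        cycle = sorted(iid for iid, d in indeg.items() if d > 0)
        raise PedigreeError(f"pedigree contains a cycle involving {cycle}")
    return order
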