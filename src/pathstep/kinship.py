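"""Theoretical kinship from pedigree structure.

The kinship coefficient ``phi_ij`` is the probability that an allele
drawn at random from individual *i* and one drawn at random from *j* are
identical by descent.  It is computed from the pedigree alone by the
classical recursion over a parents-before-children ordering:

* founders: ``phi_ii = 1/2`` and ``phi_ij = 0`` against anyone earlier,
* non-founder *i* with parents *f*, *m*:
  ``phi_ii = (1 + phi_fm) / 2`` and ``phi_ij = (phi_jf + phi_jm) / 2``
  for every *j* already processed.

``2 * phi`` is the familial covariance multiplier used by the linear
mixed model; it is block-diagonal across families (exact zeros between
families) and positive semi-definite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeError

__all__ = ["KinshipMatrix", "compute_kinship"]


class KinshipMatrix:
    """Ordered ids plus the dense kinship matrix ``phi``.

    Caches the eigendecomposition and Cholesky factor of ``2*phi``,
    which downstream REML fitting and polygenic simulation reuse across
    phenotype replicates.
    """

    def __init__(self, ids: list[str], phi: np.ndarray,
                 families: list[str] | None = None):
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (len(ids), len(ids)):
            raise ValueError("phi shape does not match ids")
        self.ids = list(ids)
        self.phi = phi
        self.families = list(families) if families is not None else None
        self._index = {iid: i for i, iid in enumerate(self.ids)}
        self._eig = None
        self._chol = None

    # -- linear-algebra caches ----------------------------------------

    @property
    def phi2(self) -> np.ndarray:
        """The covariance multiplier ``2*phi``."""
        return 2.0 * self.phi

    def eig(self):
        """Eigendecomposition ``2*phi = Q diag(lam) Q^T`` (cached).

        Eigenvalues in [-1e-8, 0) are clipped to 0; anything below
        -1e-8 fails the PSD contract.
        """
        if self._eig is None:
            lam, Q = np.linalg.eigh(self.phi2)
            if lam.min() < -1e-8:
                raise ValueError(
                    f"2*phi is not PSD (min eigenvalue {lam.min():.3g})")
            self._eig = (np.clip(lam, 0.0, None), Q)
        return self._eig

    def chol2(self, jitter: float = 1e-8) -> np.ndarray:
        """Lower Cholesky factor of ``2*phi + jitter*I`` (cached)."""
        if self._chol is None:
            a = self.phi2 + jitter * np.eye(len(self.ids))
            self._chol = np.linalg.cholesky(a)
        return self._chol

    # -- convenience ---------------------------------------------------

    def reindex(self, ids: list[str]) -> "KinshipMatrix":
        idx = [self._index[i] for i in ids]
        fam = ([self.families[i] for i in idx]
               if self.families is not None else None)
        return KinshipMatrix(list(ids), self.phi[np.ix_(idx, idx)], fam)

    def coefficient(self, a: str, b: str) -> float:
        return float(self.phi[self._index[a], self._index[b]])

    def to_long_frame(self) -> pd.DataFrame:
        n = len(self.ids)
        iu = np.triu_indices(n)
        return pd.DataFrame({
            "id1": [self.ids[i] for i in iu[0]],
            "id2": [self.ids[j] for j in iu[1]],
            "phi": self.phi[iu],
        })

    def write_tsv(self, path, fmt: str = "long") -> None:
        if fmt == "long":
            self.to_long_frame().to_csv(path, sep="\t", index=False)
        elif fmt == "square":
            pd.DataFrame(self.phi, index=self.ids,
                         columns=self.ids).to_csv(path, sep="\t")
        else:
            raise ValueError(f"unknown kinship format {fmt!r}")

    @classmethod
    def read_tsv(cls, path, fmt: str = "long") -> "KinshipMatrix":
        if fmt == "long":
            df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
            ids = list(dict.fromkeys(df["id1"].tolist() + df["id2"].tolist()))
            idx = {iid: i for i, iid in enumerate(ids)}
            phi = np.zeros((len(ids), len(ids)))
            for id1, id2, v in df.itertuples(index=False):
                phi[idx[id1], idx[id2]] = v
                phi[idx[id2], idx[id1]] = v
            return cls(ids, phi)
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy())


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix for a validated pedigree.

    Computed densely per family over the pedigree's topological order
    and assembled block-diagonally across families, preserving exact
    zeros between unrelated families.
    """
    if not isinstance(ped, Pedigree):
        raise PedigreeError("compute_kinship needs a validated Pedigree")
    n = ped.n
    phi = np.zeros((n, n))
    # members are topologically sorted globally; process each family's
    # members in that global order so parents always precede children
    fam_members: dict[str, list[int]] = {}
    for i, m in enumerate(ped.members):
        fam_members.setdefault(m.fid, []).append(i)

    for fid, idx in fam_members.items():
        local = {ped.members[g].iid: k for k, g in enumerate(idx)}
        k = len(idx)
        block = np.zeros((k, k))
        for a, g in enumerate(idx):
            m = ped.members[g]
            if m.is_founder:
                block[a, a] = 0.5
                continue
            f = local[m.father]
            mo = local[m.mother]
            block[a, a] = 0.5 * (1.0 + block[f, mo])
            for b in range(a):
                v = 0.5 * (block[b, f] + block[b, mo])
                block[a, b] = block[b, a] = v
        phi[np.ix_(idx, idx)] = block

    return KinshipMatrix(ped.ids, phi, families=[m.fid for m in ped.members])
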