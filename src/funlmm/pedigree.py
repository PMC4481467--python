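"""Pedigree structures and expected relationship matrices.

The relationship matrix R used by the mixed model is twice the kinship
matrix, so unrelated individuals give R = I and the polygenic variance
has its usual additive interpretation.  Genomic relationship matrices can
be supplied from a file instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Pedigree:
    """Ordered individuals with parent links.

    ``father``/``mother`` hold the index of each parent in ``ids`` or -1
    for founders.  Individuals with exactly one known parent get a dummy
    founder for the missing one at construction time.
    """

    ids: list[str]
    father: np.ndarray
    mother: np.ndarray
    family: list[str] = field(default_factory=list)
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids in pedigree")
        if not self.family:
            self.family = ["F1"] * n

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.father < 0) & (self.mother < 0)))

    def topological_order(self) -> np.ndarray:
        """Indices ordered so every parent precedes its offspring.

        Raises on cycles (an individual that is its own ancestor).
        """
        n = len(self)
        indeg = np.zeros(n, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for p in (self.father[i], self.mother[i]):
                if p >= 0:
                    indeg[i] += 1
                    children[p].append(i)
        order = [i for i in range(n) if indeg[i] == 0]
        head = 0
        while head < len(order):
            i = order[head]
            head += 1
            for ch in children[i]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    order.append(ch)
        if len(order) != n:
            raise ValueError("cycle detected in pedigree")
        return np.asarray(order)


@dataclass
class RelationshipMatrix:
    """Symmetric PSD expected-relationship matrix with aligned labels."""

    R: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("relationship matrix must be square")
        if R.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if np.max(np.abs(R - R.T)) > 1e-8:
            raise ValueError("relationship matrix is not symmetric")
        self.R = 0.5 * (R + R.T)

    def subset(self, labels: list[str]) -> "RelationshipMatrix":
        """Restrict to the given individuals, in the given order."""
        pos = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise KeyError(f"individuals absent from relationship matrix: {missing[:5]}")
        idx = np.array([pos[l] for l in labels])
        return RelationshipMatrix(self.R[np.ix_(idx, idx)], list(labels))


def kinship_from_pedigree(ped: Pedigree) -> RelationshipMatrix:
    """Expected relationship matrix R = 2 * kinship.

    Uses the standard recursion phi(i,i) = (1 + phi(f_i, m_i))/2 and
    phi(i,j) = (phi(f_i,j) + phi(m_i,j))/2, processing individuals in
    topological order.
    """
    n = len(ped)
    order = ped.topological_order()
    K = np.zeros((n, n))
    done = np.zeros(n, dtype=bool)
    processed: list[int] = []
    for i in order:
        f, m = ped.father[i], ped.mother[i]
        if f < 0 and m < 0:
            K[i, i] = 0.5
        else:
            K[i, i] = 0.5 + 0.5 * K[f, m]
        if processed:
            idx = np.asarray(processed)
            rowf = K[f, idx] if f >= 0 else 0.0
            rowm = K[m, idx] if m >= 0 else 0.0
            K[i, idx] = 0.5 * (rowf + rowm)
            K[idx, i] = K[i, idx]
        done[i] = True
        processed.append(i)
    return RelationshipMatrix(2.0 * K, list(ped.ids))


def read_pedigree(path) -> Pedigree:
    """Read a PED/FAM-style whitespace file.

    Columns: family_id individual_id father_id mother_id [sex ...];
    "0" marks a missing parent.  Half-known parent pairs are completed
    with a dummy founder.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 4:
        raise ValueError("pedigree file needs >= 4 columns (fam id father mother)")
    fam = df.iloc[:, 0].tolist()
    ids = df.iloc[:, 1].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in pedigree file")
    father_id = df.iloc[:, 2].tolist()
    mother_id = df.iloc[:, 3].tolist()
    sex = None
    if df.shape[1] >= 5:
        sex = pd.to_numeric(df.iloc[:, 4], errors="coerce").to_numpy()

    # complete half-known parents with dummy founders
    known = set(ids)
    extra_ids: list[str] = []
    extra_fam: list[str] = []
    for k, (fid, mid) in enumerate(zip(father_id, mother_id)):
        pair = [fid, mid]
        for slot, pid in enumerate(pair):
            if pid != "0" and pid not in known:
                raise ValueError(f"unknown parent identifier {pid!r}")
        if (fid == "0") != (mid == "0"):
            dummy = f"_dummy{len(extra_ids)}"
            extra_ids.append(dummy)
            extra_fam.append(fam[k])
            if fid == "0":
                father_id[k] = dummy
            else:
                mother_id[k] = dummy
    all_ids = ids + extra_ids
    all_fam = fam + extra_fam
    pos = {v: i for i, v in enumerate(all_ids)}
    father = np.array([pos.get(p, -1) if p != "0" else -1 for p in father_id]
                      + [-1] * len(extra_ids))
    mother = np.array([pos.get(p, -1) if p != "0" else -1 for p in mother_id]
                      + [-1] * len(extra_ids))
    if sex is not None and extra_ids:
        sex = np.concatenate([sex, np.full(len(extra_ids), np.nan)])
    ped = Pedigree(ids=all_ids, father=father, mother=mother,
                   family=all_fam, sex=sex)
    ped.topological_order()  # validates acyclicity
    return ped


def read_matrix(path) -> RelationshipMatrix:
    """Read a square labelled relationship matrix (tab-delimited; first
    row and column carry individual ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in df.columns]
    row_labels = [str(r) for r in df.index]
    if labels != row_labels:
        raise ValueError("matrix row and column labels disagree")
    R = df.to_numpy(dtype=float)
    if R.shape[0] != R.shape[1]:
        raise ValueError("relationship matrix file is not square")
    return RelationshipMatrix(R, labels)


def write_fam(ped: Pedigree, path) -> None:
    """Write the pedigree as a whitespace FAM file (phenotype column -9)."""
    with open(path, "w") as fh:
        for i, iid in enumerate(ped.ids):
            f = ped.ids[ped.father[i]] if ped.father[i] >= 0 else "0"
            m = ped.ids[ped.mother[i]] if ped.mother[i] >= 0 else "0"
            s = int(ped.sex[i]) if ped.sex is not None and np.isfinite(ped.sex[i]) else 0
            fh.write(f"{ped.family[i]} {iid} {f} {m} {s} -9\n")
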