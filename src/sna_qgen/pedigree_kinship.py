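"""Pedigree kinship: inbreeding, the additive relationship matrix A, and A-inverse.

The additive (numerator) relationship matrix A holds expected additive
genetic relationships between all pedigree members; its diagonal is
1 + F (the inbreeding coefficient).  The Gibbs sampler never needs dense A —
only its sparse inverse, which Henderson's rules build directly from parent
triplets, adjusted for parental inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class PedigreeTable:
    """Topologically sorted pedigree with 1-based integer codes.

    ``sire[i]``/``dam[i]`` are 0 for unknown parents and otherwise point to a
    smaller index than ``i + 1`` (parents precede offspring).  ``labels``
    retains the original identifiers in sorted order.
    """

    sire: np.ndarray          # int32, 0 = unknown
    dam: np.ndarray           # int32, 0 = unknown
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sire)
        if len(self.dam) != n:
            raise ValueError("sire/dam length mismatch")
        for i in range(n):
            for p in (self.sire[i], self.dam[i]):
                if p < 0 or p > n:
                    raise ValueError(f"parent code {p} out of range for animal {i + 1}")
                if p >= i + 1 and p != 0:
                    raise ValueError(
                        f"pedigree not sorted: animal {i + 1} has parent {p}"
                    )
        if not self.labels:
            self.labels = [str(i + 1) for i in range(n)]

    @property
    def n(self) -> int:
        return len(self.sire)

    @property
    def index_of(self) -> dict:
        """Original label -> 1-based sorted index."""
        return {lab: i + 1 for i, lab in enumerate(self.labels)}

    @classmethod
    def from_records(cls, animals, sires, dams) -> "PedigreeTable":
        """Build from label triplets, applying a stable topological sort.

        Unknown parents are ``"0"``, ``0``, ``""`` or None.  Parents that
        appear only as parents are appended as founders (phantom parents).
        Ties in the sort are broken by original file order, so indices are
        reproducible.
        """
        def norm(x):
            if x is None:
                return ""
            x = str(x).strip()
            return "" if x in ("0", "") else x

        animals = [str(a).strip() for a in animals]
        sires = [norm(s) for s in sires]
        dams = [norm(d) for d in dams]
        seen = set()
        for a in animals:
            if a in seen:
                raise ValueError(f"duplicated animal row {a!r}")
            seen.add(a)
        parents = {}
        order = {a: i for i, a in enumerate(animals)}
        for a, s, d in zip(animals, sires, dams):
            parents[a] = (s, d)
        # phantom parents become founders, ordered by first appearance
        extra = []
        for s, d in zip(sires, dams):
            for p in (s, d):
                if p and p not in parents and p not in extra:
                    extra.append(p)
        for j, p in enumerate(extra):
            parents[p] = ("", "")
            order[p] = -len(extra) + j  # founders first, stable
        # Kahn's algorithm, ties by original order
        import heapq

        children = {a: [] for a in parents}
        indeg = {a: 0 for a in parents}
        for a, (s, d) in parents.items():
            for p in (s, d):
                if p:
                    children[p].append(a)
                    indeg[a] += 1
        heap = [(order[a], a) for a in parents if indeg[a] == 0]
        heapq.heapify(heap)
        sorted_labels = []
        while heap:
            _, a = heapq.heappop(heap)
            sorted_labels.append(a)
            for ch in children[a]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    heapq.heappush(heap, (order[ch], ch))
        if len(sorted_labels) != len(parents):
            cyclic = sorted(a for a in parents if indeg[a] > 0)
            raise ValueError(f"pedigree cycle involving {cyclic[:5]}")
        idx = {a: i + 1 for i, a in enumerate(sorted_labels)}
        sire = np.zeros(len(sorted_labels), dtype=np.int32)
        dam = np.zeros(len(sorted_labels), dtype=np.int32)
        for a in sorted_labels:
            s, d = parents[a]
            i = idx[a] - 1
            sire[i] = idx[s] if s else 0
            dam[i] = idx[d] if d else 0
        return cls(sire=sire, dam=dam, labels=sorted_labels)

    def to_dataframe(self) -> pd.DataFrame:
        lab = np.asarray(self.labels, dtype=object)
        return pd.DataFrame({
            "animal": lab,
            "sire": [lab[s - 1] if s else "0" for s in self.sire],
            "dam": [lab[d - 1] if d else "0" for d in self.dam],
        })


def compute_inbreeding(ped: PedigreeTable, method: str = "meuwissen_luo") -> np.ndarray:
    """Inbreeding coefficients F (diagonal of A minus one).

    ``meuwissen_luo`` computes F without forming A, via the Cholesky-based
    recursion on Mendelian-sampling variances; ``tabular`` reads F off the
    dense tabular A (quadratic memory — small pedigrees only).  Both agree
    exactly.
    """
    if method == "tabular":
        A = build_A(ped).A
        return np.diag(A) - 1.0
    if method != "meuwissen_luo":
        raise ValueError(f"unknown method {method!r}")
    import heapq

    n = ped.n
    s = ped.sire
    d = ped.dam
    F = np.zeros(n)
    # For each animal walk its ancestors accumulating row i of the unit
    # Cholesky factor L of A = L D L'; then A_ii = sum_j L_ij^2 D_j and
    # F_i = A_ii - 1.  D_j is the Mendelian-sampling variance of j.
    for i in range(n):
        si, di = s[i], d[i]
        if si == 0 and di == 0:
            F[i] = 0.0
            continue
        L = {i + 1: 1.0}
        Fi = 0.0
        # process animals in decreasing index order so each L_ij is final
        heap = [-(i + 1)]
        inheap = {i + 1}
        while heap:
            j = -heapq.heappop(heap)
            inheap.discard(j)
            lj = L.pop(j)
            sj, dj = s[j - 1], d[j - 1]
            Dj = 1.0 - 0.25 * ((1.0 + F[sj - 1] if sj else 0.0)
                               + (1.0 + F[dj - 1] if dj else 0.0))
            Fi += lj * lj * Dj
            for p in (sj, dj):
                if p:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
                    if p not in inheap:
                        heapq.heappush(heap, -p)
                        inheap.add(p)
        F[i] = Fi - 1.0
    return F


def build_A(ped: PedigreeTable):
    """Dense additive relationship matrix by the tabular method.

    a_ii = 1 + 0.5 a_{s(i),d(i)};  a_ij = 0.5 (a_{j,s(i)} + a_{j,d(i)}) for
    j < i, with unknown-parent terms zero.  Quadratic in pedigree size; meant
    for founder populations, tests and debugging, not the full study pedigree.
    """
    n = ped.n
    A = np.zeros((n, n))
    s = ped.sire
    d = ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        row = np.zeros(n)
        if si:
            row += A[si - 1]
        if di:
            row += A[di - 1]
        row *= 0.5
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        A[i, i] = 1.0 + (0.5 * A[si - 1, di - 1] if (si and di) else 0.0)
    return AdditiveRelationshipMatrix(A=A, F=np.diag(A) - 1.0)


@dataclass
class AdditiveRelationshipMatrix:
    A: np.ndarray
    F: np.ndarray


def build_A_inverse(ped: PedigreeTable, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A-inverse by Henderson's rules with inbreeding adjustment.

    For animal i with Mendelian sampling variance
    d_i = 0.5 - 0.25 (F_s + F_d)   (both parents known)
        = 0.75 - 0.25 F_p          (one parent known)
        = 1                        (founder)
    add alpha_i = 1/d_i to (i,i), -alpha_i/2 to (i,p) for each known parent,
    and alpha_i/4 to every known-parent pair (p,p') including p = p'.
    """
    if F is None:
        F = compute_inbreeding(ped)
    n = ped.n
    rows, cols, vals = [], [], []
    for i in range(n):
        si, di = ped.sire[i], ped.dam[i]
        known = [p - 1 for p in (si, di) if p]
        dvar = 1.0 - sum(0.25 * (1.0 + F[p]) for p in known)
        alpha = 1.0 / dvar
        # alpha * u u' with u_i = 1 and u_p = -1/2 per known parent slot
        slots = [(i, 1.0)] + [(p, -0.5) for p in known]
        for a, ua in slots:
            for b, ub in slots:
                rows.append(a)
                cols.append(b)
                vals.append(alpha * ua * ub)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def export_kinship_debug(ped: PedigreeTable, path_prefix: str) -> None:
    """Write F and the A-inverse triplets as CSV for inspection."""
    F = compute_inbreeding(ped)
    pd.DataFrame({"animal": ped.labels, "F": F}).to_csv(
        f"{path_prefix}inbreeding.csv", index=False
    )
    Ainv = build_A_inverse(ped, F).tocoo()
    pd.DataFrame({"row": Ainv.row + 1, "col": Ainv.col + 1, "value": Ainv.data}).to_csv(
        f"{path_prefix}a_inverse.csv", index=False
    )
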