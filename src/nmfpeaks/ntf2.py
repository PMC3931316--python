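"""NTF2 decomposition of 3D spectra by repeated 2D NMF.

A 3D spectrum tensor ``Y`` (I x T x Q) is modelled slice-wise: every frontal
slice ``Y_q`` (the 2D plane at point q of the slab axis) shares one basis
matrix ``A`` (I x J) and has its own source matrix,

    Y_q = A D_q X_q' + N_q = A X_q + N_q,   q = 1..Q,

where ``D_q`` is a diagonal weight matrix and ``X_q'`` holds row-normalized
(unit l1) 1D source shapes.  Stacking the slices column-wise turns this into
a single 2D NMF problem ``[Y_1 ... Y_Q] = A [X_1 ... X_Q]``, which is how
the default ``shared_basis`` mode solves it.  The alternative
``independent_slices`` mode factorizes every slice separately and links
matching components across adjacent slices by the cosine similarity of
their basis columns.

The per-slice weights ``D_q`` of a component, read across q, are its 1D
profile along the slab axis — the third lineshape from which the third peak
coordinate is interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nmf import FactorPair, factorize, normalize_factors, preprocess
from .spectra_io import Spectrum

__all__ = [
    "Ntf2Factorization",
    "slice_tensor",
    "factorize_ntf2",
    "component_slab_profile",
    "link_components",
]


@dataclass
class Ntf2Factorization:
    """Shared basis A (I x J), per-slice sources Xq (Q of them, J x T),
    per-slice component weights D_q (rows of ``slice_scales``, Q x J),
    total squared residual over the tensor, global intensity scale, and the
    position of the slab axis in the original spectrum's axis order."""

    A: np.ndarray
    Xq: list[np.ndarray]
    slice_scales: np.ndarray  # (Q, J): D_q diagonal entries
    residual_tensor_norm: float
    scale: float
    slab_axis: int

    @property
    def n_components(self) -> int:
        return self.A.shape[1]

    @property
    def n_slices(self) -> int:
        return len(self.Xq)

    def reconstruct_slice(self, q: int, restore_scale: bool = True) -> np.ndarray:
        out = self.A @ self.Xq[q]
        return out * self.scale if restore_scale else out


def _tensor_data(S) -> np.ndarray:
    return S.data if isinstance(S, Spectrum) else np.asarray(S, dtype=float)


def slice_tensor(S, slab_axis: int = -1) -> list[np.ndarray]:
    """Frontal slices of a 3D spectrum: the 2D planes at each slab-axis point.

    Returns the Q matrices in slab-index order; the two remaining axes keep
    their relative order.
    """
    data = _tensor_data(S)
    if data.ndim != 3:
        raise ValueError(
            f"slice_tensor expects a 3D spectrum, got {data.ndim}D; "
            "use nmf.factorize for 2D data"
        )
    slab_axis = slab_axis % 3
    moved = np.moveaxis(data, slab_axis, 0)
    return [moved[q] for q in range(moved.shape[0])]


def _split_rows(Xq_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (D_q diagonal as J-vector, X_q) where D_q = row l1 norms."""
    d = Xq_raw.sum(axis=1)
    return d, Xq_raw


def _shared_basis(slices, J, scale, config):
    Yun = np.concatenate(slices, axis=1)  # I x (T*Q)
    pair, trace = factorize(Yun, J, scale=scale, **config)
    T = slices[0].shape[1]
    Xq = [pair.X[:, q * T:(q + 1) * T].copy() for q in range(len(slices))]
    return pair.A, Xq


def link_components(
    per_slice: list[FactorPair], similarity_floor: float = 0.9
) -> list[list[tuple[int, int]]]:
    """Chain components across adjacent slices by basis-column similarity.

    Greedy: for each pair of adjacent slices, links are made in decreasing
    order of the cosine similarity between the A-columns, refusing links
    below ``similarity_floor``.  Each resulting chain — a list of
    ``(slice_index, component_index)`` — is one 3D component; components
    that never link form single-slice chains.
    """
    if len(per_slice) < 2:
        raise ValueError("need at least two factorized slices to link")
    chains: list[list[tuple[int, int]]] = [
        [(0, j)] for j in range(per_slice[0].A.shape[1])
    ]
    open_chains = {j: j for j in range(per_slice[0].A.shape[1])}  # comp -> chain
    for q in range(1, len(per_slice)):
        prev_A, cur_A = per_slice[q - 1].A, per_slice[q].A
        norms_p = np.linalg.norm(prev_A, axis=0)
        norms_c = np.linalg.norm(cur_A, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = (prev_A.T @ cur_A) / np.outer(norms_p, norms_c)
        cos = np.nan_to_num(cos, nan=0.0)
        next_open: dict[int, int] = {}
        taken_prev: set[int] = set()
        taken_cur: set[int] = set()
        order = np.dstack(np.unravel_index(np.argsort(-cos, axis=None), cos.shape))[0]
        for jp, jc in order:
            jp, jc = int(jp), int(jc)
            if cos[jp, jc] < similarity_floor:
                break
            if jp in taken_prev or jc in taken_cur or jp not in open_chains:
                continue
            chain_id = open_chains[jp]
            chains[chain_id].append((q, jc))
            next_open[jc] = chain_id
            taken_prev.add(jp)
            taken_cur.add(jc)
        for jc in range(cur_A.shape[1]):
            if jc not in taken_cur:  # start a new chain
                chains.append([(q, jc)])
                next_open[jc] = len(chains) - 1
        open_chains = next_open
    return chains


def _independent_slices(slices, J, scale, config):
    seed = config.pop("seed", None)
    floor = config.pop("similarity_floor", 0.9)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(slices))]
    pairs = []
    for q, Yq in enumerate(slices):
        pair, _ = factorize(Yq, J, seed=seeds[q], scale=scale, **config)
        pairs.append(pair)
    chains = link_components(pairs, similarity_floor=floor)
    # keep the J strongest chains (by total linked source energy)
    def chain_weight(ch):
        return sum(pairs[q].X[j].sum() for q, j in ch)

    chains = sorted(chains, key=chain_weight, reverse=True)[:J]
    I = slices[0].shape[0]
    T = slices[0].shape[1]
    Q = len(slices)
    A = np.zeros((I, len(chains)))
    Xq = [np.zeros((len(chains), T)) for _ in range(Q)]
    for cid, ch in enumerate(chains):
        wsum = 0.0
        acc = np.zeros(I)
        for q, j in ch:
            w = pairs[q].X[j].sum()  # slice strength of the component
            acc += w * pairs[q].A[:, j]
            wsum += w
            Xq[q][cid] = pairs[q].X[j]
        if wsum > 0:
            acc /= wsum
        s = acc.sum()
        if s > 0:  # keep unit l1 basis columns; compensate in the sources
            acc /= s
            for q, _ in ch:
                Xq[q][cid] *= s
        A[:, cid] = acc
    return A, Xq


def factorize_ntf2(
    S,
    J: int,
    *,
    slab_axis: int = -1,
    mode: str = "shared_basis",
    similarity_floor: float = 0.9,
    seed: int | None = None,
    **config,
) -> Ntf2Factorization:
    """Decompose a 3D spectrum under the shared-basis slice model.

    Parameters
    ----------
    S : Spectrum or 3D array
        Raw spectrum; clipped to non-negative and unit-normalized here.
    J : int
        Number of components.
    slab_axis : int
        Axis treated as the slab (third) dimension; its planes are the
        frontal slices.  Defaults to the last stored (directly detected)
        axis.
    mode : {"shared_basis", "independent_slices"}
        ``shared_basis`` fits one A against the column-stacked slices (the
        exact slice model); ``independent_slices`` runs a separate 2D NMF
        per slice and links components across slices afterwards.
    """
    data = _tensor_data(S)
    if data.ndim != 3:
        raise ValueError(f"factorize_ntf2 expects 3D data, got {data.ndim}D")
    if J < 1:
        raise ValueError(f"J must be >= 1, got {J}")
    if mode not in ("shared_basis", "independent_slices"):
        raise ValueError(f"unknown mode {mode!r}")
    slab_axis = slab_axis % 3
    norm, scale = preprocess(data)
    slices = slice_tensor(norm, slab_axis)
    cfg = dict(config)
    cfg["seed"] = seed
    if mode == "shared_basis":
        A, Xq = _shared_basis(slices, J, scale, cfg)
    else:
        cfg["similarity_floor"] = similarity_floor
        A, Xq = _independent_slices(slices, J, scale, cfg)
    slice_scales = np.stack([x.sum(axis=1) for x in Xq])  # (Q, J) l1 row norms
    resid = float(sum(np.sum((Yq - A @ x) ** 2) for Yq, x in zip(slices, Xq)))
    return Ntf2Factorization(
        A=A,
        Xq=Xq,
        slice_scales=slice_scales,
        residual_tensor_norm=resid,
        scale=scale,
        slab_axis=slab_axis,
    )


def component_slab_profile(F: Ntf2Factorization, j: int) -> np.ndarray:
    """Per-slice weight of component j: its 1D profile along the slab axis."""
    if not 0 <= j < F.n_components:
        raise IndexError(f"component index {j} out of range ({F.n_components})")
    return F.slice_scales[:, j].copy()
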