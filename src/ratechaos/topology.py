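"""Random E/I network realizations shared by the spiking and rate engines.

Connectivity is fixed in-degree: every neuron receives exactly ``C_E``
excitatory and ``C_I`` inhibitory synapses drawn uniformly without
replacement within each population, with no self-connections and no
multiple connections between the same ordered pair.  An Erdős–Rényi mode
(each possible edge present with probability C/N) is provided as well; the
fixed in-degree mode is the default because the mean-field calculation
assumes identical input statistics for every neuron.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np

from .params import ModelParams

__all__ = ["NetworkTopology", "build_topology", "save_topology", "load_topology"]


@dataclasses.dataclass
class NetworkTopology:
    """Sparse signed connectivity realization.

    ``pre_indptr``/``pre_indices`` hold, per postsynaptic neuron, its
    presynaptic partners (CSR over rows = postsynaptic neurons);
    ``pre_weights`` the signed synaptic strengths in mV.  ``is_excitatory``
    labels the neuron populations (neurons ``0..N_E-1`` are excitatory).
    """

    N: int
    pre_indptr: np.ndarray   # (N+1,) int64
    pre_indices: np.ndarray  # (nnz,) int32, presynaptic ids
    pre_weights: np.ndarray  # (nnz,) float64, mV
    is_excitatory: np.ndarray  # (N,) bool
    params: ModelParams | None = None

    @property
    def nnz(self) -> int:
        return int(self.pre_indices.size)

    def in_degrees(self) -> np.ndarray:
        return np.diff(self.pre_indptr)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.pre_indices, minlength=self.N)

    def to_outgoing_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR over rows = presynaptic neurons: (indptr, targets, weights).

        This is the layout the event-driven engine consumes: a presynaptic
        spike is delivered to ``targets[indptr[j]:indptr[j+1]]``.
        """
        order = np.argsort(self.pre_indices, kind="stable")
        out_indptr = np.zeros(self.N + 1, dtype=np.int64)
        np.cumsum(np.bincount(self.pre_indices, minlength=self.N), out=out_indptr[1:])
        # row index (postsynaptic id) of each entry in the incoming CSR
        post = np.repeat(
            np.arange(self.N, dtype=np.int32), np.diff(self.pre_indptr).astype(np.int64)
        )
        return out_indptr, post[order], self.pre_weights[order]

    def weight_matrix(self):
        """The (N, N) sparse weight matrix W with W[i, j] the j→i strength."""
        from scipy import sparse

        return sparse.csr_matrix(
            (self.pre_weights, self.pre_indices, self.pre_indptr), shape=(self.N, self.N)
        )


def build_topology(params: ModelParams, mode: str = "fixed-indegree") -> NetworkTopology:
    """Generate a network realization; deterministic given ``params.seed``.

    Raises if the requested in-degree cannot be satisfied (e.g. more
    excitatory inputs than there are candidate excitatory partners).
    """
    N, C = params.N, params.C
    N_E, C_E, C_I = params.N_E, params.C_E, params.C_I
    if C_E > N_E - 1 or C_I > (N - N_E) - (0 if C_I == 0 else 1):
        raise ValueError(
            f"infeasible topology: need C_E={C_E} of {N_E} excitatory and "
            f"C_I={C_I} of {N - N_E} inhibitory partners without self-connections"
        )
    rng = np.random.default_rng(params.seed)
    is_exc = np.zeros(N, dtype=bool)
    is_exc[:N_E] = True

    if C == 0:
        indptr = np.zeros(N + 1, dtype=np.int64)
        return NetworkTopology(
            N, indptr, np.empty(0, np.int32), np.empty(0, np.float64), is_exc, params
        )

    if mode == "fixed-indegree":
        pre = np.empty((N, C), dtype=np.int32)
        for i in range(N):
            # excitatory partners, excluding i itself when i is excitatory
            if i < N_E:
                e = rng.choice(N_E - 1, size=C_E, replace=False).astype(np.int32)
                e[e >= i] += 1
            else:
                e = rng.choice(N_E, size=C_E, replace=False).astype(np.int32)
            if i >= N_E:
                h = rng.choice(N - N_E - 1, size=C_I, replace=False).astype(np.int32)
                h[h >= i - N_E] += 1
            else:
                h = rng.choice(N - N_E, size=C_I, replace=False).astype(np.int32)
            pre[i, :C_E] = e
            pre[i, C_E:] = h + N_E
        indptr = np.arange(N + 1, dtype=np.int64) * C
        pre = pre.ravel()
    elif mode == "erdos-renyi":
        p = C / N
        rows = []
        for i in range(N):
            mask = rng.random(N) < p
            mask[i] = False
            rows.append(np.flatnonzero(mask).astype(np.int32))
        counts = np.array([r.size for r in rows], dtype=np.int64)
        indptr = np.zeros(N + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        pre = np.concatenate(rows) if rows else np.empty(0, np.int32)
    else:
        raise ValueError(f"unknown topology mode {mode!r}")

    weights = np.where(is_exc[pre], params.J, -params.g * params.J)
    return NetworkTopology(N, indptr, pre, weights.astype(np.float64), is_exc, params)


def save_topology(path, top: NetworkTopology) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("pre_indptr", data=top.pre_indptr)
        f.create_dataset("pre_indices", data=top.pre_indices)
        f.create_dataset("pre_weights", data=top.pre_weights)
        f.create_dataset("is_excitatory", data=top.is_excitatory)
        if top.params is not None:
            for k, v in dataclasses.asdict(top.params).items():
                f.attrs[k] = v


def load_topology(path) -> NetworkTopology:
    with h5py.File(path, "r") as f:
        params = None
        if "N" in f.attrs:
            from .params import ModelParams as MP

            fields = {k: f.attrs[k] for k in f.attrs}
            fields["N"] = int(fields["N"])
            fields["C"] = int(fields["C"])
            fields["seed"] = int(fields["seed"])
            params = MP(**fields)
        return NetworkTopology(
            N=int(f["is_excitatory"].shape[0]),
            pre_indptr=f["pre_indptr"][:],
            pre_indices=f["pre_indices"][:],
            pre_weights=f["pre_weights"][:],
            is_excitatory=f["is_excitatory"][:].astype(bool),
            params=params,
        )
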