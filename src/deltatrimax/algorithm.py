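"""The delta-TRIMAX greedy triclustering algorithm.

A delta-tricluster is a subtensor whose mean-squared residue (MSR, see
:mod:`deltatrimax.tensor`) is at most a user threshold ``delta``.  Starting
from the full tensor, the algorithm alternates three greedy phases until no
further tricluster can be isolated:

1. *multiple node deletion* — batch-remove every gene/sample/time point whose
   per-node residue score exceeds ``lam * S`` (``lam > 1``); large modes only,
   controlled by ``deletion_guard``;
2. *single node deletion* — remove the single worst node at a time until
   ``S <= delta``;
3. *node addition* — re-admit any outside node whose residue score against the
   current cluster does not exceed its MSR, growing the cluster without
   raising its score.

Each reported tricluster is then *masked*: its cells in the working tensor are
replaced with uniform random values over the observed range so later
iterations find different structure.

``estimate_delta`` implements the K-means heuristic for choosing ``delta``
from the data: per sample plane, genes are clustered over their time profiles
and time points are clustered within each gene cluster; the minimum MSR over
randomly drawn (plane, gene-cluster, time-cluster) submatrices is taken as
``delta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .tensor import ExpressionTensor, Tricluster, TriclusterError, residue_array

__all__ = [
    "TrimaxParams",
    "TrimaxResult",
    "ParameterError",
    "DataError",
    "MSR_TOL",
    "impute_missing",
    "multiple_node_deletion",
    "single_node_deletion",
    "node_addition",
    "delta_trimax",
    "estimate_delta",
]

#: Absolute slack used in every ``S <= delta`` comparison.  A perfect shifting
#: block has an MSR of ~1e-28 rather than exactly 0 in double precision, and
#: the delta-estimation heuristic can legitimately return 0.0, so comparisons
#: at machine scale need a small absolute tolerance.
MSR_TOL = 1e-9


class ParameterError(ValueError):
    """Invalid algorithm parameters."""


class DataError(ValueError):
    """Unusable input data (e.g. a tensor with every cell missing)."""


@dataclass(frozen=True)
class TrimaxParams:
    """Tuning parameters of a delta-TRIMAX run.

    Attributes
    ----------
    delta
        Maximum allowable MSR of a reported tricluster (``>= 0``).
    lam
        Multiple-deletion threshold (``> 1``): a node is batch-deleted when
        its residue score exceeds ``lam * S``.  Values close to 1 delete
        aggressively.
    deletion_guard
        A mode whose current cardinality is at or below this value is skipped
        by the batch-deletion phase (single deletion still applies).
    max_triclusters
        Cap on outer masking iterations.
    min_genes, min_samples, min_times
        Floor sizes; no phase shrinks a mode below its floor.
    seed
        Seed for all randomness (imputation and masking).
    """

    delta: float
    lam: float = 1.2
    deletion_guard: int = 50
    max_triclusters: int = 50
    min_genes: int = 1
    min_samples: int = 1
    min_times: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ParameterError(f"delta must be >= 0, got {self.delta}")
        if self.lam <= 1:
            raise ParameterError(f"lam must be > 1, got {self.lam}")
        if self.deletion_guard < 1:
            raise ParameterError("deletion_guard must be >= 1")
        if self.max_triclusters < 1:
            raise ParameterError("max_triclusters must be >= 1")
        if min(self.min_genes, self.min_samples, self.min_times) < 1:
            raise ParameterError("floor sizes must be >= 1")

    @property
    def floors(self) -> tuple[int, int, int]:
        return (self.min_genes, self.min_samples, self.min_times)


@dataclass
class TrimaxResult:
    """Triclusters in discovery order plus per-iteration diagnostics."""

    triclusters: list[Tricluster]
    params: TrimaxParams
    iterations: list[dict[str, Any]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# internals operating on a raw values array and integer index arrays
# ---------------------------------------------------------------------------

def _scores(values: np.ndarray, I: np.ndarray, J: np.ndarray, K: np.ndarray):
    """(S, mu_gene, mu_sample, mu_time) of values restricted to I x J x K."""
    sub = values[np.ix_(I, J, K)]
    sq = residue_array(sub) ** 2
    return (float(sq.mean()), sq.mean(axis=(1, 2)), sq.mean(axis=(0, 2)),
            sq.mean(axis=(0, 1)))


def _multiple_node_deletion(values, I, J, K, params, trace=None):
    delta, lam = params.delta, params.lam
    guard = params.deletion_guard
    floors = params.floors
    while True:
        S, mu_g, mu_c, mu_t = _scores(values, I, J, K)
        if S <= delta + MSR_TOL:
            break
        changed = False
        for axis, mu in ((0, mu_g), (1, mu_c), (2, mu_t)):
            idx = (I, J, K)[axis]
            if len(idx) <= guard:
                continue
            drop = mu > lam * S
            n_drop = int(drop.sum())
            if n_drop == 0 or len(idx) - n_drop < floors[axis]:
                continue
            if trace is not None:
                trace.append({"phase": "multiple", "mode": axis, "S": S,
                              "deleted": idx[drop].tolist(),
                              "threshold": lam * S,
                              "mu": mu[drop].tolist()})
            kept = idx[~drop]
            if axis == 0:
                I = kept
            elif axis == 1:
                J = kept
            else:
                K = kept
            changed = True
            S, mu_g, mu_c, mu_t = _scores(values, I, J, K)
            if S <= delta + MSR_TOL:
                break
        if not changed or S <= delta + MSR_TOL:
            break
    return I, J, K


def _single_node_deletion(values, I, J, K, params, trace=None):
    delta = params.delta
    floors = params.floors
    while True:
        S, mu_g, mu_c, mu_t = _scores(values, I, J, K)
        if S <= delta + MSR_TOL:
            return I, J, K, S, False
        best_axis = -1
        best_mu = -np.inf
        best_pos = -1
        # modes in gene, sample, time order; strict > keeps the earlier mode
        # on ties; np.argmax keeps the smallest index within a mode.
        for axis, mu in ((0, mu_g), (1, mu_c), (2, mu_t)):
            if len((I, J, K)[axis]) <= floors[axis]:
                continue
            pos = int(np.argmax(mu))
            if mu[pos] > best_mu:
                best_axis, best_mu, best_pos = axis, float(mu[pos]), pos
        if best_axis < 0:  # every mode at its floor and S still > delta
            return I, J, K, S, True
        idx = (I, J, K)[best_axis]
        if trace is not None:
            trace.append({"phase": "single", "mode": best_axis, "S": S,
                          "deleted": int(idx[best_pos]), "mu": best_mu})
        kept = np.delete(idx, best_pos)
        if best_axis == 0:
            I = kept
        elif best_axis == 1:
            J = kept
        else:
            K = kept


def _node_addition(values, I, J, K, trace=None):
    G, C, T = values.shape
    while True:
        changed = False
        for axis, size in ((0, G), (1, C), (2, T)):
            sub = values[np.ix_(I, J, K)]
            gm = sub.mean(axis=(1, 2))
            cm = sub.mean(axis=(0, 2))
            tm = sub.mean(axis=(0, 1))
            g = sub.mean()
            S = float((residue_array(sub) ** 2).mean())
            inside = (I, J, K)[axis]
            outside = np.setdiff1d(np.arange(size), inside,
                                   assume_unique=True)
            if outside.size == 0:
                continue
            # residue score of each outside node against the current cluster:
            # its own marginal mean over the cluster's other two index sets,
            # with the cluster's remaining means and grand mean.
            if axis == 0:
                block = values[np.ix_(outside, J, K)]
                own = block.mean(axis=(1, 2))
                res = (block - own[:, None, None] - cm[None, :, None]
                       - tm[None, None, :] + 2.0 * g)
                scores = (res ** 2).mean(axis=(1, 2))
            elif axis == 1:
                block = values[np.ix_(I, outside, K)]
                own = block.mean(axis=(0, 2))
                res = (block - gm[:, None, None] - own[None, :, None]
                       - tm[None, None, :] + 2.0 * g)
                scores = (res ** 2).mean(axis=(0, 2))
            else:
                block = values[np.ix_(I, J, outside)]
                own = block.mean(axis=(0, 1))
                res = (block - gm[:, None, None] - cm[None, :, None]
                       - own[None, None, :] + 2.0 * g)
                scores = (res ** 2).mean(axis=(0, 1))
            add = outside[scores <= S + MSR_TOL]
            if add.size == 0:
                continue
            if trace is not None:
                trace.append({"phase": "addition", "mode": axis, "S": S,
                              "added": add.tolist()})
            merged = np.sort(np.concatenate([inside, add]))
            if axis == 0:
                I = merged
            elif axis == 1:
                J = merged
            else:
                K = merged
            changed = True
        if not changed:
            return I, J, K


def _as_arrays(tc: Tricluster):
    return (np.asarray(tc.gene_idx, dtype=np.intp),
            np.asarray(tc.sample_idx, dtype=np.intp),
            np.asarray(tc.time_idx, dtype=np.intp))


def _to_tricluster(values, I, J, K) -> Tricluster:
    S, _, _, _ = _scores(values, I, J, K)
    return Tricluster(tuple(I.tolist()), tuple(J.tolist()), tuple(K.tolist()),
                      msr=S)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def impute_missing(tensor: ExpressionTensor, seed: int) -> ExpressionTensor:
    """Fill masked cells with uniform draws over the observed value range.

    Returns the input unchanged when nothing is missing; otherwise a new
    tensor whose masked cells hold ``Uniform[observed min, observed max]``
    draws (deterministic given ``seed``).  The mask is preserved so the
    provenance of imputed cells is not lost.
    """
    mask = tensor.missing_mask
    if not mask.any():
        return tensor
    observed = tensor.values[~mask]
    if observed.size == 0:
        raise DataError("every cell is missing; nothing to impute from")
    rng = np.random.default_rng(seed)
    values = tensor.values.copy()
    values[mask] = rng.uniform(observed.min(), observed.max(),
                               size=int(mask.sum()))
    return ExpressionTensor(values, tensor.gene_ids, tensor.sample_ids,
                            tensor.time_labels, missing_mask=mask)


def multiple_node_deletion(tensor: ExpressionTensor, start: Tricluster,
                           params: TrimaxParams,
                           trace: list | None = None) -> Tricluster:
    """Batch-delete nodes with residue score ``> lam * S`` until coherent.

    Modes at or below ``params.deletion_guard`` in size are left untouched;
    a batch that would shrink a mode below its floor is skipped that round.
    """
    tensor._check_bounds(start)
    I, J, K = _as_arrays(start)
    I, J, K = _multiple_node_deletion(tensor.values, I, J, K, params, trace)
    return _to_tricluster(tensor.values, I, J, K)


def single_node_deletion(tensor: ExpressionTensor, start: Tricluster,
                         params: TrimaxParams,
                         trace: list | None = None) -> Tricluster:
    """Delete the single worst node at a time until ``S <= delta``.

    Ties across modes prefer gene, then sample, then time; ties within a
    mode prefer the smallest index.  Modes at their floor size are excluded;
    if every mode is at its floor and ``S > delta`` the current (at-floor)
    tricluster is returned.
    """
    tensor._check_bounds(start)
    I, J, K = _as_arrays(start)
    I, J, K, S, _ = _single_node_deletion(tensor.values, I, J, K, params,
                                          trace)
    return Tricluster(tuple(I.tolist()), tuple(J.tolist()),
                      tuple(K.tolist()), msr=S)


def node_addition(tensor: ExpressionTensor, core: Tricluster,
                  trace: list | None = None) -> Tricluster:
    """Grow a coherent core with every outside node scoring ``<= S``.

    Iterates gene, sample and time additions to a fixed point.  The result
    contains the core and its MSR never exceeds the core's MSR.
    """
    tensor._check_bounds(core)
    I, J, K = _as_arrays(core)
    I, J, K = _node_addition(tensor.values, I, J, K, trace)
    return _to_tricluster(tensor.values, I, J, K)


def delta_trimax(tensor: ExpressionTensor,
                 params: TrimaxParams) -> TrimaxResult:
    """Run the full masking loop and return all discovered delta-triclusters.

    Missing cells are imputed first.  Each iteration runs the three phases on
    the working copy, records the resulting tricluster (scored on the working
    copy, whose covered cells are snapshotted into the iteration diagnostics),
    then masks its cells with uniform random values over the observed range.

    Stops when single deletion bottoms out at the floor with ``S > delta``,
    when the deletion phases return the full remaining tensor twice in a row
    (the data is exhausted and refills are being re-reported), or after
    ``max_triclusters`` iterations.  Bit-reproducible given ``params.seed``.
    """
    ss = np.random.SeedSequence(params.seed)
    impute_seed, mask_seed = [int(s) for s in ss.generate_state(2) >> 1]
    work = impute_missing(tensor, impute_seed)
    observed = tensor.values[~tensor.missing_mask]
    if observed.size == 0:
        raise DataError("every cell is missing")
    lo, hi = float(observed.min()), float(observed.max())
    rng = np.random.default_rng(mask_seed)

    D = work.values.copy()
    G, C, T = D.shape
    full_I = np.arange(G, dtype=np.intp)
    full_J = np.arange(C, dtype=np.intp)
    full_K = np.arange(T, dtype=np.intp)
    floors = params.floors

    result = TrimaxResult(triclusters=[], params=params)
    consecutive_full = 0
    for it in range(params.max_triclusters):
        trace: list = []
        I, J, K = _multiple_node_deletion(D, full_I, full_J, full_K, params,
                                          trace)
        I, J, K, S, at_floor = _single_node_deletion(D, I, J, K, params,
                                                     trace)
        diag: dict[str, Any] = {"iteration": it, "trace": trace}
        if at_floor and S > params.delta + MSR_TOL:
            diag["stop"] = "deletion bottomed out above delta"
            result.iterations.append(diag)
            break
        if (len(I), len(J), len(K)) == floors:
            diag["stop"] = "tricluster at floor size in every mode"
            result.iterations.append(diag)
            break
        is_full = (len(I), len(J), len(K)) == (G, C, T)
        if is_full:
            consecutive_full += 1
            if consecutive_full >= 2:
                diag["stop"] = "full tensor returned twice in a row"
                result.iterations.append(diag)
                break
        else:
            consecutive_full = 0
        core_shape = (len(I), len(J), len(K))
        I, J, K = _node_addition(D, I, J, K, trace)
        tc = _to_tricluster(D, I, J, K)
        diag.update({
            "shape": tc.shape,
            "msr": tc.msr,
            "grew": tc.shape != core_shape,
            "data": D[np.ix_(I, J, K)].copy(),
        })
        result.iterations.append(diag)
        result.triclusters.append(tc)
        # masking: refill the whole reported box with in-range random values
        D[np.ix_(I, J, K)] = rng.uniform(lo, hi, size=tc.shape)
    return result


def estimate_delta(tensor: ExpressionTensor, k_genes: int | None = None,
                   k_times: int | None = None, trials: int | None = None,
                   seed: int = 0) -> float:
    """K-means heuristic for choosing ``delta`` from the data.

    Per sample plane, genes are K-means-partitioned on their time profiles
    into ``k_genes`` clusters; within each gene cluster the time points are
    partitioned into ``k_times`` clusters.  Each (plane, gene-cluster,
    time-cluster) triple induces a single-sample submatrix; the minimum MSR
    over the probed triples is returned — an estimate of the residue level of
    the most coherent module-sized submatrix in the data.

    With ``trials=None`` (default) every induced submatrix is evaluated,
    which is cheaper than the clustering step itself and gives the sharpest,
    least noisy minimum; an integer ``trials`` instead draws that many
    triples at random (seeded), whose minimum is an upward-biased estimate
    that is non-increasing in ``trials``.

    Cluster counts default to ``max(2, G // 10)`` gene clusters and
    ``max(2, T // 4)`` time clusters, so that a typical cell has the
    granularity of a minimal coherent module (a handful of genes over a few
    time points); coarse partitions would only ever probe background-sized
    submatrices, whose MSR reflects noise rather than coherence.  Cells with
    fewer than two genes or two time points are excluded: their MSR is
    identically zero for any data and carries no information.

    The returned value is an extreme order statistic: on data with implanted
    near-perfect structure it lands at or below the smallest genuinely
    coherent submatrix, which is its intended use.  For data whose modules
    carry substantial noise, set ``delta`` near the expected within-module
    residue level (about the noise variance) instead.
    """
    from sklearn.cluster import KMeans

    G, C, T = tensor.shape
    if k_genes is None:
        k_genes = max(2, G // 10)
    if k_times is None:
        k_times = max(2, T // 4)
    if k_genes < 2 or k_genes > G:
        raise ParameterError(f"k_genes must be in [2, {G}], got {k_genes}")
    if k_times < 2 or k_times > T:
        raise ParameterError(f"k_times must be in [2, {T}], got {k_times}")
    if trials is not None and trials < 1:
        raise ParameterError("trials must be >= 1")

    ss = np.random.SeedSequence(seed)
    trial_rng = np.random.default_rng(int(ss.generate_state(1)[0] >> 1))
    km_states = iter(int(s >> 1) for s in
                     np.random.SeedSequence((seed, 1)).generate_state(
                         C * (1 + k_genes)))
    values = tensor.values

    # eligible cells: (plane, gene set, time set) with >= 2 genes and times
    cells: list[tuple[int, np.ndarray, np.ndarray]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points trip KMeans warnings
        for j in range(C):
            plane = values[:, j, :]  # G x T
            g_labels = KMeans(n_clusters=k_genes, n_init=10,
                              random_state=next(km_states)).fit_predict(plane)
            for a in range(k_genes):
                genes = np.flatnonzero(g_labels == a)
                if genes.size == 0:
                    next(km_states)
                    continue
                t_feats = plane[genes, :].T  # T x |genes|
                t_labels = KMeans(n_clusters=min(k_times, T), n_init=10,
                                  random_state=next(km_states)
                                  ).fit_predict(t_feats)
                if genes.size < 2:
                    continue
                for b in range(k_times):
                    times = np.flatnonzero(t_labels == b)
                    if times.size >= 2:
                        cells.append((j, genes, times))
    if not cells:
        raise DataError("no non-degenerate (gene cluster, time cluster) "
                        "submatrix available; lower k_genes/k_times")

    if trials is None:
        probe = cells
    else:
        probe = [cells[int(trial_rng.integers(len(cells)))]
                 for _ in range(trials)]
    best = np.inf
    for j, genes, times in probe:
        sub = values[np.ix_(genes, [j], times)]
        S = float((residue_array(sub) ** 2).mean())
        best = min(best, S)
    return best
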