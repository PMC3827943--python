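"""3D expression tensors and additive-coherence (mean-squared-residue) mathematics.

A time-series expression experiment measuring G genes in C samples at T time
points is modelled as a dense tensor ``D`` of shape ``(G, C, T)``, cell
``d[i, j, k]`` holding the expression of gene *i* in sample *j* at time *k*.
A *tricluster* is a subtensor ``M(I, J, K)`` — a subset of genes coexpressed
over a subset of samples across a subset of time points.

Coherence of a tricluster is judged against the additive *shifting* model

    m[i, j, k] = Gamma + alpha_i + beta_j + eta_k

whose least-squares fit on a full factorial block is given by the marginal
means.  The residue of a cell is

    r[i, j, k] = m[i, j, k] - m_iJK - m_IjK - m_IJk + 2 * m_IJK

where ``m_iJK`` is the mean of gene *i* over ``J x K`` (likewise ``m_IjK``,
``m_IJk``) and ``m_IJK`` the grand mean.  The mean-squared residue (MSR)

    S = mean over (i, j, k) of r[i, j, k] ** 2

is zero exactly when the block is a perfect shifting tricluster; lower S
means stronger coherence.  Everything else in this package is built on the
three functions here: :func:`subtensor_stats`, :func:`msr` and
:func:`mode_scores`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ExpressionTensor",
    "Tricluster",
    "SubtensorStats",
    "TriclusterError",
    "subtensor_stats",
    "msr",
    "mode_scores",
    "MODES",
]

MODES = ("gene", "sample", "time")


class TriclusterError(ValueError):
    """Raised for invalid triclusters (empty or out-of-bounds index sets)."""


def _unique_sorted(idx: Iterable[int]) -> tuple[int, ...]:
    out = tuple(sorted(int(i) for i in idx))
    if len(set(out)) != len(out):
        raise TriclusterError(f"duplicate indices in {out!r}")
    return out


@dataclass(frozen=True)
class Tricluster:
    """Index sets ``I``, ``J``, ``K`` of a subtensor, plus its MSR score ``S``.

    Index sets are stored sorted ascending (0-based) so that outputs are
    deterministic and directly comparable.  ``msr`` is ``None`` until scored.
    """

    gene_idx: tuple[int, ...]
    sample_idx: tuple[int, ...]
    time_idx: tuple[int, ...]
    msr: float | None = None

    def __post_init__(self) -> None:
        for name in ("gene_idx", "sample_idx", "time_idx"):
            idx = _unique_sorted(getattr(self, name))
            if not idx:
                raise TriclusterError(f"empty {name}: a tricluster needs >= 1 "
                                      "gene, sample and time point")
            if idx[0] < 0:
                raise TriclusterError(f"negative index in {name}: {idx[0]}")
            object.__setattr__(self, name, idx)
        if self.msr is not None:
            object.__setattr__(self, "msr", float(self.msr))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.gene_idx), len(self.sample_idx), len(self.time_idx))

    @property
    def volume(self) -> int:
        g, c, t = self.shape
        return g * c * t

    def same_indices(self, other: "Tricluster") -> bool:
        """True when both triclusters cover exactly the same index box."""
        return (self.gene_idx == other.gene_idx
                and self.sample_idx == other.sample_idx
                and self.time_idx == other.time_idx)


@dataclass(frozen=True)
class ExpressionTensor:
    """A labelled ``(G, C, T)`` expression tensor with a missing-value mask.

    Parameters
    ----------
    values
        Real array of shape ``(G, C, T)``; cells flagged in ``missing_mask``
        may be non-finite until imputation.
    gene_ids, sample_ids
        Unique string labels for the gene and sample axes.
    time_labels
        Strictly increasing numeric time values (hours).
    missing_mask
        Boolean array of the same shape, ``True`` where the original input
        had no value.  Defaults to all-``False``.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    time_labels: tuple[float, ...]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError(f"values must be a non-empty 3D array, got shape "
                             f"{values.shape}")
        object.__setattr__(self, "values", values)
        for name, labels in (("gene_ids", self.gene_ids),
                             ("sample_ids", self.sample_ids)):
            labels = tuple(str(x) for x in labels)
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate labels in {name}")
            object.__setattr__(self, name, labels)
        times = tuple(float(t) for t in self.time_labels)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time_labels must be strictly increasing")
        object.__setattr__(self, "time_labels", times)
        expected = (len(self.gene_ids), len(self.sample_ids), len(times))
        if values.shape != expected:
            raise ValueError(f"values shape {values.shape} does not match "
                             f"labels {expected}")
        mask = self.missing_mask
        if mask is None:
            mask = np.zeros(values.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != values.shape:
                raise ValueError("missing_mask shape mismatch")
        object.__setattr__(self, "missing_mask", mask)
        if not np.isfinite(values[~mask]).all():
            raise ValueError("non-finite values outside the missing mask")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def full_tricluster(self) -> Tricluster:
        """The tricluster covering the entire tensor."""
        return Tricluster(tuple(range(self.n_genes)),
                          tuple(range(self.n_samples)),
                          tuple(range(self.n_times)))

    def subtensor(self, tc: Tricluster) -> np.ndarray:
        """Copy of the values restricted to ``I x J x K``."""
        self._check_bounds(tc)
        return self.values[np.ix_(tc.gene_idx, tc.sample_idx, tc.time_idx)]

    def _check_bounds(self, tc: Tricluster) -> None:
        G, C, T = self.shape
        if tc.gene_idx[-1] >= G or tc.sample_idx[-1] >= C or tc.time_idx[-1] >= T:
            raise TriclusterError(
                f"tricluster indices out of bounds for tensor of shape "
                f"{self.shape}: max indices "
                f"({tc.gene_idx[-1]}, {tc.sample_idx[-1]}, {tc.time_idx[-1]})")

    # -- label helpers -----------------------------------------------------
    def gene_labels(self, idx: Sequence[int]) -> tuple[str, ...]:
        return tuple(self.gene_ids[i] for i in idx)

    def sample_labels(self, idx: Sequence[int]) -> tuple[str, ...]:
        return tuple(self.sample_ids[j] for j in idx)

    def time_values(self, idx: Sequence[int]) -> tuple[float, ...]:
        return tuple(self.time_labels[k] for k in idx)


@dataclass(frozen=True)
class SubtensorStats:
    """Marginal means and residues of one tricluster.

    ``residues`` is the ``|I| x |J| x |K|`` array ``r[i, j, k]``; by
    construction its overall mean is zero and ``mean(residues ** 2)`` equals
    the tricluster's MSR.
    """

    gene_means: np.ndarray
    sample_means: np.ndarray
    time_means: np.ndarray
    grand_mean: float
    residues: np.ndarray

    @property
    def msr(self) -> float:
        return float(np.mean(self.residues ** 2))


# ---------------------------------------------------------------------------
# core math (also usable on raw subarrays; the algorithm module calls these)
# ---------------------------------------------------------------------------

def residue_array(sub: np.ndarray) -> np.ndarray:
    """Residues of a raw 3D subarray under the additive shifting model."""
    gm = sub.mean(axis=(1, 2))
    cm = sub.mean(axis=(0, 2))
    tm = sub.mean(axis=(0, 1))
    g = sub.mean()
    return sub - gm[:, None, None] - cm[None, :, None] - tm[None, None, :] + 2.0 * g


def subtensor_stats(tensor: ExpressionTensor, tc: Tricluster) -> SubtensorStats:
    """All four mean families and the residue array of a tricluster."""
    sub = tensor.subtensor(tc)
    gm = sub.mean(axis=(1, 2))
    cm = sub.mean(axis=(0, 2))
    tm = sub.mean(axis=(0, 1))
    g = float(sub.mean())
    res = sub - gm[:, None, None] - cm[None, :, None] - tm[None, None, :] + 2.0 * g
    return SubtensorStats(gene_means=gm, sample_means=cm, time_means=tm,
                          grand_mean=g, residues=res)


def msr(tensor: ExpressionTensor, tc: Tricluster) -> float:
    """Mean-squared residue ``S`` of a tricluster (0 iff perfectly shifting)."""
    sub = tensor.subtensor(tc)
    res = residue_array(sub)
    return float(np.mean(res * res))


def mode_scores(tensor: ExpressionTensor, tc: Tricluster, mode: str) -> np.ndarray:
    """Per-node residue scores ``mu`` along one mode of a tricluster.

    For ``mode="gene"`` this is ``mu(i) = mean over (j, k) of r[i,j,k]**2``
    for each ``i`` in ``I`` (analogously for samples and time points).  The
    unweighted mean of the scores along any mode equals the MSR.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    sub = tensor.subtensor(tc)
    sq = residue_array(sub) ** 2
    axis = {"gene": (1, 2), "sample": (0, 2), "time": (0, 1)}[mode]
    return sq.mean(axis=axis)
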