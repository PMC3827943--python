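"""Per-tricluster eigengenes, hub genes, and gene-set enrichment.

The *eigengene* of a tricluster summarizes its expression: each gene's
subtensor values are flattened to a row of length ``|J|*|K|`` (sample-major),
rows are standardized to mean 0 / variance 1, and the top right-singular
vector of the resulting matrix is taken as the cluster's representative
profile.  *Membership* of a gene is its Pearson correlation with the
eigengene; the top-correlated genes (15 by convention) are the cluster's
*hub genes*.

``enrichment_test`` is a generic hypergeometric gene-set over-representation
test with Benjamini-Hochberg or Benjamini-Yekutieli FDR correction, usable
with any named gene-set collection (e.g. transcription-factor target sets in
GMT form).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .tensor import ExpressionTensor, Tricluster

__all__ = [
    "EigengeneResult",
    "EnrichmentResult",
    "PostprocessError",
    "eigengene",
    "hub_genes",
    "enrichment_test",
]

CORRECTIONS = {"BH": "fdr_bh", "BY": "fdr_by"}


class PostprocessError(ValueError):
    pass


@dataclass(frozen=True)
class EigengeneResult:
    """Eigengene vector, SVD spectrum and per-gene memberships.

    ``eigengene`` has unit Euclidean norm and length ``|J|*|K|``; its sign is
    fixed so the mean membership is non-negative.  ``flatten_order`` records
    the (sample_id, time_label) pair of each flattened column.
    """

    eigengene: np.ndarray
    singular_values: np.ndarray
    explained_fraction: float
    memberships: dict[str, float]
    flatten_order: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set hypergeometric enrichment table plus the correction used."""

    table: pd.DataFrame  # set, overlap, set_size, cluster_size, universe_size,
    #                      p_value, adjusted_p, significant
    correction: str
    alpha: float


def _flatten_rows(tensor: ExpressionTensor, tc: Tricluster) -> np.ndarray:
    sub = tensor.subtensor(tc)                       # |I| x |J| x |K|
    return sub.reshape(sub.shape[0], -1)             # sample-major columns


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    nonconstant = sd[:, 0] > 0
    Z = np.zeros_like(X)
    if nonconstant.any():
        Z[nonconstant] = (X[nonconstant] - mean[nonconstant]) / sd[nonconstant]
    return Z, nonconstant


def eigengene(tensor: ExpressionTensor, tc: Tricluster) -> EigengeneResult:
    """Top right-singular vector of the standardized gene x (sample*time)
    matrix of a tricluster, with per-gene Pearson memberships.

    Constant (zero-variance) gene rows become all-zero rows: they receive
    membership 0 and do not participate in the sign convention.  Raises
    :class:`PostprocessError` when every row is constant.
    """
    X = _flatten_rows(tensor, tc)
    Z, nonconstant = _standardize_rows(X)
    if not nonconstant.any():
        raise PostprocessError("degenerate tricluster: every gene profile is "
                               "constant, no eigengene exists")
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    e = e / np.linalg.norm(e)
    labels = tensor.gene_labels(tc.gene_idx)
    corr = _row_correlations(Z, e, nonconstant)
    if corr[nonconstant].mean() < 0:
        e = -e
        corr = -corr
        corr[~nonconstant] = 0.0
    memberships = {lab: float(c) for lab, c in zip(labels, corr)}
    order = tuple((tensor.sample_ids[j], tensor.time_labels[k])
                  for j in tc.sample_idx for k in tc.time_idx)
    return EigengeneResult(
        eigengene=e,
        singular_values=s,
        explained_fraction=float(s[0] ** 2 / np.sum(s ** 2)),
        memberships=memberships,
        flatten_order=order,
    )


def _row_correlations(Z: np.ndarray, e: np.ndarray,
                      nonconstant: np.ndarray) -> np.ndarray:
    ec = e - e.mean()
    en = np.linalg.norm(ec)
    corr = np.zeros(Z.shape[0])
    if en > 0:
        # rows of Z are standardized (mean 0), so Pearson r = z . ec / (|z||ec|)
        norms = np.linalg.norm(Z, axis=1)
        ok = nonconstant & (norms > 0)
        corr[ok] = (Z[ok] @ ec) / (norms[ok] * en)
    corr = np.clip(corr, -1.0, 1.0)
    return corr


def hub_genes(tensor: ExpressionTensor, tc: Tricluster,
              top_n: int = 15) -> list[tuple[str, float]]:
    """Top ``top_n`` genes of a tricluster by membership (Pearson correlation
    with the eigengene), descending; ties broken by gene label ascending."""
    if top_n < 1:
        raise PostprocessError("top_n must be >= 1")
    result = eigengene(tensor, tc)
    ranked = sorted(result.memberships.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def enrichment_test(cluster_genes: set[str],
                    gene_sets: Mapping[str, Sequence[str]],
                    universe: set[str],
                    correction: str = "BY",
                    alpha: float = 0.05) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test per gene set.

    Each gene set is intersected with the universe; the p-value is the
    probability of observing at least the seen overlap when drawing
    ``|cluster|`` genes from the universe with ``|set|`` of them marked.
    P-values are adjusted with Benjamini-Hochberg (``"BH"``) or
    Benjamini-Yekutieli (``"BY"``); sets with adjusted p <= ``alpha`` are
    flagged significant.
    """
    if correction not in CORRECTIONS:
        raise PostprocessError(f"correction must be one of "
                               f"{tuple(CORRECTIONS)}")
    universe = set(universe)
    cluster = set(cluster_genes)
    outside = cluster - universe
    if outside:
        raise PostprocessError("cluster genes outside the universe: "
                               f"{sorted(outside)}")
    M, N = len(universe), len(cluster)
    rows = []
    for name, members in gene_sets.items():
        marked = set(members) & universe
        n = len(marked)
        k = len(cluster & marked)
        p = float(hypergeom.sf(k - 1, M, n, N))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append((name, k, n, N, M, p))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                        "cluster_size", "universe_size",
                                        "p_value"])
    if len(table):
        _, adj, _, _ = multipletests(table["p_value"].to_numpy(),
                                     method=CORRECTIONS[correction])
        table["adjusted_p"] = np.minimum(1.0, adj)
        table["adjusted_p"] = np.maximum(table["adjusted_p"],
                                         table["p_value"])
        table["significant"] = table["adjusted_p"] <= alpha
        table = table.sort_values("p_value", kind="stable",
                                  ignore_index=True)
    else:
        table["adjusted_p"] = []
        table["significant"] = []
    return EnrichmentResult(table=table, correction=correction, alpha=alpha)
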