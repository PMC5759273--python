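"""Alpha and beta diversity, batch correction, ordination, and PERMANOVA.

Alpha diversity (Shannon, inverse Simpson) is computed per sample; beta
diversity is Bray-Curtis. Between-run sequencing batch effects are removed from
relative abundances with a per-taxon group-mean linear model before ordination.
PCoA is classical metric scaling (Gower double-centering + eigendecomposition);
PERMANOVA is the standard pseudo-F permutation test on a distance matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .community import OtuTable, SampleMetadata, relative_abundance

__all__ = [
    "shannon",
    "inverse_simpson",
    "bray_curtis",
    "batch_correct",
    "OrdinationResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "pairwise_tests_holm",
    "alpha_diversity_table",
]


def _proportions(counts) -> np.ndarray:
    v = np.asarray(counts, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("count vector sums to zero")
    if np.any(v < 0):
        raise ValueError("negative counts")
    return v / total


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over taxa with p_i > 0.

    The default logarithm base is e; pass ``base=2`` for bits. The index is
    invariant to rescaling the counts by a positive constant.
    """
    p = _proportions(counts)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum p_i^2 (effective number of taxa)."""
    p = _proportions(counts)
    return float(1.0 / (p ** 2).sum())


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    """Shannon (base e) and inverse Simpson for every sample column."""
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rows.append(
            {"sample_id": sid, "shannon": shannon(col), "inverse_simpson": inverse_simpson(col)}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table_or_matrix, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    Accepts an :class:`~lungbiota.community.OtuTable` (computed on counts) or a
    taxa-by-samples array of counts/proportions. BC(x, y) =
    sum|x_i - y_i| / sum(x_i + y_i), in [0, 1] for non-negative input.
    """
    if isinstance(table_or_matrix, OtuTable):
        matrix = table_or_matrix.counts.astype(float)
        sample_ids = list(table_or_matrix.sample_ids)
    else:
        matrix = np.asarray(table_or_matrix, dtype=float)
        if sample_ids is None:
            sample_ids = [f"s{j}" for j in range(matrix.shape[1])]
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    sums = matrix.sum(axis=0)
    if np.any(sums <= 0):
        bad = sample_ids[int(np.argmin(sums))]
        raise ValueError(f"zero-sum sample column: {bad!r}")
    cond = pdist(matrix.T, metric="braycurtis")
    return DistanceMatrix(squareform(cond), ids=sample_ids)


def batch_correct(
    proportions: np.ndarray,
    sample_ids: list[str],
    metadata: SampleMetadata,
) -> np.ndarray:
    """Remove per-taxon sequencing-batch shifts from relative abundances.

    For every taxon, a least-squares fit of proportion ~ intercept + batch
    indicators is computed across samples (equivalently, batch group means);
    the corrected value is the residual plus the taxon's grand mean. Negative
    corrected values are clipped to zero and each column is renormalized to
    sum 1. With fewer than two batches the transform is the identity (up to
    renormalization).
    """
    X = np.asarray(proportions, dtype=float)
    if X.shape[1] != len(sample_ids):
        raise ValueError("sample_ids length does not match matrix columns")
    batches = np.array([metadata.batch_of(s) for s in sample_ids])
    labels = np.unique(batches)
    if len(labels) < 2:
        out = X.copy()
    else:
        grand = X.mean(axis=1, keepdims=True)
        out = np.empty_like(X)
        for lab in labels:
            cols = batches == lab
            batch_mean = X[:, cols].mean(axis=1, keepdims=True)
            out[:, cols] = X[:, cols] - batch_mean + grand
        out = np.clip(out, 0.0, None)
    sums = out.sum(axis=0)
    if np.any(sums <= 0):
        bad = sample_ids[int(np.argmin(sums))]
        raise ValueError(f"batch correction produced an empty sample: {bad!r}")
    return out / sums[np.newaxis, :]


@dataclass
class OrdinationResult:
    """Classical-scaling output: coordinates, eigenvalues, variance explained."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # non-increasing, positive axes only
    proportion_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and returns coordinates scaled by
    the square root of each positive eigenvalue. Negative-eigenvalue axes are
    discarded without correction; variance explained is relative to the sum of
    positive eigenvalues. Axis signs follow the convention that the first
    coordinate of non-negligible magnitude on each axis is positive.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    D = dm.data
    n = D.shape[0]
    d2 = D ** 2
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    B = -0.5 * (d2 - row - col + d2.mean())
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1.0, float(np.abs(eigvals).max())) * 1e-9
    keep = eigvals > tol
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    coords = eigvecs * np.sqrt(eigvals)[np.newaxis, :]
    for a in range(coords.shape[1]):
        nonzero = np.flatnonzero(np.abs(coords[:, a]) > 1e-9)
        if nonzero.size and coords[nonzero[0], a] < 0:
            coords[:, a] *= -1
    total = eigvals.sum() if eigvals.size else 1.0
    k = min(n_axes, coords.shape[1])
    return OrdinationResult(
        sample_ids=list(dm.ids),
        coordinates=coords[:, :k],
        eigenvalues=eigvals[:k],
        proportion_explained=eigvals[:k] / total,
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray):
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g, size in enumerate(sizes):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / size
    ss_between = ss_total - ss_within
    a = len(sizes)
    if ss_within == 0:
        return np.inf, ss_between / ss_total
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``grouping`` maps sample id to group label (mapping or pandas Series).
    The p-value uses the "+1" convention: the observed statistic is counted
    among the permutations, so p >= 1/(n_permutations + 1).
    """
    labels = np.array([grouping[s] for s in dm.ids])
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if len(uniq) == len(labels):
        raise ValueError("every sample is its own group")
    d2 = dm.data ** 2
    f_obs, r2 = _permanova_stats(d2, codes, sizes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_perm, _ = _permanova_stats(d2, perm, sizes)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def pairwise_tests_holm(
    values,
    metadata: SampleMetadata,
    sites: tuple[str, ...] = ("oral", "nasal", "bronchial", "lung"),
) -> pd.DataFrame:
    """Paired two-sided t tests between sites with Holm step-down adjustment.

    ``values`` maps sample id to a per-sample scalar (e.g. Shannon diversity).
    For each site pair, subjects sampled at both sites are matched; pairs with
    fewer than two complete subjects are reported as not testable. If the
    paired differences are identically zero the raw p is reported as 1.
    """
    vals = dict(values) if not isinstance(values, pd.Series) else values.to_dict()
    rows = []
    for site_a, site_b in itertools.combinations(sites, 2):
        xs, ys = [], []
        subjects = sorted(
            set(metadata.df.loc[metadata.df["site"] == site_a, "subject_id"])
            & set(metadata.df.loc[metadata.df["site"] == site_b, "subject_id"])
        )
        for subj in subjects:
            sa, sb = metadata.sample_of(subj, site_a), metadata.sample_of(subj, site_b)
            if sa in vals and sb in vals:
                xs.append(vals[sa])
                ys.append(vals[sb])
        row = {"site_a": site_a, "site_b": site_b, "n_pairs": len(xs)}
        if len(xs) < 2:
            row.update(statistic=np.nan, p_raw=np.nan, testable=False)
        else:
            diffs = np.asarray(xs) - np.asarray(ys)
            if np.allclose(diffs, 0):
                row.update(statistic=0.0, p_raw=1.0, testable=True)
            else:
                t = stats.ttest_rel(xs, ys)
                row.update(statistic=float(t.statistic), p_raw=float(t.pvalue), testable=True)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    testable = out["testable"].fillna(False).astype(bool)
    if testable.any():
        _, adj, _, _ = multipletests(out.loc[testable, "p_raw"], method="holm")
        out.loc[testable, "p_holm"] = adj
    return out
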