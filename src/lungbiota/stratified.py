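"""Batch-stratified permutation test for within-subject site similarity.

Tests whether each subject's bronchial and lung-tissue communities are more
similar to each other than to those of other subjects. The statistic is the
mean of the diagonal of the bronchial-by-lung cross-distance matrix (the
within-subject distances). Subjects are permuted *within* sequencing batch —
realignments that would pair samples across batches are never generated, so the
batch effect cannot masquerade as subject effect. With batch sizes of 3 and 5
the composite group has 3! x 5! = 720 elements, all enumerated; larger cohorts
fall back to Monte-Carlo sampling. Small within-subject distances indicate
similarity, so the p-value is the fraction of permutations whose statistic is
less than or equal to the observed one (identity included).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix

from .community import SampleMetadata

__all__ = [
    "PairedSiteMatrix",
    "build_paired_site_matrix",
    "count_stratified_permutations",
    "PermutationResult",
    "stratified_permutation_test",
]


@dataclass
class PairedSiteMatrix:
    """Cross-distance matrix between two sites over subjects having both.

    ``cross[s, t]`` is the distance between subject ``s``'s site-A sample and
    subject ``t``'s site-B sample; the diagonal holds the within-subject
    distances.
    """

    subject_ids: list[str]
    cross: np.ndarray
    batch_of: dict[str, str]

    def __post_init__(self) -> None:
        self.cross = np.asarray(self.cross, dtype=float)
        n = len(self.subject_ids)
        if self.cross.shape != (n, n):
            raise ValueError("cross matrix must be square over subjects")
        if np.any(self.cross < 0):
            raise ValueError("distances must be non-negative")
        missing = [s for s in self.subject_ids if s not in self.batch_of]
        if missing:
            raise ValueError(f"subjects without batch label: {missing}")


def build_paired_site_matrix(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    site_a: str = "bronchial",
    site_b: str = "lung",
) -> PairedSiteMatrix:
    """Assemble the subject-by-subject cross-distance matrix for two sites.

    Subjects lacking either site in ``dm`` (for example because a low-yield
    sample was dropped at rarefaction) are excluded.
    """
    present = set(dm.ids)
    subjects = []
    sample_a: dict[str, str] = {}
    sample_b: dict[str, str] = {}
    for subj in dict.fromkeys(
        metadata.df.loc[metadata.df["site"] != "control", "subject_id"]
    ):
        sa = metadata.sample_of(subj, site_a)
        sb = metadata.sample_of(subj, site_b)
        if sa in present and sb in present:
            subjects.append(subj)
            sample_a[subj], sample_b[subj] = sa, sb
    if len(subjects) < 2:
        raise ValueError(
            f"need at least two subjects with both {site_a!r} and {site_b!r} samples"
        )
    n = len(subjects)
    cross = np.empty((n, n))
    for i, s in enumerate(subjects):
        for j, t in enumerate(subjects):
            cross[i, j] = dm[sample_a[s], sample_b[t]]
    batch_of = {
        s: metadata.batch_of(sample_a[s]) for s in subjects
    }
    return PairedSiteMatrix(subjects, cross, batch_of)


def count_stratified_permutations(batch_sizes: list[int]) -> int:
    """Number of composite within-batch permutations, prod(size!)."""
    if not batch_sizes:
        raise ValueError("batch_sizes must be non-empty")
    if any(s < 1 for s in batch_sizes):
        raise ValueError("batch sizes must be >= 1")
    out = 1
    for s in batch_sizes:
        out *= math.factorial(s)
    return out


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray = field(repr=False)
    n_permutations: int
    p_value: float
    mode: str  # "exhaustive" or "monte_carlo"
    seed: int | None


def _batch_indices(psm: PairedSiteMatrix) -> list[np.ndarray]:
    order: dict[str, list[int]] = {}
    for i, subj in enumerate(psm.subject_ids):
        if subj not in psm.batch_of:
            raise ValueError(f"subject {subj!r} has no batch label")
        order.setdefault(psm.batch_of[subj], []).append(i)
    return [np.asarray(v) for v in order.values()]


def stratified_permutation_test(
    psm: PairedSiteMatrix,
    max_exhaustive: int = 100_000,
    n_monte_carlo: int = 10_000,
    seed: int | None = 0,
) -> PermutationResult:
    """Left-tail permutation test of the mean within-subject cross distance.

    The statistic of a composite permutation sigma (permuting subjects within
    each batch independently) is ``mean_s cross[s, sigma(s)]``. If the
    composite group size prod(batch_size!) is at most ``max_exhaustive`` every
    permutation is enumerated exactly once (exhaustive mode); otherwise
    ``n_monte_carlo`` permutations are sampled uniformly with the identity
    forced into the sample. The p-value is the fraction of permutation
    statistics less than or equal to the observed diagonal mean; ties count,
    and the identity's presence guarantees p >= 1/n_permutations.
    """
    batches = _batch_indices(psm)
    n = len(psm.subject_ids)
    k_total = count_stratified_permutations([len(b) for b in batches])

    # per-batch partial sums share the same accumulation order as the observed
    # statistic, so the identity permutation ties the observed value exactly
    def batch_sum(idx: np.ndarray, perm: np.ndarray) -> float:
        return float(psm.cross[idx, perm].sum())

    observed_parts = [batch_sum(b, b) for b in batches]
    observed = sum(observed_parts) / n

    if k_total <= max_exhaustive:
        per_batch_sums = []
        for b in batches:
            sums = [batch_sum(b, np.asarray(perm)) for perm in itertools.permutations(b)]
            per_batch_sums.append(np.asarray(sums))
        total = per_batch_sums[0]
        for sums in per_batch_sums[1:]:
            total = np.add.outer(total, sums).ravel()
        null_values = total / n
        mode = "exhaustive"
        used_seed = None
    else:
        if seed is None:
            raise ValueError("seed is required for monte_carlo mode")
        rng = np.random.default_rng(seed)
        stats = np.empty(n_monte_carlo)
        stats[0] = sum(observed_parts) / n  # identity forced into the sample
        for r in range(1, n_monte_carlo):
            acc = 0.0
            for b in batches:
                acc += batch_sum(b, rng.permutation(b))
            stats[r] = acc / n
        null_values = stats
        mode = "monte_carlo"
        used_seed = seed

    n_perm = len(null_values)
    p = float(np.count_nonzero(null_values <= observed)) / n_perm
    return PermutationResult(
        observed=float(observed),
        null_values=null_values,
        n_permutations=n_perm,
        p_value=p,
        mode=mode,
        seed=used_seed,
    )
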