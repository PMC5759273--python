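"""Sloan neutral-community-model fit of source-to-lung immigration.

Under the neutral model, the relative abundance of a taxon in a local (lung)
community of N individuals receiving immigrants from a source community at
per-death probability m is, at equilibrium, Beta(N m p, N m (1 - p)) where p is
the taxon's relative abundance in the source. A taxon is detected in a sample
when its relative abundance exceeds the detection limit d = 1/N, so its
predicted detection probability across subjects is the upper tail of that beta
distribution. m is estimated by the method of moments: minimize the sum of
squared differences between predicted detection probabilities and the observed
detection frequencies across subjects. Taxa are then classified as consistent
with the neutral prediction or falling above/below a binomial confidence band
around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betainc
from scipy.stats import binom
from statsmodels.stats.proportion import proportion_confint

from .community import OtuTable, SampleMetadata, relative_abundance

__all__ = [
    "NeutralModelInputs",
    "prepare_inputs",
    "detection_probability",
    "NeutralFitResult",
    "fit_immigration",
    "classify_otus",
]

_M_MIN = 1e-4  # lower edge of the immigration-probability search interval


@dataclass
class NeutralModelInputs:
    """Per-taxon source abundances and sink detection frequencies.

    ``p[i]`` is the mean relative abundance of taxon i across source-site
    samples; ``f[i]`` is the fraction of sink (lung) samples in which taxon i
    was detected (count > 0); ``N`` is the average total reads per sink sample
    and ``d = 1/N`` the detection limit.
    """

    otu_ids: list[str]
    p: np.ndarray
    f: np.ndarray
    n_subjects: int
    N: float
    d: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.p.shape != self.f.shape or len(self.otu_ids) != self.p.size:
            raise ValueError("otu_ids, p and f must have matching lengths")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("source abundances p must lie in [0, 1]")
        if np.any((self.f < 0) | (self.f > 1)):
            raise ValueError("detection frequencies f must lie in [0, 1]")
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not np.isclose(self.d, 1.0 / self.N):
            raise ValueError("detection limit d must equal 1/N")


def prepare_inputs(
    table: OtuTable,
    metadata: SampleMetadata,
    source_site: str,
    sink_site: str = "lung",
) -> NeutralModelInputs:
    """Build neutral-model inputs from an OTU table and metadata.

    Source abundance is the across-sample mean of within-sample relative
    abundance at ``source_site``; detection frequency is the fraction of
    ``sink_site`` samples with a positive count.
    """
    source = metadata.samples_for_site(source_site, within=table.sample_ids)
    sink = metadata.samples_for_site(sink_site, within=table.sample_ids)
    if not source:
        raise ValueError(f"no {source_site!r} samples in table")
    if len(sink) < 2:
        raise ValueError(f"need at least two {sink_site!r} samples")
    src_rel = relative_abundance(table.select_samples(source))
    p = src_rel.mean(axis=1)
    sink_counts = table.select_samples(sink).counts
    f = (sink_counts > 0).mean(axis=1)
    N = float(sink_counts.sum(axis=0).mean())
    return NeutralModelInputs(
        otu_ids=list(table.taxon_ids),
        p=p,
        f=f,
        n_subjects=len(sink),
        N=N,
        d=1.0 / N,
    )


def detection_probability(p_i, m: float, N: float, d: float):
    """P(relative abundance > d) under Beta(N m p, N m (1 - p)).

    Computed as ``1 - I_d(N m p, N m (1 - p))`` with I the regularized
    incomplete beta function. Boundary conventions: p = 0 gives 0 (absent from
    the source stays absent) and p = 1 gives 1. Vectorized over ``p_i``.
    """
    if not (0 < m <= 1):
        raise ValueError("m must lie in (0, 1]")
    if N <= 0:
        raise ValueError("N must be positive")
    if not (0 < d < 1):
        raise ValueError("d must lie in (0, 1)")
    p = np.asarray(p_i, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_i must lie in [0, 1]")
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    out = np.zeros_like(p)
    interior = (p > 0) & (p < 1)
    a = N * m * p[interior]
    b = N * m * (1.0 - p[interior])
    out[interior] = 1.0 - betainc(a, b, d)
    out[p == 1] = 1.0
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


@dataclass
class NeutralFitResult:
    """Immigration estimate with per-taxon predictions and classifications."""

    m_hat: float
    sse: float
    otus: pd.DataFrame = field(repr=False)  # p, f, predicted, lower, upper, class
    n_subjects: int
    N: float
    d: float
    confidence_level: float
    band_method: str

    def class_counts(self) -> dict[str, int]:
        return self.otus["class"].value_counts().to_dict()


def _sse_terms(inputs: NeutralModelInputs, m: float) -> float:
    mask = inputs.p > 0
    pred = detection_probability(inputs.p[mask], m, inputs.N, inputs.d)
    return float(((pred - inputs.f[mask]) ** 2).sum())


def fit_immigration(
    inputs: NeutralModelInputs,
    grid: int = 2000,
    tol: float = 1e-6,
    confidence: float = 0.95,
    band_method: str = "quantile",
) -> NeutralFitResult:
    """Estimate the immigration probability by least squares over m in (0, 1].

    The SSE over taxa present in the source is evaluated on a uniform grid of
    ``grid`` points, then refined by bounded scalar minimization between the
    grid neighbours of the best point, to absolute tolerance ``tol``. Ties on
    the grid resolve toward smaller m. Taxa absent from the source contribute
    a constant to any objective and are excluded from it, but are reported in
    the per-taxon table with class ``absent_in_source``.
    """
    mask = inputs.p > 0
    if not mask.any():
        raise ValueError("no taxa with positive source abundance")
    ms = np.linspace(_M_MIN, 1.0, grid)
    # vectorized SSE over the whole grid
    a = inputs.N * ms[:, None] * inputs.p[None, mask]
    b = inputs.N * ms[:, None] * (1.0 - inputs.p[None, mask])
    P = 1.0 - betainc(a, b, inputs.d)
    sse_grid = ((P - inputs.f[None, mask]) ** 2).sum(axis=1)
    best = int(np.argmin(sse_grid))  # first minimum -> smaller m on ties
    lo = ms[max(best - 1, 0)]
    hi = ms[min(best + 1, grid - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda m: _sse_terms(inputs, m),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        m_hat, sse = float(res.x), float(res.fun)
        if sse_grid[best] < sse:  # keep the grid point if refinement ties/loses
            m_hat, sse = float(ms[best]), float(sse_grid[best])
    else:
        m_hat, sse = float(ms[best]), float(sse_grid[best])
    otus = classify_otus(inputs, m_hat, confidence=confidence, method=band_method)
    return NeutralFitResult(
        m_hat=m_hat,
        sse=sse,
        otus=otus,
        n_subjects=inputs.n_subjects,
        N=inputs.N,
        d=inputs.d,
        confidence_level=confidence,
        band_method=band_method,
    )


def classify_otus(
    inputs: NeutralModelInputs,
    m_hat: float,
    confidence: float = 0.95,
    method: str = "quantile",
) -> pd.DataFrame:
    """Classify taxa against the neutral prediction at ``m_hat``.

    The band around the predicted detection probability P_i is, per taxon,
    the ``confidence`` interval of Binomial(n_subjects, P_i) scaled by
    1/n_subjects — either exact binomial quantiles (``method="quantile"``,
    the default) or the Wilson score interval (``method="wilson"``).
    Detection frequencies inside the band (inclusive) are ``consistent``;
    otherwise ``above`` or ``below``. Taxa with p = 0 are ``absent_in_source``.
    """
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie in (0, 1)")
    n = inputs.n_subjects
    alpha = 1.0 - confidence
    pred = np.where(
        inputs.p > 0,
        detection_probability(np.clip(inputs.p, 0, 1), m_hat, inputs.N, inputs.d),
        0.0,
    )
    if method == "quantile":
        lower = binom.ppf(alpha / 2, n, pred) / n
        upper = binom.ppf(1 - alpha / 2, n, pred) / n
        # binom.ppf returns -1 at q=0 mass edge for p=0; clamp to the support
        lower = np.clip(lower, 0.0, 1.0)
        upper = np.clip(upper, 0.0, 1.0)
    elif method == "wilson":
        lower, upper = proportion_confint(pred * n, n, alpha=alpha, method="wilson")
        lower, upper = np.clip(lower, 0.0, 1.0), np.clip(upper, 0.0, 1.0)
    else:
        raise ValueError(f"unknown band method {method!r}")
    cls = np.where(inputs.f > upper, "above", np.where(inputs.f < lower, "below", "consistent"))
    cls = np.where(inputs.p == 0, "absent_in_source", cls)
    return pd.DataFrame(
        {
            "otu_id": inputs.otu_ids,
            "p": inputs.p,
            "f": inputs.f,
            "predicted": pred,
            "lower": lower,
            "upper": upper,
            "class": cls,
        }
    ).set_index("otu_id")
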