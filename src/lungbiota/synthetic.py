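"""Synthetic respiratory-tract cohorts with known ground truth.

Generates cohorts with the structure of a multi-site airway microbiota study:
per subject one oral, nasal, bronchial and lung-tissue sample, plus negative
extraction/sequencing controls, split over two sequencing batches. Taxa belong
to guilds (oral-associated, nasal-associated, shared upper-airway, lung
resident, contaminant); oral and nasal communities are drawn from largely
disjoint guilds, the bronchial community is a subject-specific mixture of
oral, nasal and an "unknown" lung-resident component, and the lung-tissue
community arises from the bronchial profile through the Sloan neutral model
with a known immigration probability ``m_true``. Sequencing depths are
log-normal per site with the upper airway orders of magnitude deeper than the
lung, and one designated subject's lung sample is given a low yield so that
rarefaction drops it, as happens with real low-biomass specimens.

The neutral lung community is discretized by flooring N*x and assigning the
remainder reads among already-detected taxa, so that a taxon has a positive
count exactly when its relative abundance exceeds the detection limit 1/N —
the discrete Wright-Fisher community that the moment estimator assumes. An
extra multinomial read-sampling layer would double-count sampling noise and
systematically inflate detection of sub-threshold taxa (see docs/methods.md).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .community import OtuTable, SampleMetadata

__all__ = [
    "GuildSizes",
    "CohortConfig",
    "CohortTruth",
    "simulate_cohort",
    "simulate_neutral_lung",
]

_SUBJECT_SITES = ("oral", "nasal", "bronchial", "lung")


@dataclass
class GuildSizes:
    oral: int = 160
    nasal: int = 140
    shared: int = 40
    lung_resident: int = 140
    contaminant: int = 20

    @property
    def total(self) -> int:
        return self.oral + self.nasal + self.shared + self.lung_resident + self.contaminant


@dataclass
class CohortConfig:
    """Ground-truth parameters of a simulated cohort.

    Defaults mirror the emulated study: 9 subjects in sequencing batches of 3
    and 6, site depths ordered oral ~ nasal >> bronchial ~ lung, lung source
    mixing weights 0.21 / 0.09 / 0.70 (oral / nasal / unknown), and one
    low-yield lung specimen (subject 8). ``reads_N`` is the expected lung read
    total and sets both the neutral-model community size and the log-normal
    location of lung depths. ``dirichlet_concentration`` controls how tightly
    subject-level source profiles cluster around the shared site profile.
    """

    n_subjects: int = 9
    batch_sizes: tuple[int, ...] = (3, 6)
    guild_sizes: GuildSizes = field(default_factory=GuildSizes)
    depth_log_mean: dict = field(
        default_factory=lambda: {
            "oral": math.log(8e5),
            "nasal": math.log(3.5e5),
            "bronchial": math.log(2000.0),
        }
    )
    depth_log_sd: dict = field(
        default_factory=lambda: {
            "oral": 0.5,
            "nasal": 1.0,
            "bronchial": 1.0,
            "lung": 0.9,
        }
    )
    mix_weights: tuple[float, float, float] = (0.21, 0.09, 0.70)
    mix_weight_sd: float = 0.015
    m_true: float = 0.69
    reads_N: float = 1500.0
    dirichlet_concentration: float = 15000.0
    abundance_log_sd: float = 1.2  # spread of the rank-abundance curve per guild
    contaminant_proportion: float = 0.02  # reagent taxon carried into subject samples
    batch_effect_logfold: float = 0.25
    batch_effect_fraction: float = 0.10
    n_controls: int = 6
    control_depth_range: tuple[int, int] = (75, 820)
    #: floor on subject-sample depths (all retained study specimens exceeded
    #: ~580 reads); the designated low-yield lung sample is exempt
    min_subject_depth: int = 600
    low_yield_lung_subject: int | None = 8  # 1-based; None disables
    low_yield_depth_range: tuple[int, int] = (20, 100)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if sum(self.batch_sizes) != self.n_subjects:
            raise ValueError("batch_sizes must partition n_subjects")
        if any(b < 1 for b in self.batch_sizes):
            raise ValueError("batch_sizes entries must be >= 1")
        g = self.guild_sizes
        if min(g.oral, g.nasal, g.shared, g.lung_resident, g.contaminant) < 0:
            raise ValueError("guild_sizes must be non-negative")
        w = np.asarray(self.mix_weights, dtype=float)
        if w.size != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mix_weights must be three non-negative values summing to 1")
        if not (0 < self.m_true <= 1):
            raise ValueError("m_true must lie in (0, 1]")
        if self.reads_N < 1:
            raise ValueError("reads_N must be >= 1")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.control_depth_range[0] > self.control_depth_range[1] or self.control_depth_range[0] < 1:
            raise ValueError("control_depth_range must be an increasing pair of depths >= 1")
        for site in ("oral", "nasal", "bronchial"):
            if site not in self.depth_log_mean:
                raise ValueError(f"depth_log_mean missing site {site!r}")
        for site in ("oral", "nasal", "bronchial", "lung"):
            if site not in self.depth_log_sd:
                raise ValueError(f"depth_log_sd missing site {site!r}")


@dataclass
class CohortTruth:
    """Exactly the values used during generation, for downstream validation."""

    subject_ids: list[str]
    batch_of: dict[str, str]
    m_true: float
    mix_weights: dict[str, tuple[float, float, float]]
    profiles: dict[str, dict[str, list[float]]]  # subject -> site/unknown -> profile
    contaminant_taxa: list[str]
    guild_of: dict[str, str]
    lung_depths: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh)

    def mean_source_profile(self, site: str) -> np.ndarray:
        """Across-subject mean of the true per-subject profiles for a site."""
        mats = [np.asarray(self.profiles[s][site]) for s in self.subject_ids]
        return np.mean(mats, axis=0)


def _neutral_relative_abundance(
    source: np.ndarray, m: float, N: float, rng: np.random.Generator
) -> np.ndarray:
    """One beta draw per source-present taxon, renormalized to sum 1."""
    x = np.zeros_like(source)
    pos = source > 0
    a = N * m * source[pos]
    b = N * m * (1.0 - source[pos])
    x[pos] = rng.beta(a, b)
    total = x.sum()
    if total == 0:  # vanishingly unlikely; fall back to the source itself
        x[pos] = source[pos]
        total = x.sum()
    return x / total


def _discretize_community(x: np.ndarray, N: int) -> np.ndarray:
    """Floor N*x and assign remainder reads among already-detected taxa.

    Keeps the column sum exactly N while preserving the detection pattern
    count >= 1  <=>  x >= 1/N, matching the moment estimator's detection
    limit. Remainders are never used to promote sub-threshold taxa.
    """
    raw = N * x
    base = np.floor(raw).astype(np.int64)
    deficit = int(N - base.sum())
    detected = np.flatnonzero(base > 0)
    if detected.size == 0:
        base[int(np.argmax(x))] = N
        return base
    order = detected[np.argsort(-(raw[detected] - base[detected]))]
    for i in range(deficit):
        base[order[i % order.size]] += 1
    return base


def simulate_neutral_lung(
    source_profile: np.ndarray, m: float, N: float, seed: int
) -> np.ndarray:
    """Sample one neutral lung community of N reads from a source profile.

    Each source-present taxon's relative abundance is drawn from
    Beta(N m p, N m (1 - p)); the vector is renormalized and discretized to
    integer counts summing to N. Taxa absent from the source stay at zero.
    """
    p = np.asarray(source_profile, dtype=float)
    if np.any(p < 0):
        raise ValueError("source profile must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("source profile must sum to 1")
    if not (0 < m <= 1):
        raise ValueError("m must lie in (0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    x = _neutral_relative_abundance(p, m, float(N), rng)
    return _discretize_community(x, int(N))


def _base_profile(rng: np.random.Generator, idx: np.ndarray, n_taxa: int, log_sd: float) -> np.ndarray:
    prof = np.zeros(n_taxa)
    raw = rng.lognormal(0.0, log_sd, idx.size)
    prof[idx] = raw / raw.sum()
    return prof


def _dirichlet_around(
    rng: np.random.Generator, base: np.ndarray, conc: float
) -> np.ndarray:
    out = np.zeros_like(base)
    pos = base > 0
    out[pos] = rng.dirichlet(conc * base[pos])
    return out


def simulate_cohort(
    config: CohortConfig | None = None,
) -> tuple[OtuTable, SampleMetadata, CohortTruth]:
    """Generate one cohort: OTU table, metadata, and generation ground truth.

    Deterministic given ``config.seed``. Controls contain reads only from the
    contaminant guild; the first contaminant taxon is also carried into every
    subject sample at ``contaminant_proportion``, so the control-driven
    contaminant filter has exactly one taxon to remove.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.guild_sizes
    n_taxa = g.total

    # taxon ids and greengenes-style lineages; a tenth of lung-resident taxa
    # are left unclassified at genus so rank aggregation has something to drop
    guild_slices = {}
    start = 0
    for name, size in (
        ("oral", g.oral),
        ("shared", g.shared),
        ("nasal", g.nasal),
        ("lung", g.lung_resident),
        ("contaminant", g.contaminant),
    ):
        guild_slices[name] = np.arange(start, start + size)
        start += size
    taxon_ids = []
    taxonomy = []
    guild_of = {}
    for name, idx in guild_slices.items():
        for k, i in enumerate(idx):
            tid = f"OTU_{i + 1:04d}"
            taxon_ids.append(tid)
            guild_of[tid] = name
            genus = f"g__{name.capitalize()}{k + 1}"
            if name == "lung" and k % 10 == 9:
                genus = "g__"
            taxonomy.append(
                f"k__Bacteria;p__P_{name};c__C_{name};o__O_{name};"
                f"f__F_{name}{k // 10 + 1};{genus}"
            )

    oral_idx = np.concatenate([guild_slices["oral"], guild_slices["shared"]])
    nasal_idx = np.concatenate([guild_slices["shared"], guild_slices["nasal"]])
    lung_idx = guild_slices["lung"]
    contam_idx = guild_slices["contaminant"]

    base = {
        "oral": _base_profile(rng, oral_idx, n_taxa, config.abundance_log_sd),
        "nasal": _base_profile(rng, nasal_idx, n_taxa, config.abundance_log_sd),
        "contaminant": _base_profile(rng, contam_idx, n_taxa, config.abundance_log_sd),
    }
    contam0 = int(contam_idx[0]) if contam_idx.size else None

    # measurement-stage batch bias: a multiplicative log-fold shift on a
    # random subset of taxa, applied to batch-2 sample profiles only
    biased = rng.random(n_taxa) < config.batch_effect_fraction
    batch_bias = np.where(biased, math.exp(config.batch_effect_logfold), 1.0)

    subject_ids = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    batch_labels = []
    for b, size in enumerate(config.batch_sizes):
        batch_labels += [f"run{b + 1}"] * size
    batch_of = dict(zip(subject_ids, batch_labels))

    def with_contaminant(profile: np.ndarray) -> np.ndarray:
        if contam0 is None or config.contaminant_proportion <= 0:
            return profile
        out = profile * (1.0 - config.contaminant_proportion)
        out[contam0] += config.contaminant_proportion
        return out

    def measure(profile: np.ndarray, depth: int, batch: str) -> np.ndarray:
        p = profile * (batch_bias if batch != "run1" else 1.0)
        p = p / p.sum()
        return rng.multinomial(depth, p)

    conc = config.dirichlet_concentration
    columns = {}
    truth_profiles = {}
    mix_weights = {}
    lung_depths = {}
    meta_rows = []

    for si, subj in enumerate(subject_ids):
        batch = batch_of[subj]
        p_oral = with_contaminant(_dirichlet_around(rng, base["oral"], conc))
        p_nasal = with_contaminant(_dirichlet_around(rng, base["nasal"], conc))
        p_unknown = np.zeros(n_taxa)
        p_unknown[lung_idx] = rng.dirichlet(np.full(lung_idx.size, conc / lung_idx.size))
        w = np.asarray(config.mix_weights) + rng.normal(0.0, config.mix_weight_sd, 3)
        w = np.clip(w, 0.01, None)
        w = w / w.sum()
        p_bronchial = w[0] * p_oral + w[1] * p_nasal + w[2] * p_unknown

        depths = {}
        for site in ("oral", "nasal", "bronchial"):
            depths[site] = max(
                config.min_subject_depth,
                int(rng.lognormal(config.depth_log_mean[site], config.depth_log_sd[site])),
            )
        if config.low_yield_lung_subject is not None and si + 1 == config.low_yield_lung_subject:
            lo, hi = config.low_yield_depth_range
            n_lung = int(rng.integers(lo, hi + 1))
        else:
            n_lung = max(
                config.min_subject_depth,
                int(rng.lognormal(math.log(config.reads_N), config.depth_log_sd["lung"])),
            )

        for site, prof in (("oral", p_oral), ("nasal", p_nasal), ("bronchial", p_bronchial)):
            sid = f"{subj}_{site}"
            columns[sid] = measure(prof, depths[site], batch)
            meta_rows.append((sid, subj, site, batch))

        x_lung = _neutral_relative_abundance(p_bronchial, config.m_true, float(n_lung), rng)
        if batch != "run1":
            x_lung = x_lung * batch_bias
            x_lung = x_lung / x_lung.sum()
        sid = f"{subj}_lung"
        columns[sid] = _discretize_community(x_lung, n_lung)
        meta_rows.append((sid, subj, "lung", batch))
        lung_depths[subj] = n_lung

        truth_profiles[subj] = {
            "oral": p_oral.tolist(),
            "nasal": p_nasal.tolist(),
            "unknown": p_unknown.tolist(),
            "bronchial": p_bronchial.tolist(),
        }
        mix_weights[subj] = tuple(float(v) for v in w)

    batch_cycle = [f"run{b + 1}" for b in range(len(config.batch_sizes))]
    for c in range(config.n_controls):
        sid = f"control_{c + 1}"
        depth = int(rng.integers(config.control_depth_range[0], config.control_depth_range[1] + 1))
        batch = batch_cycle[c % len(batch_cycle)]
        columns[sid] = measure(base["contaminant"], depth, batch)
        meta_rows.append((sid, "", "control", batch))

    sample_ids = list(columns)
    counts = np.column_stack([columns[s] for s in sample_ids])
    table = OtuTable(taxon_ids, sample_ids, counts, taxonomy)
    metadata = SampleMetadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "subject_id", "site", "batch"])
    )
    truth = CohortTruth(
        subject_ids=subject_ids,
        batch_of=batch_of,
        m_true=config.m_true,
        mix_weights=mix_weights,
        profiles=truth_profiles,
        contaminant_taxa=[taxon_ids[i] for i in contam_idx],
        guild_of=guild_of,
        lung_depths=lung_depths,
    )
    return table, metadata, truth
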