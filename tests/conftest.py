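import numpy as np
import pandas as pd
import pytest

import lungbiota as lb


@pytest.fixture(scope="session")
def default_cohort():
    """One study-structured cohort (9 subjects, batches 3+6, 6 controls)."""
    return lb.simulate_cohort(lb.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def rarefied_cohort(default_cohort):
    """The default cohort taken through contaminant filtering and rarefaction."""
    table, metadata, truth = default_cohort
    filtered, removed = lb.remove_contaminant_taxa(table, metadata)
    subject_ids = [s for s in filtered.sample_ids if metadata.site_of(s) != "control"]
    rarefied, dropped = lb.rarefy(filtered.select_samples(subject_ids), 563, seed=11)
    return rarefied, metadata, truth, removed, dropped


@pytest.fixture(scope="session")
def recover_immigration():
    """Harness: simulate an equal-lung-depth cohort and re-estimate m.

    Lung depths are held at the generator's expected read total because the
    moment fit assumes a single community size N; the fit is fed the pooled
    true bronchial source profile and the observed lung detection frequencies.
    """

    def _recover(m_true: float, n_subjects: int, seed: int) -> float:
        cfg = lb.CohortConfig(
            n_subjects=n_subjects,
            batch_sizes=(n_subjects // 2, n_subjects - n_subjects // 2),
            m_true=m_true,
            low_yield_lung_subject=None,
            seed=seed,
        )
        cfg.depth_log_sd = dict(cfg.depth_log_sd)
        cfg.depth_log_sd["lung"] = 0.0
        table, metadata, truth = lb.simulate_cohort(cfg)
        lungs = [s for s in table.sample_ids if metadata.site_of(s) == "lung"]
        lung_counts = table.select_samples(lungs).counts
        p = truth.mean_source_profile("bronchial")
        f = (lung_counts > 0).mean(axis=1)
        N = float(lung_counts.sum(axis=0).mean())
        inputs = lb.NeutralModelInputs(
            list(table.taxon_ids), p, f, len(lungs), N, 1.0 / N
        )
        return lb.fit_immigration(inputs).m_hat

    return _recover


@pytest.fixture()
def toy_table():
    """3 taxa x 4 samples with taxonomy, two subjects at two sites."""
    counts = np.array(
        [
            [10, 0, 3, 7],
            [5, 5, 2, 1],
            [0, 15, 5, 2],
        ]
    )
    table = lb.OtuTable(
        ["t1", "t2", "t3"],
        ["A_oral", "A_lung", "B_oral", "B_lung"],
        counts,
        [
            "k__Bacteria;p__p1;c__c1;o__o1;f__f1;g__g1",
            "k__Bacteria;p__p1;c__c1;o__o1;f__f1;g__g2",
            "k__Bacteria;p__p2;c__c2;o__o2;f__f2;g__",
        ],
    )
    metadata = lb.SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["A_oral", "A_lung", "B_oral", "B_lung"],
                "subject_id": ["A", "A", "B", "B"],
                "site": ["oral", "lung", "oral", "lung"],
                "batch": ["run1", "run1", "run2", "run2"],
            }
        )
    )
    return table, metadata
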