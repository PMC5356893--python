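import dataclasses
import logging

import numpy as np
import pytest

from crgpred.data_model import CtMatrix, ExpressionMatrix
from crgpred.preprocess import impute_nondetects
from crgpred.simulate import SimulationConfig, generate_cohort

# silence the deliberate full-set leakage warning in test output
logging.getLogger("crgpred.model_selection").setLevel(logging.ERROR)

TRUE_SIGNATURE = ("HBEGF", "HOXC13", "IGFBP2", "SATB1")


@pytest.fixture
def toy_ct() -> CtMatrix:
    """3 genes x 2 samples with one non-detect."""
    return CtMatrix(
        gene_ids=["BECN1", "G1", "G2"],
        sample_ids=["S1", "S2"],
        ct=np.array([[25.0, 25.0], [22.0, 30.0], [np.nan, 28.0]]),
        detected=np.array([[True, True], [True, True], [False, True]]),
    )


@pytest.fixture(scope="session")
def study_cohort():
    """Study-shaped synthetic cohort at the canonical demo seed and low noise."""
    cfg = dataclasses.replace(SimulationConfig(), seed=1, noise_sd=0.5)
    ct, records, split, truth = generate_cohort(cfg)
    return {"cfg": cfg, "ct": ct, "records": records, "split": split, "truth": truth}


@pytest.fixture(scope="session")
def training_expression(study_cohort):
    """EM-imputed training expression with outcome-grouped means."""
    ct = study_cohort["ct"].subset_samples(study_cohort["split"].training_ids)
    labels = {
        s: study_cohort["truth"]["labels"][s]
        for s in study_cohort["split"].training_ids
    }
    expr, model = impute_nondetects(ct, labels=labels, seed=1)
    return expr, model, labels


def make_expression(values, labels_bool, gene_ids=None, provenance="imputed"):
    """Tiny complete ExpressionMatrix from a genes x samples array."""
    values = np.atleast_2d(np.asarray(values, float))
    n_genes, n_samples = values.shape
    gene_ids = list(gene_ids) if gene_ids else [f"G{i}" for i in range(n_genes)]
    sample_ids = [f"S{i}" for i in range(n_samples)]
    expr = ExpressionMatrix(gene_ids, sample_ids, values, provenance)
    labels = {s: bool(b) for s, b in zip(sample_ids, labels_bool)}
    return expr, labels
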