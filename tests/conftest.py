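"""Shared fixtures.

The expensive simulation studies (50-seed Lasso support recovery, 20-seed
boosted-model evaluation) are computed once per session and shared between
the property tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ghrspipe import boost, lasso, simulate

N_RECOVERY_SEEDS = 50
N_MODEL_SEEDS = 20


@pytest.fixture(scope="session")
def recovery_study():
    """Support recovery of the planted 19-symptom truth at lambda.1se, 50 seeds."""
    sens, fsr = [], []
    for seed in range(N_RECOVERY_SEEDS):
        dataset, truth = simulate.generate_clinical_cohort(seed=seed)
        selected, _, _ = lasso.select_core_symptoms(dataset, k=10, seed=seed)
        true_set = set(truth.informative_symptoms)
        got = set(selected.names)
        sens.append(len(true_set & got) / len(true_set))
        fsr.append(len(got - true_set) / max(1, len(got)))
    return {"sensitivity": np.array(sens), "false_selection_rate": np.array(fsr)}


@pytest.fixture(scope="session")
def model_study():
    """Test-set metrics of the boosted model on the default cohort, 20 seeds."""
    aucs, accs = [], []
    for seed in range(N_MODEL_SEEDS):
        dataset, _ = simulate.generate_clinical_cohort(seed=seed)
        train, test = boost.split_train_test(dataset, 0.3, seed=seed)
        model = boost.fit_model(train, seed=seed)
        model.threshold = boost.optimal_threshold(model, train)
        report = boost.classification_metrics(
            test.y, model.predict_proba(test.X), model.threshold
        )
        aucs.append(report.auc)
        accs.append(report.accuracy)
    return {"auc": np.array(aucs), "accuracy": np.array(accs)}
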