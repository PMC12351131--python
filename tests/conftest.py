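import numpy as np
import pytest

from cardiocycle.classify_eval import CycleClassifier
from cardiocycle.pipeline import RunConfig, records_to_features, _shared_plan
from cardiocycle.synth_ecg import synth_dataset


@pytest.fixture(scope="session")
def default_cohort():
    """The frozen default synthetic study: 10+10 subjects, ~100 cycles each,
    master seed 1."""
    return synth_dataset(n_subjects_per_class=10, cycles_per_subject=100, seed=1)


@pytest.fixture(scope="session")
def paired_cv_results(default_cohort):
    """Median- and mean-centered 10-fold CV results on identical folds."""
    cfg = RunConfig(seed=1)
    feats_median = records_to_features(default_cohort, cfg, "median")
    feats_mean = records_to_features(default_cohort, cfg, "mean")
    plan = _shared_plan(feats_median, cfg)
    res = {}
    for name, feats in (("median", feats_median), ("mean", feats_mean)):
        model = CycleClassifier.from_cycle_features(feats, config=cfg.mlp)
        res[name] = model.fit(mode="cv", k=10, seed=1, plan=plan)
    res["features_median"] = feats_median
    return res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
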