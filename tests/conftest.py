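import numpy as np
import pytest

from kinesens import distributions, mdrm, pipeline, shapemodel, spine, surrogate


@pytest.fixture(scope="session")
def template():
    return spine.default_template()


@pytest.fixture(scope="session")
def population36():
    return pipeline.generate_fixture_population(36, seed=123)


@pytest.fixture(scope="session")
def aligned_spines(template, population36):
    return pipeline.align_population(template, population36, tol=0.01)


@pytest.fixture(scope="session")
def shape_model(template, aligned_spines):
    return shapemodel.SpineShapeModel.fit(aligned_spines, n_components=2, template=template)


@pytest.fixture(scope="session")
def param_specs():
    return distributions.build_parameter_set()


@pytest.fixture(scope="session")
def rules5(param_specs):
    return [mdrm.quadrature_rule(p, 5) for p in param_specs]


@pytest.fixture(scope="session")
def design5(param_specs, rules5):
    return mdrm.build_design(param_specs, 5, rules5)


@pytest.fixture(scope="session")
def skin_spec(param_specs):
    return next(p for p in param_specs if p.coupling == "skin")


@pytest.fixture(scope="session")
def design_responses(design5, shape_model, skin_spec):
    """Batch-simulated responses of the 29-run design (time, head, t1)."""
    X = design5.runs[list(design5.parameters)].to_numpy(dtype=float)
    states = surrogate.occupant_batch_from_matrix(X, shape_model, skin_spec)
    return surrogate.simulate_batch(states, surrogate.BrakingPulse())


@pytest.fixture(scope="session")
def design_metrics(design5, design_responses):
    """run_id -> metric arrays for the 29-run design."""
    time, head, t1 = design_responses
    bm = surrogate.batch_metrics(time, head, t1)
    run_ids = list(design5.runs["run_id"])
    return {m: dict(zip(run_ids, v)) for m, v in bm.items()}
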