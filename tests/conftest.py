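import numpy as np
import pytest

import censmix as cm


@pytest.fixture(scope="session")
def fictive():
    """The regenerated two-gamma reference datasets (fixed seed)."""
    return cm.fictive_reference_datasets(1234)


@pytest.fixture(scope="session")
def two_gamma_mixture():
    """The true generating model of the fictive data."""
    return cm.MixtureModel(
        (cm.DistributionSpec("gamma", (10.0, 20.0)), cm.DistributionSpec("gamma", (5.0, 10.0))),
        (0.5, 0.5),
    )


@pytest.fixture(scope="session")
def gamma2_fit(fictive):
    """MLE of the two-component gamma model on the censored dataset."""
    return cm.fit_mle(fictive.censored_a, "gamma", 2, seed=0)


@pytest.fixture(scope="session")
def gamma2_trace(fictive, gamma2_fit):
    """A short posterior chain for the fitted model (unit-test sized)."""
    return cm.run_mcmc(fictive.censored_a, gamma2_fit, n_iter=1200, burn_in=100, seed=11)


def constant_trace(model: cm.MixtureModel, n_rows: int = 50) -> cm.MCMCTrace:
    """An MCMCTrace whose every draw equals ``model`` — isolates code that
    consumes a trace from posterior noise."""
    from censmix.mcmc import MCMCTrace, _natural_names, _to_natural_row
    from censmix.mle import ParamTransform

    transform = ParamTransform(model.family, model.J)
    y = transform.to_free(model)
    free = np.tile(y, (n_rows + 1, 1))
    nat = np.tile(_to_natural_row(transform, y), (n_rows + 1, 1))
    return MCMCTrace(
        draws=nat,
        logliks=np.zeros(n_rows + 1),
        param_names=_natural_names(model.family, model.J),
        burn_in=0,
        acceptance_rate=0.0,
        proposal_sds=np.full(transform.n_free, 0.1),
        priors=np.column_stack(
            [np.full(transform.n_free, -1e12), np.full(transform.n_free, 1e12)]
        ),
        seed=0,
        family=model.family,
        J=model.J,
        free_draws=free,
    )
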