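"""Feed posterior-predictive imputations into a downstream model.

Demonstrates the repeated-reanalysis pattern: a binary outcome is
regressed on a concentration whose low values are censored at a
detection limit. Each UnQ cell is replaced by a posterior-predictive
draw, a logistic regression is fitted to the completed dataset, and the
procedure is repeated so the imputation uncertainty shows up as spread
in the replicate coefficients — instead of the false certainty an
LDL/2 substitution would give.

Run:  python examples/impute_then_glm.py
"""

import math

import numpy as np
import statsmodels.api as sm

import censmix as cm
from censmix.distributions import Interval

N = 250
LDL = 60.0
N_REPLICATES = 200

rng = np.random.default_rng(7)

# synthetic study: exposure ~ gamma, outcome risk rises with log-exposure
exposure = rng.gamma(4.0, 25.0, size=N)
logit_p = -6.0 + 1.3 * np.log(exposure)
outcome = rng.uniform(size=N) < 1.0 / (1.0 + np.exp(-logit_p))

obs = cm.censor(exposure, Interval(LDL, math.inf))
print(f"{obs.n_unq} of {N} exposures below the detection limit ({LDL})")

fit = cm.fit_mle(obs, "gamma", 1, seed=0)
trace = cm.run_mcmc(obs, fit, n_iter=3000, burn_in=100, seed=1)
draws = cm.impute(trace, obs, n_draws=N_REPLICATES, seed=2)

coefs = []
for completed in draws.completed_datasets:
    x = sm.add_constant(np.log(completed))
    res = sm.GLM(outcome, x, family=sm.families.Binomial()).fit()
    coefs.append(res.params[1])
coefs = np.asarray(coefs)

lo, hi = np.quantile(coefs, [0.025, 0.975])
print(f"log-exposure coefficient across {N_REPLICATES} imputed datasets:")
print(f"  mean {coefs.mean():.3f}, 95% replicate interval [{lo:.3f}, {hi:.3f}]")
print(
    "  (imputing from the marginal exposure fit, not conditional on the\n"
    "   outcome, deliberately avoids circularity; it attenuates the slope\n"
    "   toward zero relative to the generating value 1.3)"
)

# LDL/2 substitution for comparison: a single fabricated dataset
substituted = np.where(obs.unq_mask, LDL / 2.0, obs.values)
res = sm.GLM(outcome, sm.add_constant(np.log(substituted)), family=sm.families.Binomial()).fit()
print(f"LDL/2 substitution gives a single point estimate: {res.params[1]:.3f}")
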