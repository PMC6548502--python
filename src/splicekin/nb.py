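"""Negative binomial log-likelihood shared by the spike-in GLM and the
kinetic fits.

The NB is parameterised by its mean ``mu`` and a dispersion (size) ``theta``
such that ``var = mu + mu**2 / theta``; ``theta -> inf`` recovers Poisson
noise.  The gamma-function form below is continuous in ``k``, which lets
noiseless round-trip tests fit non-integer expected counts directly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_MU_FLOOR = 1e-12
_POISSON_THETA = 1e8


def nb_loglik(k, mu, theta):
    """Sum of NB(mean=mu, size=theta) log-likelihood terms.

    ``k`` and ``mu`` broadcast; ``theta`` is scalar. Equals
    ``scipy.stats.nbinom.logpmf(k, theta, theta/(theta+mu)).sum()`` for
    integer ``k``.
    """
    k = np.asarray(k, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    if theta >= _POISSON_THETA:
        # exact theta -> inf limit; the gamma-function form loses all
        # precision to cancellation between ~theta*log(theta) terms there
        return float(np.sum(k * np.log(mu) - mu - gammaln(k + 1.0)))
    return float(
        np.sum(
            gammaln(k + theta)
            - gammaln(theta)
            - gammaln(k + 1.0)
            + theta * (np.log(theta) - np.log(theta + mu))
            + k * (np.log(mu) - np.log(theta + mu))
        )
    )


def nb_dloglik_dmu(k, mu, theta):
    """Element-wise derivative of the NB log-likelihood wrt the mean."""
    k = np.asarray(k, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    return k / mu - (k + theta) / (theta + mu)
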