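"""Shared hand-built fixtures for threshold/scenario tests."""

import numpy as np
from scipy.special import logsumexp

from maxampo.maxent_core import FeatureExpander, FeatureSpec, MaxEntModel


def single_driver_model(stack, var="clim01", weight=4.0):
    """Model with a single linear feature: response strictly increasing in
    ``var``, log-partition computed over the stack's land cells."""
    land = stack.land_mask()
    vals = stack[var][land]
    exp = FeatureExpander(classes=["linear"])
    exp.variables = [var]
    exp.normalisers = {var: (float(vals.min()), float(vals.max()))}
    exp.specs = [FeatureSpec("linear", (var,))]
    scaled = (vals - vals.min()) / (vals.max() - vals.min())
    log_z = float(logsumexp(weight * scaled))
    q = np.exp(weight * scaled - log_z)
    entropy = float(-np.sum(q * np.log(q)))
    return MaxEntModel(
        expander=exp, weights=np.array([weight]), reg_weights=np.array([0.0]),
        clamp=None, log_partition=log_z, entropy=entropy,
        n_background=int(land.sum()), converged=True,
    )
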