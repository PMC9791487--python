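"""Hebbian LTP/LTD rule applied to every excitatory-to-excitatory synapse.

The rule is local and threshold-based.  Writing ω for the presynaptic
cell's low-pass output estimate and V for the postsynaptic membrane
potential:

* LTP (+Δw):  ω ≥ ϑ_pre  and  V ≥ ϑ_+
* LTD (−Δw):  ω ≥ ϑ_pre  and  ϑ_− ≤ V < ϑ_+, or — heterosynaptic case,
  on by default — ω < ϑ_pre and V ≥ ϑ_+
* no change otherwise.

Weights are clipped to [0, w_max] after every update.  The presynaptic
quantity is the rate estimate ω (training time constant 30 steps) rather
than the instantaneous spike, so "presynaptic output activity" is a level
comparable against the 0.05 threshold.  Heterosynaptic depression lets
synapses from silent cells onto strongly active cells decay, which is what
keeps unrelated inputs from being absorbed into a forming cell assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .netcore import ModelParams, Network, NetworkState

__all__ = ["SynapseEvent", "classify_synapse_event", "apply_hebbian", "HebbianReport"]


@dataclass(frozen=True)
class SynapseEvent:
    pre_activity: float
    post_potential: float
    outcome: str  # "LTP" | "LTD" | "none"
    delta: float


def classify_synapse_event(
    pre_activity: float, post_potential: float, params: ModelParams
) -> SynapseEvent:
    """Classify one synapse's update for given pre/post quantities."""
    if not (np.isfinite(pre_activity) and np.isfinite(post_potential)):
        raise ValueError("non-finite pre/post values")
    pre_on = pre_activity >= params.theta_pre
    if pre_on and post_potential >= params.theta_ltp:
        outcome, delta = "LTP", params.delta_w
    elif pre_on and params.theta_ltd <= post_potential < params.theta_ltp:
        outcome, delta = "LTD", -params.delta_w
    elif (not pre_on) and params.hetero_ltd and post_potential >= params.theta_ltp:
        outcome, delta = "LTD", -params.delta_w
    else:
        outcome, delta = "none", 0.0
    return SynapseEvent(pre_activity, post_potential, outcome, delta)


@dataclass(frozen=True)
class HebbianReport:
    n_ltp: int
    n_ltd: int
    n_none: int


@njit(cache=True)
def _hebbian_kernel(
    indptr, indices, data, omega_pre, v_post,
    th_pre, th_plus, th_minus, dw, w_max, hetero,
):  # pragma: no cover - exercised through apply_hebbian
    n_ltp = 0
    n_ltd = 0
    for post in range(indptr.size - 1):
        v = v_post[post]
        if v < th_minus:
            continue  # no branch can fire for this postsynaptic cell
        post_hi = v >= th_plus
        for k in range(indptr[post], indptr[post + 1]):
            pre_on = omega_pre[indices[k]] >= th_pre
            if pre_on:
                if post_hi:
                    w = data[k] + dw
                    n_ltp += 1
                else:
                    w = data[k] - dw
                    n_ltd += 1
            elif hetero and post_hi:
                w = data[k] - dw
                n_ltd += 1
            else:
                continue
            if w < 0.0:
                w = 0.0
            elif w > w_max:
                w = w_max
            data[k] = w
    return n_ltp, n_ltd


def apply_hebbian(network: Network, state: NetworkState) -> HebbianReport:
    """Update every excitatory synapse in place; returns event counts.

    Must only be called during training: raises if learning is disabled on
    the network (protocol guard for the read-out phase).
    """
    if not network.learning_enabled:
        raise RuntimeError(
            "apply_hebbian called while learning is disabled (testing phase)"
        )
    p = network.params
    w = network.weights
    n_ltp, n_ltd = _hebbian_kernel(
        w.indptr, w.indices, w.data, state.omega, state.V,
        p.theta_pre, p.theta_ltp, p.theta_ltd, p.delta_w, p.w_max,
        p.hetero_ltd,
    )
    return HebbianReport(
        n_ltp=int(n_ltp), n_ltd=int(n_ltd),
        n_none=int(w.data.size - n_ltp - n_ltd),
    )
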