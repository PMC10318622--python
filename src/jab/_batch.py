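"""Batched yearly iteration of the stage map and its hand-derived adjoint.

Arrays carry the species on the last axis and arbitrary batch axes in front
(plots, or chains × plots); parameter arrays must broadcast against the state
arrays.  The adjoint (`step_vjp`) is the exact reverse-mode derivative of one
step, used to backpropagate the observation likelihood through the
deterministic inter-survey simulation.  It is verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

PARAM_KEYS = ("r", "c_J", "s", "g", "c_A", "h", "b", "c_B")


def step_batch(J, A, B, nat, Lp, beta_uA, beta_mA):
    """One step of the map; returns (J', A', B')."""
    BA = A * beta_mA + B
    SJ = J.sum(-1, keepdims=True)
    SBA = BA.sum(-1, keepdims=True)
    den_J = 1.0 + nat["c_J"] * SJ + nat["s"] * SBA
    den_A = 1.0 + nat["c_A"] * SBA
    den_B = 1.0 + nat["c_B"] * SBA
    Jn = Lp + nat["r"] * BA + (1.0 - nat["g"]) * J / den_J
    An = nat["g"] * J / den_J + (1.0 - nat["h"]) * A / den_A
    Bn = nat["h"] * A * beta_uA / den_A + (1.0 + nat["b"]) * B / den_B
    return Jn, An, Bn


def forward_sim(J0, A0, B0, nat, Lp, beta_uA, beta_mA, T: int):
    """Simulate ``T`` steps, returning per-stage lists of the T+1 states."""
    Js, As, Bs = [J0], [A0], [B0]
    J, A, B = J0, A0, B0
    for _ in range(T):
        J, A, B = step_batch(J, A, B, nat, Lp, beta_uA, beta_mA)
        Js.append(J)
        As.append(A)
        Bs.append(B)
    return Js, As, Bs


def step_vjp(J, A, B, nat, Lp, beta_uA, beta_mA, gJ, gA, gB, plot_axis=-2):
    """Reverse-mode derivative of one step.

    Given cotangents ``(gJ, gA, gB)`` of the *next* state, returns the
    cotangents of the current state ``(aJ, aA, aB)``, the cotangent of ``Lp``,
    and natural-scale parameter cotangents summed over the plot axis.
    """
    BA = A * beta_mA + B
    SJ = J.sum(-1, keepdims=True)
    SBA = BA.sum(-1, keepdims=True)
    den_J = 1.0 + nat["c_J"] * SJ + nat["s"] * SBA
    den_A = 1.0 + nat["c_A"] * SBA
    den_B = 1.0 + nat["c_B"] * SBA

    one_m_g = 1.0 - nat["g"]
    one_m_h = 1.0 - nat["h"]
    one_p_b = 1.0 + nat["b"]

    adj_den_J = -(gJ * one_m_g * J + gA * nat["g"] * J) / den_J**2
    adj_den_A = -(gA * one_m_h * A + gB * nat["h"] * A * beta_uA) / den_A**2
    adj_den_B = -(gB * one_p_b * B) / den_B**2

    aJ = gJ * one_m_g / den_J + gA * nat["g"] / den_J
    aA = gA * one_m_h / den_A + gB * nat["h"] * beta_uA / den_A
    aB = gB * one_p_b / den_B
    aBA = gJ * nat["r"]

    adj_SJ = (adj_den_J * nat["c_J"]).sum(-1, keepdims=True)
    adj_SBA = (adj_den_J * nat["s"] + adj_den_A * nat["c_A"]
               + adj_den_B * nat["c_B"]).sum(-1, keepdims=True)

    aJ = aJ + adj_SJ
    aBA = aBA + adj_SBA
    aA = aA + aBA * beta_mA
    aB = aB + aBA

    def psum(x):
        return x.sum(axis=plot_axis, keepdims=True)

    param_adj = {
        "r": psum(gJ * BA),
        "g": psum((gA - gJ) * J / den_J),
        "h": psum((gB * beta_uA - gA) * A / den_A),
        "b": psum(gB * B / den_B),
        "c_J": psum(adj_den_J * SJ),
        "s": psum(adj_den_J * SBA),
        "c_A": psum(adj_den_A * SBA),
        "c_B": psum(adj_den_B * SBA),
    }
    return aJ, aA, aB, gJ, param_adj
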