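"""Seed-stream management.

A single master seed is split into named, order-stable child streams, one per
stochastic stage of the simulation.  The split is performed unconditionally
for every stage, whether or not the stage is active in a given run, so that
toggling an optional stage (equalization, UMI collapse) never perturbs the
random stream consumed by any other stage.  This is what makes paired
unequalized/equalized runs share identical latent mRNA, capture and
tagmentation noise.
"""

from __future__ import annotations

import numpy as np

# Order is part of the reproducibility contract; never reorder.
STAGE_STREAMS = (
    "draws",      # per-cell parameter realizations (omega, lambda, rho, gamma, rho2)
    "initial",    # Poisson latent mRNA
    "capture",    # capture multinomial
    "equalize",   # dilution factors + equalization multinomial (+ post-eq scaling)
    "tagment",    # tagmentation multinomial
    "sequence",   # sequencing multinomial
    "collapse",   # UMI occupancy draws
)


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Derive one independent Generator per protocol stage from a master seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGE_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(STAGE_STREAMS, children)}
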