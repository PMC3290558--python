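"""The canonical set of group organizations studied with the model.

Six continuum networks of 10 individuals span centralized to
decentralized organization (star, highly / intermediately / low / very
low centralized, equal), complemented by a chain (linear hierarchy) and
a seeded connected Erdős–Rényi random network.
"""

from __future__ import annotations

from .networks import (
    SocialNetwork,
    build_chain_network,
    build_continuum_network,
    build_random_network,
)

__all__ = ["CONTINUUM_R_CC", "CONTINUUM_NAMES", "make_canonical_networks"]

#: non-central-to-central affiliation r(c,C) of each continuum network
CONTINUUM_R_CC: dict[str, float] = {
    "star": 1.0,
    "highly_centralized": 0.75,
    "intermediately_centralized": 0.50,
    "low_centralized": 0.25,
    "very_low_centralized": 0.125,
    "equal": 1.0 / 9.0,
}

CONTINUUM_NAMES: tuple[str, ...] = tuple(CONTINUUM_R_CC)

#: group size shared by every canonical network
GROUP_SIZE = 10

#: defaults for the canonical random network (density matching the equal
#: network's full connectivity in expectation; fixed seed for reproducibility)
RANDOM_P = 0.5
RANDOM_SEED = 42


def make_canonical_networks(
    n: int = GROUP_SIZE,
    random_p: float = RANDOM_P,
    random_seed: int = RANDOM_SEED,
) -> dict[str, SocialNetwork]:
    """Named canonical networks: six continuum plus chain and random."""
    nets = {
        name: build_continuum_network(n, r_cc)
        for name, r_cc in CONTINUUM_R_CC.items()
    }
    nets["chain"] = build_chain_network(n)
    nets["random"] = build_random_network(n, p=random_p, seed=random_seed)
    return nets
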