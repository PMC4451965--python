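"""Bundled example networks with documented expected outcomes, and a
seeded random-network generator for property tests.

Every fixture ships as on-disk ``.rxn`` (and, where the influence pattern
is not plain mass-action, ``.tsv``) files, so loading a fixture also
exercises the text parsers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from types import MappingProxyType
from typing import Dict, Mapping, Tuple

from ..network import (
    InfluenceMatrix,
    Reaction,
    ReactionNetwork,
    mass_action_influence,
    parse_influence_tsv,
    parse_network,
)

__all__ = ["Fixture", "FIXTURE_NAMES", "get_fixture", "random_network"]

FIXTURE_NAMES: Tuple[str, ...] = (
    "mitosis_z1",
    "mitosis_z2",
    "ubiquitination",
    "phospho_two_site",
    "cascade_2layer",
    "apoptosis",
    "michaelis_menten",
)


@dataclass(frozen=True)
class Fixture:
    name: str
    network: ReactionNetwork
    influence: InfluenceMatrix
    expected: Mapping[str, object]
    description: str


# (rxn file, tsv file or None for mass-action, short description)
_SOURCES: Dict[str, Tuple[str, str | None, str]] = {
    "mitosis_z1": (
        "mitosis.rxn", "mitosis_z1.tsv",
        "mitosis-onset toy model, phosphorylation rate self-activated by its product",
    ),
    "mitosis_z2": (
        "mitosis.rxn", "mitosis_z2.tsv",
        "mitosis-onset toy model, phosphorylation rate independent of its product",
    ),
    "ubiquitination": (
        "ubiquitination.rxn", "ubiquitination.tsv",
        "Ring1B/Bmi1 histone-H2A ubiquitination model",
    ),
    "phospho_two_site": (
        "phospho_two_site.rxn", None,
        "two-site distributive phosphorylation cycle, mass-action",
    ),
    "cascade_2layer": (
        "cascade_2layer.rxn", None,
        "two-layer phosphorylation cascade with explicit positive feedback, mass-action",
    ),
    "apoptosis": (
        "apoptosis.rxn", None,
        "basic caspase-activation model of apoptosis, mass-action",
    ),
    "michaelis_menten": (
        "michaelis_menten.rxn", None,
        "bare Michaelis-Menten mechanism, mass-action",
    ),
}

# Documented outcomes; every entry here is asserted by the test suite.
_EXPECTED: Dict[str, Dict[str, object]] = {
    "mitosis_z1": {
        "n_species": 3,
        "n_reactions": 4,
        "rank": 2,
        "verdict": "INCONCLUSIVE",
        "multistationary": True,
        "total_circuits": 7,
        "positive_loops": 3,
        "wrong_sign_terms": 2,
        "wrong_sign_nuclei": 2,
        "relevant_loops": 1,
        "relevant_loop_species": [("Xnucp",)],
    },
    "mitosis_z2": {
        "n_species": 3,
        "n_reactions": 4,
        "rank": 2,
        "verdict": "INJECTIVE",
        "multistationary": False,
        "wrong_sign_terms": 0,
        "relevant_loops": 0,
    },
    "ubiquitination": {
        "n_species": 10,
        "n_reactions": 15,
        "verdict": "INCONCLUSIVE",
        "multistationary": True,
        "relevant_loops": 2,
        # self-ubiquitination of the complex Z and of R
        "relevant_loop_species": [("Rub",), ("Zub",)],
    },
    "phospho_two_site": {
        "n_species": 10,
        "n_reactions": 12,
        "verdict": "INCONCLUSIVE",
        "multistationary": True,
        "relevant_loops": 2,
        "loop_species_counts": [2, 4],
        "four_species_loop_negative_edges": 2,
        # the 2-species loop is the Michaelis-Menten loop on (E, ES1)
        "two_species_loop_species": ("E", "ES1"),
    },
    "cascade_2layer": {
        "n_species": 11,
        "n_reactions": 13,
        "verdict": "INCONCLUSIVE",
        "multistationary": True,
        "relevant_loops": 3,
        "max_loop_species": 5,
    },
    "apoptosis": {
        "n_species": 6,
        "n_reactions": 14,
        "verdict": "INCONCLUSIVE",
        "multistationary": True,
        "relevant_loops": 2,
    },
    "michaelis_menten": {
        "n_species": 4,
        "n_reactions": 3,
        "verdict": "INJECTIVE",
        "multistationary": False,
        "relevant_loops": 0,
    },
}


def _read_data(filename: str) -> str:
    return (resources.files(__name__) / "data" / filename).read_text(encoding="utf-8")


def get_fixture(name: str) -> Fixture:
    """Load a fixture by name (see ``FIXTURE_NAMES``)."""
    if name not in _SOURCES:
        raise KeyError(
            f"unknown fixture {name!r}; known fixtures: {', '.join(FIXTURE_NAMES)}"
        )
    rxn_file, tsv_file, description = _SOURCES[name]
    net = parse_network(_read_data(rxn_file))
    if tsv_file is None:
        influence = mass_action_influence(net)
    else:
        influence = parse_influence_tsv(net, _read_data(tsv_file))
    return Fixture(name, net, influence, MappingProxyType(_EXPECTED[name]), description)


def random_network(
    seed: int, n_max: int = 5, m_max: int = 8
) -> Tuple[ReactionNetwork, InfluenceMatrix]:
    """Reproducible random network + influence pattern for property tests.

    Stoichiometric coefficients lie in {0, 1, 2}; every reaction has a
    nonzero net-stoichiometry column; the influence support is a superset
    of the reactant support with random signs.  Identical seeds give
    identical output.
    """
    if n_max > 6:
        raise ValueError("n_max must be <= 6 to keep brute-force oracles tractable")
    rng = random.Random(seed)
    n = rng.randint(2, n_max)
    m = rng.randint(1, m_max)
    species = [f"X{i}" for i in range(1, n + 1)]
    reactions = []
    for j in range(1, m + 1):
        while True:
            alpha = [rng.choices((0, 1, 2), weights=(11, 7, 2))[0] for _ in range(n)]
            beta = [rng.choices((0, 1, 2), weights=(11, 7, 2))[0] for _ in range(n)]
            if (any(alpha) or any(beta)) and alpha != beta:
                break
        reactions.append(
            Reaction(
                f"r{j}",
                {name: c for name, c in zip(species, alpha) if c},
                {name: c for name, c in zip(species, beta) if c},
            )
        )
    net = ReactionNetwork(species, reactions)
    signs = []
    for i in range(n):
        row = []
        for j in range(m):
            if net.alpha(i, j) > 0:
                row.append(-1 if rng.random() < 0.25 else 1)
            elif rng.random() < 0.15:
                row.append(rng.choice((1, -1)))
            else:
                row.append(0)
        signs.append(tuple(row))
    return net, InfluenceMatrix(tuple(signs))
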