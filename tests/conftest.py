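"""Shared fixtures: tiny fully-enumerable designs and enumeration oracles.

The oracles deliberately avoid the package's closed-form machinery: they
enumerate the per-subject outcome space of small trials directly from the
four-cell multinomial law, so that selection probabilities, conditional
biases, Rao-Blackwell estimates and conditional tail probabilities can be
checked against independent brute force.
"""

from __future__ import annotations

import numpy as np
import pytest

from seamsel import DesignSpec, EndpointModel, TrialData
from seamsel.bivbin import binom_pmf_vector, counts_pmf


def count_triples(n: int) -> list[tuple[int, int, int]]:
    """All admissible (x, y, z) count triples for n subjects."""
    return [(x, y, z) for x in range(n + 1) for y in range(n + 1)
            for z in range(max(0, x + y - n), min(x, y) + 1)]


@pytest.fixture(scope="session")
def tiny_design() -> DesignSpec:
    """G=2 treatments plus control, two subjects per stage: fully enumerable."""
    return DesignSpec(G=2, n1=(2, 2, 2), n2=(2, 2, 2))


class TinyTrialEnumerator:
    """Brute-force enumeration of G=2, n1=n2=2 trials.

    Yields every outcome (competitor stage-1 count, selected group's
    stage-1 and stage-2 (x, y, z) triples) with its exact probability,
    restricted to the event Q = s under the argmax/smallest-index rule.
    """

    def __init__(self, s: int, xi, pi, rho):
        self.s = s
        self.other = 3 - s
        self.xi, self.pi, self.rho = xi, pi, rho
        self.model = EndpointModel(xi[s], pi[s], rho, 2)
        self.pmf_other = binom_pmf_vector(2, xi[self.other])

    def outcomes(self):
        for xo in range(3):
            po = float(self.pmf_other[xo])
            for t1 in count_triples(2):
                p1 = counts_pmf(*t1, self.model)
                if p1 == 0.0:
                    continue
                selected = t1[0] >= xo if self.s == 1 else t1[0] > xo
                if not selected:
                    continue
                for t2 in count_triples(2):
                    p2 = counts_pmf(*t2, self.model)
                    if p2 == 0.0:
                        continue
                    yield xo, t1, t2, po * p1 * p2

    def trial(self, xo: int, t1, t2, control=(0, 0, 0, 0, 0, 0)) -> TrialData:
        """Assemble a TrialData for one enumerated outcome."""
        x1v = [control[0], 0, 0]
        x1v[self.s] = t1[0]
        x1v[self.other] = xo
        c_x1, c_y1, c_z1, c_x2, c_y2, c_z2 = control
        return TrialData(
            s=self.s,
            x1=tuple(x1v),
            x2={0: c_x2, self.s: t2[0]},
            y={0: c_y1 + c_y2, self.s: t1[1] + t2[1]},
            z={0: c_z1 + c_z2, self.s: t1[2] + t2[2]},
        )


@pytest.fixture
def tiny_enumerator():
    return TinyTrialEnumerator


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
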