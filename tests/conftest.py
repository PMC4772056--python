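"""Shared fixtures and the independent proton-counting oracle.

The oracle builds each C18 acyl chain atom by atom and classifies every
proton by its local environment, independently of the closed-form counts
used by the generator.
"""

from __future__ import annotations

from collections import Counter

import pytest

import oilnmr as o

#: First carbons of the cis double bonds of each modelled chain.
CHAIN_DOUBLE_BONDS = {
    "saturated": (),
    "oleic": (9,),
    "linoleic": (9, 12),
    "linolenic": (9, 12, 15),
}


def chain_proton_signals(double_bond_starts: tuple[int, ...]) -> Counter:
    """Signals of one C18 acyl chain, classified carbon by carbon.

    C1 is the carbonyl (no protons).  Olefinic carbons carry one proton
    (J); the terminal methyl carries three (B when the chain is n-3, else
    A); C2 is alpha to the carbonyl (F), C3 beta (D); a CH2 flanked by two
    olefinic carbons is bis-allylic (G), by one is allylic (E); everything
    else is bulk chain (C).
    """
    db_carbons = set()
    for start in double_bond_starts:
        db_carbons.update((start, start + 1))
    signals: Counter = Counter()
    for c in range(2, 19):
        if c == 18:
            signals["B" if 15 in double_bond_starts else "A"] += 3
        elif c in db_carbons:
            signals["J"] += 1
        elif c == 2:
            signals["F"] += 2
        elif c == 3:
            signals["D"] += 2
        else:
            n_olefinic_neighbours = len({c - 1, c + 1} & db_carbons)
            if n_olefinic_neighbours == 2:
                signals["G"] += 2
            elif n_olefinic_neighbours == 1:
                signals["E"] += 2
            else:
                signals["C"] += 2
    return signals


def oracle_proton_counts(x: float, y: float, z: float, w: float) -> dict[str, float]:
    """Per-mole-TG proton counts for a chain mixture, from the atom oracle."""
    counts: Counter = Counter()
    for fraction, chain in zip(
        (x, y, z, w), ("saturated", "oleic", "linoleic", "linolenic")
    ):
        for signal, n in chain_proton_signals(CHAIN_DOUBLE_BONDS[chain]).items():
            counts[signal] += 3.0 * fraction * n  # three chains per TG
    counts["H"] += 4.0  # glycerol sn-1,3
    counts["I"] += 1.0  # glycerol sn-2
    return {s: counts.get(s, 0.0) for s in o.simulate.SIGNAL_NAMES}


@pytest.fixture(scope="session")
def default_params():
    return o.AcquisitionParameters()


@pytest.fixture(scope="session")
def regions():
    return o.default_regions()


@pytest.fixture(scope="session")
def olive_spec():
    return o.OilSpec.preset("olive")


@pytest.fixture(scope="session")
def olive_spectrum(olive_spec):
    """Noiseless transformed olive spectrum (no phasing/baseline needed)."""
    return o.synthesize_spectrum(olive_spec)


@pytest.fixture(scope="session")
def olive_processed(olive_spec):
    """Full automatic chain applied to a noiseless olive FID."""
    fid = o.synthesize_fid(olive_spec)
    return o.process(fid)
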