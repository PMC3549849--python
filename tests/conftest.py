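"""Shared fixtures: exhaustively enumerated structure ensembles.

The enumeration (with genus and irreducibility per structure) is the ground
truth that both the generating functions and the dynamic programs are
checked against, so it is built once per session.
"""

from __future__ import annotations

import pytest

from rnasparse import enumerate_structures


@pytest.fixture(scope="session")
def enumerated():
    """{n: list of Structure} for n = 1..12, all genera."""
    return {n: enumerate_structures(n) for n in range(1, 13)}


@pytest.fixture(scope="session")
def genus_counts(enumerated):
    """{(g, n): (count, irreducible count)} from the enumeration."""
    table = {}
    for n, structs in enumerated.items():
        for s in structs:
            g = s.genus
            c, ci = table.get((g, n), (0, 0))
            table[(g, n)] = (c + 1, ci + (1 if s.irreducible else 0))
    return table
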