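"""Small hand-authored lattices for tests and examples.

Each fixture is an embedded text snapshot ('.' empty, 'C' cooperator, 'D'
defector, digit = punisher with that tolerance threshold) parsed into a
:class:`~pggmob.lattice.Population` on demand.
"""

from __future__ import annotations

from .lattice import Population

__all__ = ["fixture_lattice", "FIXTURES"]

FIXTURES = {
    # a single punisher (theta=2) surrounded by 8 defectors, rest empty
    "lone_punisher_theta2": """
        .....
        .DDD.
        .D2D.
        .DDD.
        .....
    """,
    # fully occupied 3x3 lattice of defectors (absorbing from the start)
    "all_defectors_3x3": """
        DDD
        DDD
        DDD
    """,
    # cooperator block facing a defector block across an empty column
    "cd_interface_5x5": """
        CC.DD
        CC.DD
        CC.DD
        CC.DD
        CC.DD
    """,
    # a lone cooperator with no neighbors: organizes a trivial 1-member game
    "isolated_cooperator_5x5": """
        .....
        .....
        ..C..
        .....
        .....
    """,
    # never-migrating punisher (theta=8) among mixed company
    "punisher8_mixed_5x5": """
        C.D..
        .8D..
        ..C..
        .D...
        .....
    """,
}


def fixture_lattice(name: str) -> Population:
    """A fresh :class:`Population` parsed from the named embedded snapshot."""
    try:
        text = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return Population.from_text(text)
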