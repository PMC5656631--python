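"""Strategy encoding shared by the whole package.

Sites on the lattice hold one of: empty, cooperator (C), defector (D), or a
punisher carrying a heritable defector-tolerance threshold theta in [0, 8]
(8 = the Moore group-size cap, i.e. a punisher that never migrates).  The
integer codes below are the in-memory representation used by the simulation
kernel; the single-character labels are the text-snapshot and reporting
vocabulary.
"""

from __future__ import annotations

EMPTY = -1
COOPERATOR = 0
DEFECTOR = 1
PUNISHER_BASE = 2  # punisher with threshold t -> code PUNISHER_BASE + t

THETA_MAX = 8  # Moore neighborhood size; a group holds at most 8 defectors
NUM_CLASSES = 2 + THETA_MAX + 1  # C, D, P0..P8

#: reporting labels, indexed by strategy code
CLASS_LABELS: tuple[str, ...] = ("C", "D") + tuple(f"P{t}" for t in range(THETA_MAX + 1))

_LABEL_TO_CODE = {lab: i for i, lab in enumerate(CLASS_LABELS)}


def punisher_code(theta: int) -> int:
    """Integer strategy code for a punisher with tolerance ``theta``."""
    if not 0 <= theta <= THETA_MAX:
        raise ValueError(f"theta must be in [0, {THETA_MAX}], got {theta}")
    return PUNISHER_BASE + theta


def is_punisher(code: int) -> bool:
    return code >= PUNISHER_BASE


def is_contributor(code: int) -> bool:
    """Cooperators and punishers both contribute c to the common pool."""
    return code == COOPERATOR or code >= PUNISHER_BASE


def code_for_label(label: str) -> int:
    try:
        return _LABEL_TO_CODE[label]
    except KeyError:
        raise ValueError(f"unknown strategy label {label!r}; valid: {CLASS_LABELS}") from None


def label_for_code(code: int) -> str:
    if not 0 <= code < NUM_CLASSES:
        raise ValueError(f"invalid strategy code {code}")
    return CLASS_LABELS[code]


def kind_of(label: str) -> str:
    """Collapse a class label to its kind: 'C', 'D' or 'P'."""
    return "P" if label.startswith("P") else label
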