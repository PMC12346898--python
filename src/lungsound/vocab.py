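"""Controlled vocabularies: auscultation positions and diagnostic classes.

Positions follow the clinical naming used for multi-site chest auscultation:
six lung fields (right/left x upper/mid/lower) on the anterior (``F``) or
posterior (``B``) chest wall, e.g. ``BRUL`` = back right upper lung.

The canonical channel order is fixed so that stacked feature grids are
reproducible: anterior before posterior; within a view, right before left;
within a side, upper -> mid -> lower.
"""

from __future__ import annotations

_VIEWS = ("F", "B")
_FIELDS = ("RUL", "RML", "RLL", "LUL", "LML", "LLL")

#: The 12 recognised auscultation position codes, in canonical channel order.
POSITIONS: tuple[str, ...] = tuple(v + f for v in _VIEWS for f in _FIELDS)

_POSITION_RANK = {p: i for i, p in enumerate(POSITIONS)}

#: Diagnostic classes, index-aligned with the integer labels 0, 1, 2.
LABELS: tuple[str, ...] = ("normal", "wheeze", "fine_crackle")

LABEL_TO_INDEX = {name: i for i, name in enumerate(LABELS)}
INDEX_TO_LABEL = {i: name for i, name in enumerate(LABELS)}

UNKNOWN_POSITION = "unknown"


def canonicalize_position(code: str) -> str:
    """Normalise a position code to the 12-token vocabulary.

    Accepts any capitalisation (``brul`` -> ``BRUL``). Raises ``ValueError``
    for codes outside the vocabulary; ``unknown`` passes through unchanged.
    """
    if code == UNKNOWN_POSITION:
        return code
    canon = code.strip().upper()
    if canon not in _POSITION_RANK:
        raise ValueError(
            f"unknown auscultation position {code!r}; expected one of {POSITIONS}"
        )
    return canon


def position_sort_key(code: str):
    """Sort key implementing the canonical channel order."""
    return _POSITION_RANK.get(code, len(POSITIONS))


def canonical_order(codes) -> list[str]:
    """Return the given position codes sorted into canonical channel order."""
    canon = [canonicalize_position(c) for c in codes]
    if len(set(canon)) != len(canon):
        raise ValueError(f"duplicate positions in {codes!r}")
    return sorted(canon, key=position_sort_key)


def validate_label(label: str) -> str:
    if label not in LABEL_TO_INDEX:
        raise ValueError(f"unknown class label {label!r}; expected one of {LABELS}")
    return label
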