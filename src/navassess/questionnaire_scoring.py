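"""SUS and ITC-SOPI negative-effects scoring.

The System Usability Scale (SUS) has 10 Likert items (1–5).  Odd items are
positively worded and contribute ``response - 1``; even items are negatively
worded and contribute ``5 - response``; the summed contributions are scaled by
2.5 onto 0 ("lack of usability") to 100 ("optimal usability").  Scores are
interpreted on a 7-level adjective scale from "worst imaginable" to "best
imaginable".

The ITC-SOPI negative-effects score is simply the arithmetic mean of the
completed items (1–5 Likert); the item count is not fixed here because the
instrument text is licensed content and subsets may be administered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._exceptions import InputError

#: adjective bands on [0, 100]; integer edges from the published rating scale,
#: made half-open so fractional scores fall in exactly one band
SUS_BANDS: tuple[tuple[float, float, str], ...] = (
    (0.0, 26.0, "worst imaginable"),
    (26.0, 40.0, "awful"),
    (40.0, 50.0, "poor"),
    (50.0, 70.0, "OK"),
    (70.0, 85.0, "good"),
    (85.0, 100.0, "excellent"),
    (100.0, 100.0, "best imaginable"),
)


@dataclass(frozen=True)
class SusScore:
    value: float
    band: str


@dataclass(frozen=True)
class ItcNeScore:
    value: float
    n_completed: int


def _check_likert(items: Sequence[int], instrument: str) -> None:
    for idx, item in enumerate(items, start=1):
        if item is None:
            continue
        if not (isinstance(item, (int,)) or float(item).is_integer()):
            raise InputError(f"{instrument} item {idx}: response {item!r} is not an integer")
        if not 1 <= int(item) <= 5:
            raise InputError(f"{instrument} item {idx}: response {item} outside 1–5")


def sus_band(value: float) -> str:
    """Map a 0–100 SUS score onto the 7-level adjective scale."""
    if not 0.0 <= value <= 100.0:
        raise InputError(f"SUS score {value} outside [0, 100]")
    if value == 100.0:
        return "best imaginable"
    for lo, hi, label in SUS_BANDS[:-1]:
        if lo <= value < hi:
            return label
    raise AssertionError("unreachable: bands partition [0, 100]")


def score_sus(items: Sequence[int]) -> SusScore:
    """Score a 10-item SUS response vector.

    Items must be integers 1–5; item positions are 1-based, so ``items[0]`` is
    item 1 (odd, positively worded).
    """
    if len(items) != 10:
        raise InputError(f"SUS requires exactly 10 items, got {len(items)}")
    if any(i is None for i in items):
        raise InputError("SUS does not allow blank items")
    _check_likert(items, "SUS")
    total = 0
    for pos, resp in enumerate(items, start=1):
        resp = int(resp)
        total += (resp - 1) if pos % 2 == 1 else (5 - resp)
    value = total * 2.5
    return SusScore(value=value, band=sus_band(value))


def score_itc_ne(
    items: Sequence[int | None], completed_mask: Sequence[bool] | None = None
) -> ItcNeScore:
    """Mean of completed ITC-SOPI negative-effects items.

    ``completed_mask`` marks which items were answered; if omitted, items that
    are ``None`` count as blank.  At least one completed item is required.
    """
    if completed_mask is not None:
        if len(completed_mask) != len(items):
            raise InputError("completed_mask length must match items")
        kept = [items[i] for i in range(len(items)) if completed_mask[i]]
        if any(i is None for i in kept):
            raise InputError("completed item is blank")
    else:
        kept = [i for i in items if i is not None]
    if not kept:
        raise InputError("ITC-SOPI NE requires at least one completed item")
    _check_likert(kept, "ITC-SOPI NE")
    return ItcNeScore(value=sum(int(i) for i in kept) / len(kept), n_completed=len(kept))
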