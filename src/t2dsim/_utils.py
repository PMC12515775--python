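"""Shared helpers: deterministic hashing, rounding, per-person random streams."""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Any

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (presentation-style rounding).

    Python's built-in ``round`` uses banker's rounding; published tables
    conventionally round half up, so formatted outputs go through this.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def stable_id_hash(person_id: Any) -> int:
    """Map an opaque person identifier to a stable 64-bit integer.

    Independent of Python's salted ``hash`` so that random substreams are
    reproducible across processes and runs.
    """
    digest = hashlib.sha256(str(person_id).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def person_rng(master_seed: int, person_id: Any) -> np.random.Generator:
    """Random generator for one person, derived from the master seed.

    The stream depends only on ``(master_seed, person_id)`` — not on the
    scenario, the cohort ordering, or execution order — which is what makes
    common-random-number comparisons across scenarios valid.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0xFFFFFFFFFFFF, stable_id_hash(person_id)])
    )


def person_uniform_block(
    master_seed: int, person_id: Any, n_cycles: int, n_slots: int
) -> np.ndarray:
    """Pre-drawn uniforms indexed by (cycle, slot) for one person.

    Slot assignment is fixed by the caller (mortality, one slot per
    complication, biomarker residuals), so a draw consumed at cycle ``c``
    for outcome ``j`` is identical in every scenario regardless of how the
    biomarker paths diverge.
    """
    return person_rng(master_seed, person_id).random((n_cycles, n_slots))


def config_hash(obj: Any) -> str:
    """Short deterministic hash of a JSON-serialisable configuration."""

    def _default(o: Any):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.generic):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=_default).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]
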