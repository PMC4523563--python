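"""Color-zone tape model.

A length-based weight-estimation tape is an ordered, contiguous partition of
supine height (cm) into named color zones, each carrying a weight range (kg).
Reading the tape means mapping a measured height to its zone and to a
predicted weight inside that zone's range.

Interval convention: every zone is half-open ``[lo, hi)`` in both height and
weight, except that the last zone is closed at its upper height and weight
bound.  Printed upper edges such as "64.99" are canonicalized to an exclusive
bound of 65 so that contiguous printed ranges form a true partition.  Weight
ranges need not be contiguous (the 2007-B tape prints integer-kilogram bins
with gaps between zones); a weight falling in such a gap is unclassifiable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import OutOfRangeError, TapeValidationError

__all__ = [
    "ColorZone",
    "TapeSpec",
    "ZONE_NAMES",
    "builtin_tape",
    "builtin_tape_names",
    "zone_for_height",
    "zone_for_weight",
    "predicted_weight",
    "assign_zones",
    "read_tape",
    "write_tape",
]

#: Canonical zone order, lightest to heaviest.
ZONE_NAMES = (
    "gray",
    "pink",
    "red",
    "purple",
    "yellow",
    "white",
    "blue",
    "orange",
    "green",
)

_CONVENTION = "half_open_upper"


@dataclass(frozen=True)
class ColorZone:
    """One color zone: a height interval paired with a weight interval."""

    name: str
    height_lo: float
    height_hi: float
    weight_lo: float
    weight_hi: float

    def __post_init__(self) -> None:
        for label, lo, hi in (
            ("height", self.height_lo, self.height_hi),
            ("weight", self.weight_lo, self.weight_hi),
        ):
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise TapeValidationError(
                    f"zone {self.name!r}: {label} bounds must be finite"
                )
            if lo <= 0:
                raise TapeValidationError(
                    f"zone {self.name!r}: {label} bounds must be positive"
                )
            if not lo < hi:
                raise TapeValidationError(
                    f"zone {self.name!r}: {label}_lo must be < {label}_hi "
                    f"(got [{lo}, {hi}])"
                )


@dataclass(frozen=True)
class TapeSpec:
    """An ordered, contiguous set of color zones.

    Invariants enforced at construction:

    * zones ordered by ``height_lo`` strictly increasing;
    * zone heights contiguous under the half-open convention
      (``zone[i].height_hi == zone[i+1].height_lo``);
    * zone ``weight_hi`` weakly increasing.
    """

    tape_name: str
    zones: tuple[ColorZone, ...]
    interval_convention: str = _CONVENTION

    def __post_init__(self) -> None:
        if self.interval_convention != _CONVENTION:
            raise TapeValidationError(
                f"unsupported interval convention {self.interval_convention!r};"
                f" only {_CONVENTION!r} is defined"
            )
        if len(self.zones) == 0:
            raise TapeValidationError("a tape needs at least one zone")
        object.__setattr__(self, "zones", tuple(self.zones))
        for prev, cur in zip(self.zones, self.zones[1:]):
            if not prev.height_lo < cur.height_lo:
                raise TapeValidationError(
                    f"zones {prev.name!r}/{cur.name!r} not in increasing "
                    "height order"
                )
            if abs(prev.height_hi - cur.height_lo) > 1e-9:
                kind = "overlap" if prev.height_hi > cur.height_lo else "gap"
                raise TapeValidationError(
                    f"height {kind} between zones {prev.name!r} "
                    f"({prev.height_lo}-{prev.height_hi}) and {cur.name!r} "
                    f"({cur.height_lo}-{cur.height_hi})"
                )
            if prev.weight_hi > cur.weight_hi + 1e-9:
                raise TapeValidationError(
                    f"weight ranges not weakly increasing at zone {cur.name!r}"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def height_min(self) -> float:
        return self.zones[0].height_lo

    @property
    def height_max(self) -> float:
        return self.zones[-1].height_hi

    @property
    def weight_min(self) -> float:
        return self.zones[0].weight_lo

    @property
    def weight_max(self) -> float:
        return self.zones[-1].weight_hi

    @property
    def zone_names(self) -> tuple[str, ...]:
        return tuple(z.name for z in self.zones)

    def zone(self, name: str) -> ColorZone:
        for z in self.zones:
            if z.name == name:
                return z
        raise KeyError(name)

    def _height_edges(self) -> np.ndarray:
        return np.array(
            [z.height_lo for z in self.zones] + [self.zones[-1].height_hi]
        )


# ---------------------------------------------------------------------------
# Built-in tapes
# ---------------------------------------------------------------------------

# 2007 Edition B tape: heights 46-146.5 cm, weights 3-36 kg.  The printed
# gray/pink edge "59.4 / 59.5" canonicalizes to a shared exclusive bound of
# 59.5; the shared printed boundary 66.5 belongs to red (half-open rule).
_BROSELOW_2007B = (
    ("gray", 46.0, 59.5, 3.0, 5.0),
    ("pink", 59.5, 66.5, 6.0, 7.0),
    ("red", 66.5, 74.0, 8.0, 9.0),
    ("purple", 74.0, 84.5, 10.0, 11.0),
    ("yellow", 84.5, 97.5, 12.0, 14.0),
    ("white", 97.5, 110.0, 15.0, 18.0),
    ("blue", 110.0, 120.75, 19.0, 23.0),
    ("orange", 120.75, 133.4, 24.0, 29.0),
    ("green", 133.4, 146.5, 30.0, 36.0),
)

# Recalibrated tape (IPWET): heights 50-150 cm, weights 4-36 kg, with the
# half-kilogram classification bins used for validation ("<6.49", "6.5-8.49",
# ...); printed ".99"/".49" edges canonicalized to exclusive bounds.  The
# printed orange bin lower edge 24.4 is read as 24.5 so the bins close.
_IPWET = (
    ("gray", 50.0, 65.0, 4.0, 6.5),
    ("pink", 65.0, 74.0, 6.5, 8.5),
    ("red", 74.0, 81.0, 8.5, 10.5),
    ("purple", 81.0, 95.0, 10.5, 12.5),
    ("yellow", 95.0, 107.0, 12.5, 15.5),
    ("white", 107.0, 121.0, 15.5, 19.5),
    ("blue", 121.0, 133.0, 19.5, 24.5),
    ("orange", 133.0, 138.0, 24.5, 28.5),
    ("green", 138.0, 150.0, 28.5, 36.0),
)

_BUILTINS = {"broselow_2007b": _BROSELOW_2007B, "ipwet": _IPWET}


def builtin_tape_names() -> tuple[str, ...]:
    return tuple(sorted(_BUILTINS))


def builtin_tape(name: str) -> TapeSpec:
    """Return a fully populated built-in tape.

    Parameters
    ----------
    name
        ``"broselow_2007b"`` (the 2007 Edition B tape, heights 46-146.5 cm,
        weights 3-36 kg) or ``"ipwet"`` (the recalibrated tape, heights
        50-150 cm, weights 4-36 kg).
    """
    try:
        rows = _BUILTINS[name]
    except KeyError:
        raise TapeValidationError(
            f"unknown tape {name!r}; valid names: "
            + ", ".join(builtin_tape_names())
        ) from None
    return TapeSpec(name, tuple(ColorZone(*row) for row in rows))


# ---------------------------------------------------------------------------
# Lookups
# ---------------------------------------------------------------------------

def zone_for_height(h: float, tape: TapeSpec) -> str | None:
    """Map a height (cm) to its zone name, or ``None`` if off the tape.

    The unique zone with ``height_lo <= h < height_hi`` (last zone closed at
    the top).  Non-positive heights are an error, not merely out of range.
    """
    if not h > 0:
        raise OutOfRangeError(f"height must be positive, got {h}")
    idx = _height_zone_indices(np.asarray([h], dtype=float), tape)[0]
    return tape.zones[idx].name if idx >= 0 else None


def _height_zone_indices(h: np.ndarray, tape: TapeSpec) -> np.ndarray:
    """Vectorized height -> zone index, -1 for out of range."""
    edges = tape._height_edges()
    idx = np.searchsorted(edges, h, side="right") - 1
    idx = np.where(h == edges[-1], len(tape.zones) - 1, idx)  # top edge closed
    idx = np.where((h < edges[0]) | (h > edges[-1]), -1, idx)
    return idx.astype(int)


def zone_for_weight(w: float, tape: TapeSpec) -> str | None:
    """Map a weight (kg) to its zone name, or ``None`` if unclassifiable.

    Weight bins are half-open ``[lo, hi)`` with the last bin closed at the
    top; weights in an inter-zone gap or off the tape return ``None``.
    """
    if not w > 0:
        raise OutOfRangeError(f"weight must be positive, got {w}")
    idx = _weight_zone_indices(np.asarray([w], dtype=float), tape)[0]
    return tape.zones[idx].name if idx >= 0 else None


def _weight_zone_indices(w: np.ndarray, tape: TapeSpec) -> np.ndarray:
    idx = np.full(w.shape, -1, dtype=int)
    last = len(tape.zones) - 1
    for i, z in enumerate(tape.zones):
        if i == last:
            mask = (w >= z.weight_lo) & (w <= z.weight_hi)
        else:
            mask = (w >= z.weight_lo) & (w < z.weight_hi)
        idx[mask] = i
    return idx


def predicted_weight(
    h: float | np.ndarray,
    tape: TapeSpec,
    rounding: float | None = 0.1,
) -> float | np.ndarray:
    """Predicted weight (kg) the tape reads off at height ``h`` (cm).

    Within a zone the weight interpolates linearly between the zone's weight
    endpoints, so the prediction is continuous within zones and monotone
    non-decreasing across the whole tape.  ``rounding`` snaps the result to
    the tape's printed granularity (0.1 kg by default; pass ``None`` for the
    exact interpolant).  Heights off the tape raise :class:`OutOfRangeError`.
    """
    arr = np.asarray(h, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(~(arr > 0)):
        raise OutOfRangeError("heights must be positive")
    idx = _height_zone_indices(arr, tape)
    if np.any(idx < 0):
        bad = arr[idx < 0]
        raise OutOfRangeError(
            f"height(s) outside tape {tape.tape_name!r} range "
            f"[{tape.height_min}, {tape.height_max}]: {bad[:5].tolist()}"
        )
    hlo = np.array([z.height_lo for z in tape.zones])[idx]
    hhi = np.array([z.height_hi for z in tape.zones])[idx]
    wlo = np.array([z.weight_lo for z in tape.zones])[idx]
    whi = np.array([z.weight_hi for z in tape.zones])[idx]
    w = wlo + (whi - wlo) * (arr - hlo) / (hhi - hlo)
    if rounding is not None:
        w = np.round(w / rounding) * rounding
    return float(w[0]) if scalar else w


def assign_zones(cohort: pd.DataFrame, tape: TapeSpec) -> pd.DataFrame:
    """Per-child zone assignment table.

    Returns a frame with ``child_id``, ``height_zone`` (zone read from the
    measured height; ``None`` off-tape), ``predicted_weight`` (NaN off-tape),
    ``weight_zone`` (zone containing the measured actual weight; ``None`` if
    unclassifiable) and ``match`` (height and weight zones agree).
    """
    h = cohort["height_cm"].to_numpy(dtype=float)
    w = cohort["weight_kg"].to_numpy(dtype=float)
    hz = _height_zone_indices(h, tape)
    wz = _weight_zone_indices(w, tape)
    names = np.array(tape.zone_names + (None,), dtype=object)
    pred = np.full(h.shape, np.nan)
    ok = hz >= 0
    if ok.any():
        pred[ok] = predicted_weight(h[ok], tape)
    return pd.DataFrame(
        {
            "child_id": cohort["child_id"].to_numpy(),
            "height_zone": names[hz],
            "predicted_weight": pred,
            "weight_zone": names[wz],
            "match": (hz == wz) & (hz >= 0),
        }
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_tape(tape: TapeSpec, path: str | Path) -> None:
    """Write a tape to JSON (schema: tape_name, interval_convention, zones)."""
    doc = {
        "tape_name": tape.tape_name,
        "interval_convention": tape.interval_convention,
        "zones": [asdict(z) for z in tape.zones],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_tape(path: str | Path) -> TapeSpec:
    """Read and validate a tape from JSON.

    Invariant violations (gap, overlap, ordering) are rejected with the
    offending zone named; malformed documents raise a parse error.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TapeValidationError(f"{path}: not valid JSON ({exc})") from exc
    try:
        zones = tuple(
            ColorZone(
                name=z["name"],
                height_lo=float(z["height_lo"]),
                height_hi=float(z["height_hi"]),
                weight_lo=float(z["weight_lo"]),
                weight_hi=float(z["weight_hi"]),
            )
            for z in doc["zones"]
        )
        return TapeSpec(
            tape_name=doc["tape_name"],
            zones=zones,
            interval_convention=doc.get("interval_convention", _CONVENTION),
        )
    except (KeyError, TypeError) as exc:
        raise TapeValidationError(f"{path}: malformed tape document: {exc}")
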