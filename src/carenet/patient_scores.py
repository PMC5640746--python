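"""Patient-level outcome scoring: continuity of care (ACSS-MH), social
integration (SIX), and clinical covariate validation (HoNOS).

The Alberta Continuity of Service Scale for Mental Health (ACSS-MH) has 31
items rated 1 ("completely disagree") to 5 ("completely agree"); the total
ranges 31..155 and summarizes experienced continuity across individualized
care, system responsiveness and carer responsiveness.  The published
item-to-dimension key is not redistributable, so the subscale map shipped
here is a synthetic stand-in partition (clearly marked as such) and is
fully configurable; analyses should treat subscale membership, not the
scoring arithmetic, as the replaceable part.

The SIX index sums four objective social-integration components —
employment (0-2), accommodation (0-2), family contact (0-1), friendship
(0-1) — into a 0..6 total.  HoNOS is the clinician-rated Health of the
Nation Outcome Scale total, 0 (no impairment) to 48 (extreme impairment).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from carenet.patient_scores_defaults import DEFAULT_SUBSCALE_MAP
from carenet.survey_io import DIAGNOSES, N_ACSS_ITEMS, PatientRecord

__all__ = [
    "ContinuityScore",
    "SixScore",
    "acss_total",
    "six_total",
    "validate_honos",
    "outcome_table",
    "load_subscale_map",
    "validate_subscale_map",
    "DEFAULT_SUBSCALE_MAP",
]


@dataclass(frozen=True)
class ContinuityScore:
    """ACSS-MH total (31..155) and configured subscale sums."""

    total: int
    subscales: dict[str, int]


@dataclass(frozen=True)
class SixScore:
    """SIX social-integration components and their 0..6 total."""

    employment: int
    accommodation: int
    family: int
    friendship: int

    @property
    def total(self) -> int:
        return self.employment + self.accommodation + self.family + self.friendship


def validate_subscale_map(subscale_map: Mapping[str, Sequence[int]]) -> None:
    """Check that every subscale references valid 1-based item indices."""
    for name, items in subscale_map.items():
        for i in items:
            if not (1 <= int(i) <= N_ACSS_ITEMS):
                raise ValueError(f"subscale {name!r}: item index {i} outside 1..{N_ACSS_ITEMS}")
        if len(set(items)) != len(list(items)):
            raise ValueError(f"subscale {name!r}: duplicate item indices")


def load_subscale_map(path: str | Path) -> dict[str, list[int]]:
    """Load a subscale->item-indices map from a YAML config file."""
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    mapping = {str(k): [int(i) for i in v] for k, v in raw.items()}
    validate_subscale_map(mapping)
    return mapping


def acss_total(
    items: Sequence[int],
    subscale_map: Optional[Mapping[str, Sequence[int]]] = None,
    reverse_items: Sequence[int] = (),
) -> ContinuityScore:
    """Score the 31 continuity items.

    The total is the plain sum of the (optionally reverse-coded) items;
    subscales are sums over the configured 1-based item indices.  No items
    are reverse-scored by default.
    """
    if len(items) != N_ACSS_ITEMS:
        raise ValueError(f"expected {N_ACSS_ITEMS} items, got {len(items)}")
    scored: list[int] = []
    reverse = set(int(i) for i in reverse_items)
    for i, v in enumerate(items, start=1):
        v = int(v)
        if not (1 <= v <= 5):
            raise ValueError(f"item {i} value {v} outside 1..5")
        scored.append(6 - v if i in reverse else v)
    if subscale_map is None:
        subscale_map = DEFAULT_SUBSCALE_MAP
    validate_subscale_map(subscale_map)
    subscales = {name: sum(scored[int(i) - 1] for i in idx) for name, idx in subscale_map.items()}
    return ContinuityScore(total=sum(scored), subscales=subscales)


def six_total(
    employment: int, accommodation: int, family: int, friendship: int
) -> SixScore:
    """Score the SIX index from its four components."""
    for name, v, hi in (
        ("employment", employment, 2),
        ("accommodation", accommodation, 2),
        ("family", family, 1),
        ("friendship", friendship, 1),
    ):
        if not (0 <= int(v) <= hi):
            raise ValueError(f"SIX component {name}={v} outside 0..{hi}")
    return SixScore(int(employment), int(accommodation), int(family), int(friendship))


def validate_honos(value: int) -> int:
    """Accept a HoNOS total iff it lies in 0..48."""
    v = int(value)
    if not (0 <= v <= 48):
        raise ValueError(f"HoNOS total {v} outside 0..48")
    return v


def outcome_table(
    patients: Sequence[PatientRecord],
    subscale_map: Optional[Mapping[str, Sequence[int]]] = None,
) -> pd.DataFrame:
    """Descriptive summary of outcomes, service use and covariates.

    One row per variable with columns ``mean`` and ``std`` (sample std);
    diagnosis categories appear as percentage rows with no std.  Only
    complete records should normally be passed (see
    :func:`carenet.survey_io.analysis_set`).
    """
    if not patients:
        raise ValueError("empty patient set")
    rows: dict[str, tuple[float, float]] = {}

    def add(name: str, values: list[float]) -> None:
        arr = np.asarray(values, dtype=float)
        rows[name] = (float(np.mean(arr)), float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0)

    totals = [acss_total(p.acss_items, subscale_map).total for p in patients]
    sixes = [
        six_total(p.six_employment, p.six_accommodation, p.six_family, p.six_friends).total
        for p in patients
    ]
    add("acss_total", totals)
    add("six_total", sixes)
    if subscale_map:
        for name in subscale_map:
            add(f"acss_{name}", [acss_total(p.acss_items, subscale_map).subscales[name] for p in patients])
    for field_name, label in (
        ("n_outpatient", "outpatient_services"),
        ("n_social", "social_services"),
        ("n_residential", "residential_services"),
    ):
        vals = [getattr(p, field_name) for p in patients if getattr(p, field_name) is not None]
        if vals:
            add(label, vals)
    add("age", [p.age for p in patients])
    add("male_pct", [100.0 if p.sex == "male" else 0.0 for p in patients])
    add("honos", [p.honos for p in patients])
    n = len(patients)
    for d in DIAGNOSES:
        pct = 100.0 * sum(1 for p in patients if p.diagnosis == d) / n
        rows[f"diagnosis_pct_{d}"] = (pct, np.nan)
    return pd.DataFrame(
        {"mean": [v[0] for v in rows.values()], "std": [v[1] for v in rows.values()]},
        index=list(rows.keys()),
    )
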