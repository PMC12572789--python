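"""Marker Likelihood Index (MLI) scoring and %TFI exposure profiles.

For each dietary-questionnaire item, up to ten matching commercial products
are scanned for markers of ultra-processing.  The MLI of a marker for an
item is the fraction of that item's products whose ingredient list contains
the marker; an item-level UPF likelihood is defined the same way with
"contains at least one marker" as the predicate.  Grams of an item carrying
a marker are portion grams times the MLI, and a participant's exposure to a
marker is expressed as a percentage of total food intake:

    %TFI(key) = 100 * (grams of food carrying key) / (total food grams),

with gram intakes averaged over a participant's completed recalls before
the ratio is formed (ratio of means).  Cumulative specific-MUP intake is
the plain sum of the specific-marker %TFI values (categories and the UPF
aggregate excluded), and may exceed 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicon import IngredientText, MupLexicon, scan_ingredients

__all__ = [
    "UPF_KEY",
    "ProductRecord",
    "ItemMli",
    "MliTable",
    "RecallRecord",
    "RecallIntake",
    "ExposureProfile",
    "resolve_portion",
    "item_marker_grams",
    "compute_mli",
    "build_mli_table",
    "recall_exposure",
    "build_profile",
    "build_profiles",
    "cumulative_intake",
]

UPF_KEY = "UPF"

#: Shipped specific-gravity defaults (g/mL) for millilitre portions.
DEFAULT_GRAVITY_TABLE: dict[str, float] = {"default": 1.0}


@dataclass(frozen=True)
class ProductRecord:
    """One researched commercial product for a questionnaire item."""

    item_id: str
    ingredients: IngredientText
    portion_g: float
    energy_kj_100g: float = 0.0

    def __post_init__(self) -> None:
        if not self.portion_g > 0:
            raise ValueError(f"portion_g must be positive, got {self.portion_g}")
        if self.energy_kj_100g < 0:
            raise ValueError("energy_kj_100g must be non-negative")


def resolve_portion(
    value: float,
    unit: str,
    *,
    item_id: str | None = None,
    gravity_table: Mapping[str, float] | None = None,
    fallback_g: float | None = None,
) -> float:
    """Resolve a raw portion (value, unit) into grams.

    Grams pass through; millilitres are converted with the item's specific
    gravity (``gravity_table[item_id]``, else the table's ``"default"``
    entry); any other unit (household measures such as "Mug/Cup") uses the
    per-item configured fallback grams standing in for packaging / standard
    portion-size lookups.
    """
    u = unit.strip().lower()
    if u == "g":
        grams = float(value)
    elif u == "ml":
        table = DEFAULT_GRAVITY_TABLE if gravity_table is None else gravity_table
        gravity = table.get(item_id if item_id is not None else "", table.get("default"))
        if gravity is None:
            raise KeyError(
                f"no specific gravity for item {item_id!r} and no default configured"
            )
        grams = float(value) * float(gravity)
    else:
        if fallback_g is None:
            raise KeyError(
                f"portion unit {unit!r} for item {item_id!r} needs a configured fallback"
            )
        grams = float(fallback_g)
    if not grams > 0:
        raise ValueError(f"resolved portion must be positive, got {grams}")
    return grams


def item_marker_grams(portion_g: float, mli: float) -> float:
    """Grams of a portion attributed to a marker: portion × MLI.

    E.g. a 50 g portion of an item with flavour MLI 0.6 contributes 30 g
    of flavoured food.
    """
    if not portion_g > 0:
        raise ValueError("portion_g must be positive")
    if not 0.0 <= mli <= 1.0:
        raise ValueError(f"mli must lie in [0, 1], got {mli}")
    return portion_g * mli


@dataclass(frozen=True)
class ItemMli:
    """Per-item marker likelihoods plus resolved portion and energy."""

    item_id: str
    mli: dict[str, float]  # exposure key (UPF, category, marker) -> fraction
    mean_portion_g: float
    mean_energy_kj_100g: float
    n_products: int


def compute_mli(
    products: Sequence[ProductRecord],
    lexicon: MupLexicon,
    max_products: int = 10,
) -> ItemMli:
    """Score one item's product set: MLI per exposure key, mean portion/energy.

    Only the first ``min(len(products), max_products)`` products enter both
    the MLI denominators and the portion/energy means, so truncated scoring
    (8 / 6 / 4 products) is an exact recount on the truncated catalogue.
    Items with fewer products than the cap use all available products.
    """
    if not products:
        raise ValueError("no products for item")
    if max_products < 1:
        raise ValueError("max_products must be >= 1")
    ids = {p.item_id for p in products}
    if len(ids) != 1:
        raise ValueError(f"products span multiple items: {sorted(ids)}")
    used = list(products)[:max_products]
    n = len(used)

    per_product = [scan_ingredients(p.ingredients, lexicon) for p in used]
    mli: dict[str, float] = {}
    mli[UPF_KEY] = sum(1 for s in per_product if s) / n
    for cat in lexicon.categories:
        members = {m.name for m in lexicon.markers_in(cat)}
        mli[cat] = sum(1 for s in per_product if s & members) / n
    for marker in lexicon.marker_names:
        mli[marker] = sum(1 for s in per_product if marker in s) / n

    return ItemMli(
        item_id=used[0].item_id,
        mli=mli,
        mean_portion_g=float(np.mean([p.portion_g for p in used])),
        mean_energy_kj_100g=float(np.mean([p.energy_kj_100g for p in used])),
        n_products=n,
    )


@dataclass
class MliTable:
    """MLI, mean portion and mean energy for every questionnaire item."""

    items: dict[str, ItemMli]
    categories: tuple[str, ...]
    specific_markers: tuple[str, ...]

    @property
    def exposure_keys(self) -> tuple[str, ...]:
        # markers identical to their category (e.g. flavour, fibre) share
        # its name; keep one copy
        return tuple(dict.fromkeys((UPF_KEY,) + self.categories + self.specific_markers))

    def mli(self, item_id: str, key: str) -> float:
        return self.items[item_id].mli[key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items.values():
            row = {"item_id": it.item_id, "n_products": it.n_products,
                   "mean_portion_g": it.mean_portion_g,
                   "mean_energy_kj_100g": it.mean_energy_kj_100g}
            row.update(it.mli)
            rows.append(row)
        return pd.DataFrame(rows).set_index("item_id")


def build_mli_table(
    products: pd.DataFrame,
    lexicon: MupLexicon,
    max_products: int = 10,
    *,
    gravity_table: Mapping[str, float] | None = None,
    fallback_g: Mapping[str, float] | None = None,
) -> MliTable:
    """Build the full MLI table from a products table.

    Expected columns: ``item_id``, ``ingredients_text``, ``portion_value``,
    ``portion_unit``, ``energy_kj_per_100g`` (and optionally ``product_id``
    controlling order).  Portion units are resolved per product.
    """
    required = {"item_id", "ingredients_text", "portion_value", "portion_unit",
                "energy_kj_per_100g"}
    missing = required - set(products.columns)
    if missing:
        raise ValueError(f"products table missing columns: {sorted(missing)}")
    df = products
    if "product_id" in df.columns:
        df = df.sort_values(["item_id", "product_id"], kind="stable")
    fallbacks = {} if fallback_g is None else fallback_g
    items: dict[str, ItemMli] = {}
    for item_id, grp in df.groupby("item_id", sort=True):
        recs = [
            ProductRecord(
                item_id=str(item_id),
                ingredients=IngredientText(str(r.ingredients_text) if pd.notna(r.ingredients_text) else ""),
                portion_g=resolve_portion(
                    r.portion_value,
                    str(r.portion_unit),
                    item_id=str(item_id),
                    gravity_table=gravity_table,
                    fallback_g=fallbacks.get(str(item_id)),
                ),
                energy_kj_100g=float(r.energy_kj_per_100g),
            )
            for r in grp.itertuples()
        ]
        items[str(item_id)] = compute_mli(recs, lexicon, max_products=max_products)
    return MliTable(
        items=items,
        categories=tuple(lexicon.categories),
        specific_markers=tuple(lexicon.marker_names),
    )


@dataclass(frozen=True)
class RecallRecord:
    """One completed 24-h dietary recall."""

    participant_id: str
    recall_index: int
    recall_date: date | None
    consumed: tuple[tuple[str, float], ...]  # (item_id, n_portions)

    def __post_init__(self) -> None:
        if any(n <= 0 for _, n in self.consumed):
            raise ValueError("n_portions must be positive")


@dataclass(frozen=True)
class RecallIntake:
    """Gram and energy totals for a single recall."""

    total_food_g: float
    marker_g: dict[str, float]
    total_energy_kj: float


def recall_exposure(recall: RecallRecord, mli: MliTable) -> RecallIntake:
    """Total grams, per-key marker grams and energy for one recall."""
    unknown = [i for i, _ in recall.consumed if i not in mli.items]
    if unknown:
        raise KeyError(f"recall references unknown item(s): {sorted(set(unknown))}")
    keys = mli.exposure_keys
    total_g = 0.0
    total_kj = 0.0
    marker_g = {k: 0.0 for k in keys}
    for item_id, n_portions in recall.consumed:
        it = mli.items[item_id]
        grams = n_portions * it.mean_portion_g
        total_g += grams
        total_kj += grams * it.mean_energy_kj_100g / 100.0
        for k in keys:
            marker_g[k] += grams * it.mli[k]
    return RecallIntake(total_food_g=total_g, marker_g=marker_g, total_energy_kj=total_kj)


@dataclass(frozen=True)
class ExposureProfile:
    """Per-participant exposure: %TFI per key plus daily gram/energy totals."""

    participant_id: str
    tfi_percent: dict[str, float]
    specific_markers: tuple[str, ...]
    total_food_g: float
    total_energy_kj: float
    n_recalls: int

    @property
    def cumulative_specific_mup(self) -> float:
        return cumulative_intake(self)


def build_profile(
    recalls: Sequence[RecallRecord],
    mli: MliTable,
    mode: str = "mean_over_recalls",
) -> ExposureProfile:
    """Aggregate a participant's recalls into one exposure profile.

    Gram intakes are averaged across recalls first and the %TFI ratio is
    formed from the means; ``mode="first_recall"`` instead uses only the
    recall with the lowest index (the one completed closest to baseline).
    """
    if not recalls:
        raise ValueError("at least one recall is required")
    if mode not in ("mean_over_recalls", "first_recall"):
        raise ValueError(f"unknown mode {mode!r}")
    use = list(recalls)
    if mode == "first_recall":
        use = [min(use, key=lambda r: r.recall_index)]
    intakes = [recall_exposure(r, mli) for r in use]
    mean_total = float(np.mean([i.total_food_g for i in intakes]))
    if mean_total <= 0:
        raise ValueError("zero total intake")
    mean_energy = float(np.mean([i.total_energy_kj for i in intakes]))
    tfi = {
        k: 100.0 * float(np.mean([i.marker_g[k] for i in intakes])) / mean_total
        for k in mli.exposure_keys
    }
    return ExposureProfile(
        participant_id=use[0].participant_id,
        tfi_percent=tfi,
        specific_markers=mli.specific_markers,
        total_food_g=mean_total,
        total_energy_kj=mean_energy,
        n_recalls=len(use),
    )


def cumulative_intake(profile: ExposureProfile) -> float:
    """Cumulative specific-MUP intake: the sum of specific-marker %TFI values.

    Category aggregates and the UPF key are excluded; e.g. %TFI of 3 for
    flavour, 2 for acesulfame and 5 for emulsifier gives 10.
    """
    return float(sum(profile.tfi_percent[m] for m in profile.specific_markers))


def _recall_records_from_frame(recalls: pd.DataFrame) -> list[RecallRecord]:
    required = {"participant_id", "recall_index", "item_id", "n_portions"}
    missing = required - set(recalls.columns)
    if missing:
        raise ValueError(f"recalls table missing columns: {sorted(missing)}")
    out: list[RecallRecord] = []
    for (pid, ridx), grp in recalls.groupby(["participant_id", "recall_index"], sort=True):
        rdate = None
        if "recall_date" in grp.columns:
            first = grp["recall_date"].iloc[0]
            if pd.notna(first):
                rdate = pd.Timestamp(first).date()
        out.append(
            RecallRecord(
                participant_id=str(pid),
                recall_index=int(ridx),
                recall_date=rdate,
                consumed=tuple(
                    (str(r.item_id), float(r.n_portions)) for r in grp.itertuples()
                ),
            )
        )
    return out


def build_profiles(
    recalls: pd.DataFrame,
    mli: MliTable,
    mode: str = "mean_over_recalls",
) -> pd.DataFrame:
    """Exposure profiles for every participant in a recalls table.

    Returns one row per participant with %TFI columns for every exposure
    key, the cumulative specific-MUP column, and daily gram/energy totals.
    """
    records = _recall_records_from_frame(recalls)
    by_pid: dict[str, list[RecallRecord]] = {}
    for rec in records:
        by_pid.setdefault(rec.participant_id, []).append(rec)
    rows = []
    for pid in sorted(by_pid):
        prof = build_profile(by_pid[pid], mli, mode=mode)
        row: dict[str, object] = {"participant_id": pid}
        row.update(prof.tfi_percent)
        row["cumulative_specific_mup"] = prof.cumulative_specific_mup
        row["total_food_g"] = prof.total_food_g
        row["total_energy_kj"] = prof.total_energy_kj
        row["n_recalls"] = prof.n_recalls
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")
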