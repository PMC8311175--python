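"""Preexisting-asymmetry normalization and the average-rein combination.

Horses differ in which side their habitual ("preexisting") movement
asymmetry points to.  To pool them, each of the 11 asymmetry parameters is
normalized per horse in two steps, each parameter handled independently:

1. **Sign normalization** — if the mean of a horse's straight-line values
   for a parameter is negative, *all* of that horse's values for the
   parameter (straight and lunge alike) are inverted.  Positive values then
   mean "same direction as the preexisting asymmetry", negative values mean
   the horse has switched sides in that assessment.
2. **Rein relabeling** — the left/right rein labels are replaced by
   inside/outside relative to the preexisting side: for a left-sided horse
   (positive straight-line mean under the left-minus-right convention) the
   left rein is the inside rein, and vice versa.

Finally, for every horse x surface x speed cell in which both reins were
measured, the arithmetic mean of the normalized inside- and outside-rein
values is emitted as the **average-rein** record; cells with a missing rein
produce no average row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import PARAMETERS

logger = logging.getLogger(__name__)

HEAD_PARAMETERS = ("HDmin", "HDmax", "HDup")
PELVIC_PARAMETERS = ("PDmin", "PDmax", "PDup", "HHD", "RD")

DEFAULT_HEAD_THRESHOLD = 6.0  # mm
DEFAULT_PELVIS_THRESHOLD = 3.0  # mm

KEY_COLUMNS = ["horse", "surface", "speed", "direction"]


@dataclass
class NormalizedDataset:
    """Normalized study data plus the per-horse normalization bookkeeping.

    ``records`` is tidy/long: one row per horse x surface x speed x rein x
    parameter with the normalized ``value`` and the relabeled ``direction``
    (straight / inside / outside / average).  ``signs`` and ``side_labels``
    are horse x parameter frames of the applied inversion (+1/-1) and the
    preexisting side ('left'/'right').
    """

    records: pd.DataFrame
    signs: pd.DataFrame
    side_labels: pd.DataFrame
    n_unmatched: int = 0


def preexisting_sign(straight_values) -> int:
    """Sign (+1/-1) of the preexisting asymmetry from straight-line values.

    The categorization uses the mean across all available straight-line
    measurements.  An exactly zero mean — not covered by the normalization
    rule — maps to +1 (no inversion) with a warning.
    """
    values = np.asarray(list(straight_values), dtype=float)
    if values.size == 0:
        raise ValueError("no straight-line measurement: horse must be excluded")
    mean = values.mean()
    if mean == 0.0:
        warnings.warn(
            "exactly zero straight-line mean; treating as positive (no inversion)",
            stacklevel=2,
        )
        return 1
    return 1 if mean > 0 else -1


def _check_wide(records: pd.DataFrame) -> None:
    missing = [c for c in KEY_COLUMNS + list(PARAMETERS) if c not in records.columns]
    if missing:
        raise ValueError(f"condition table is missing columns: {', '.join(missing)}")


def compute_signs(records: pd.DataFrame) -> pd.DataFrame:
    """Per-horse, per-parameter inversion signs from the straight-line rows.

    Horses without any straight-line assessment violate the inclusion rule
    (at least one straight and one lunge assessment) and raise.
    """
    _check_wide(records)
    straight = records[records["direction"] == "straight"]
    missing = sorted(set(records["horse"]) - set(straight["horse"]))
    if missing:
        raise ValueError(
            "no straight-line assessment for horse(s) "
            f"{', '.join(missing)}: excluded by the inclusion rule"
        )
    signs = {
        horse: {p: preexisting_sign(group[p]) for p in PARAMETERS}
        for horse, group in straight.groupby("horse")
    }
    return pd.DataFrame.from_dict(signs, orient="index")[list(PARAMETERS)]


def normalize_signs(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Invert each horse's parameters with negative preexisting asymmetry.

    Returns the normalized wide table and the horse x parameter sign frame.
    Idempotent: after one application every straight-line mean is >= 0, so a
    second application is the identity.
    """
    signs = compute_signs(records)
    out = records.copy()
    factors = signs.loc[out["horse"]].to_numpy(dtype=float)
    out[list(PARAMETERS)] = out[list(PARAMETERS)].to_numpy(dtype=float) * factors
    return out, signs


def side_labels_from_signs(signs: pd.DataFrame) -> pd.DataFrame:
    """'left'/'right' preexisting side per horse x parameter.

    Under the left-minus-right sign convention, a positive straight-line
    mean (no inversion, sign +1) marks a left-sided preexisting asymmetry.
    """
    return signs.replace({1: "left", -1: "right"})


def to_long(records: pd.DataFrame, value_columns=PARAMETERS) -> pd.DataFrame:
    """Wide condition table -> tidy long table (one row per parameter)."""
    _check_wide(records)
    long = records.melt(
        id_vars=KEY_COLUMNS,
        value_vars=list(value_columns),
        var_name="parameter",
        value_name="value",
    )
    return long.rename(columns={"direction": "rein"})


def assign_inside_outside(long: pd.DataFrame, side_labels: pd.DataFrame) -> pd.DataFrame:
    """Relabel left/right rein as inside/outside per horse and parameter.

    The inside rein is the rein on the horse's preexisting-asymmetry side:
    left rein is 'inside' for a left-sided horse and 'outside' for a
    right-sided one.  Straight rows keep the 'straight' label.  The side
    label may differ between parameters of the same horse, so relabeling is
    done on the long table.
    """
    out = long.copy()
    try:
        sides = side_labels.stack().rename("side_label")
        sides.index = sides.index.set_names(["horse", "parameter"])
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError("invalid side_labels frame") from exc
    keyed = out.set_index(["horse", "parameter"])
    joined = keyed.join(sides, how="left")
    if joined["side_label"].isna().any():
        bad = joined[joined["side_label"].isna()].index.unique()[:5]
        raise ValueError(f"missing side label for horse/parameter: {list(bad)}")
    joined = joined.reset_index()
    rein = joined["rein"]
    joined["direction"] = np.where(
        rein == "straight",
        "straight",
        np.where(rein == joined["side_label"], "inside", "outside"),
    )
    return joined


def average_rein(long: pd.DataFrame) -> pd.DataFrame:
    """Average-rein rows: mean of inside and outside per exercise condition.

    Only horse x surface x speed x parameter cells with *both* an inside and
    an outside measurement contribute; unmatched cells are silently excluded
    (their count is logged and stored in ``result.attrs['n_unmatched']``).
    """
    lunge = long[long["direction"].isin(["inside", "outside"])]
    grouped = lunge.groupby(["horse", "surface", "speed", "parameter"])["value"]
    counts = lunge.groupby(["horse", "surface", "speed", "parameter"])["direction"].nunique()
    complete = counts[counts == 2].index
    n_unmatched = int((counts != 2).sum())
    if n_unmatched:
        logger.info("average_rein: %d unmatched rein conditions excluded", n_unmatched)
    avg = grouped.mean().loc[complete].reset_index()
    avg["rein"] = "average"
    avg["direction"] = "average"
    if "side_label" in long.columns:
        sides = long.drop_duplicates(["horse", "parameter"])[["horse", "parameter", "side_label"]]
        avg = avg.merge(sides, on=["horse", "parameter"], how="left")
    avg.attrs["n_unmatched"] = n_unmatched
    return avg


def normalize_dataset(records: pd.DataFrame) -> NormalizedDataset:
    """Full normalization chain: signs -> inside/outside -> average rein."""
    normalized, signs = normalize_signs(records)
    side_labels = side_labels_from_signs(signs)
    long = to_long(normalized)
    long = assign_inside_outside(long, side_labels)
    avg = average_rein(long)
    records_long = pd.concat([long, avg], ignore_index=True)
    sign_series = signs.stack()
    sign_series.index = sign_series.index.set_names(["horse", "parameter"])
    records_long["inverted"] = (
        sign_series.loc[
            pd.MultiIndex.from_frame(records_long[["horse", "parameter"]])
        ].to_numpy()
        == -1
    )
    return NormalizedDataset(
        records=records_long,
        signs=signs,
        side_labels=side_labels,
        n_unmatched=avg.attrs.get("n_unmatched", 0),
    )


def flag_preexisting(
    record,
    head_threshold: float = DEFAULT_HEAD_THRESHOLD,
    pelvis_threshold: float = DEFAULT_PELVIS_THRESHOLD,
) -> dict[str, bool]:
    """Flag head/pelvic parameters exceeding the preexisting-asymmetry cut.

    ``record`` maps parameter names to straight-line values (mm).  The
    clinical screening thresholds are strict inequalities: |value| > 6 mm
    for head parameters and > 3 mm for pelvic parameters (sacrum and tuber
    coxae derived).  Withers parameters carry no screening threshold.
    """
    flags: dict[str, bool] = {}
    for p in HEAD_PARAMETERS:
        if p in record:
            flags[p] = abs(float(record[p])) > head_threshold
    for p in PELVIC_PARAMETERS:
        if p in record:
            flags[p] = abs(float(record[p])) > pelvis_threshold
    return flags
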