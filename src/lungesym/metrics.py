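"""The 11 movement-asymmetry indices and their per-condition medians.

Index families (all signed, in mm, computed per stride):

* ``HDmin/HDmax/HDup`` — left-minus-right differences of the poll's vertical
  displacement minima, maxima and upward amplitudes;
* ``WD*`` and ``PD*`` — the same for withers and sacrum (pelvis);
* ``HHD`` (hip hike difference) — upward amplitude of the left tuber coxae
  during right-hind stance minus that of the right tuber coxae during
  left-hind stance;
* ``RD`` (range-of-motion difference) — vertical range of motion of the left
  tuber coxae minus that of the right tuber coxae.

Sign convention: every index is the left-associated minus the
right-associated quantity, so a positive value is the pattern conventionally
attributed to the left limb.  The normalization layer depends only on this
convention being applied consistently.

A condition (horse x surface x speed x direction) is summarised by the
median of each index across its strides, together with the median stride
time.
"""

from __future__ import annotations

import pandas as pd

from .synth import PARAMETERS, INDEX_LANDMARK

MIN_STRIDES_DEFAULT = 15


def stride_asymmetry(features: pd.DataFrame) -> dict[str, float]:
    """The 11 signed indices (mm) for one stride's feature set.

    ``features`` is the tidy per-stride slice produced by
    :func:`lungesym.kinematics.extract_stride_features` (columns
    ``landmark``, ``feature``, ``side``, ``value_mm``) and must be complete:
    min/max/up for both sides of each midline landmark, hike and rom for
    both tubera coxarum.  Incomplete feature sets raise — strides with
    missing features are expected to be dropped upstream, never partially
    scored.
    """
    idx = features.set_index(["landmark", "feature", "side"])["value_mm"]

    def get(landmark: str, feature: str, side: str) -> float:
        try:
            v = idx.loc[(landmark, feature, side)]
        except KeyError:
            raise ValueError(
                f"incomplete stride features: missing {feature} for {landmark} ({side})"
            ) from None
        if hasattr(v, "__len__"):
            raise ValueError(
                f"duplicated stride feature: {feature} for {landmark} ({side})"
            )
        return float(v)

    out: dict[str, float] = {}
    for family, landmark in INDEX_LANDMARK.items():
        for feature, suffix in (("min", "min"), ("max", "max"), ("up", "up")):
            out[f"{family}{suffix}"] = get(landmark, feature, "left") - get(
                landmark, feature, "right"
            )
    out["HHD"] = get("left_tuber_coxae", "hike", "left") - get(
        "right_tuber_coxae", "hike", "right"
    )
    out["RD"] = get("left_tuber_coxae", "rom", "left") - get(
        "right_tuber_coxae", "rom", "right"
    )
    return out


def stride_indices_table(features: pd.DataFrame) -> pd.DataFrame:
    """Per-stride index table; strides with incomplete features are skipped.

    Returns one row per stride with the 11 index columns; the number of
    skipped strides is available as ``result.attrs['n_skipped']``.
    """
    rows = []
    skipped = 0
    for stride, group in features.groupby("stride"):
        try:
            row = stride_asymmetry(group)
        except ValueError:
            skipped += 1
            continue
        row["stride"] = stride
        rows.append(row)
    table = pd.DataFrame(rows, columns=["stride", *PARAMETERS])
    table.attrs["n_skipped"] = skipped
    return table


def condition_summary(
    indices: pd.DataFrame,
    stride_times_ms,
    min_strides: int = MIN_STRIDES_DEFAULT,
    **labels: str,
) -> dict[str, object]:
    """Median of each index and of stride time across a condition's strides.

    ``labels`` (horse, surface, speed, direction, ...) are passed through
    into the returned record.  Raises if fewer than ``min_strides`` strides
    contribute, naming the condition.
    """
    n = len(indices)
    if n < min_strides:
        cond = ", ".join(f"{k}={v}" for k, v in labels.items()) or "condition"
        raise ValueError(
            f"{cond}: only {n} strides with complete features (minimum {min_strides})"
        )
    record: dict[str, object] = dict(labels)
    for p in PARAMETERS:
        record[p] = float(indices[p].median())
    record["stride_time"] = float(pd.Series(stride_times_ms).median())
    record["n_strides"] = int(n)
    return record
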