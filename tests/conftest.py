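import numpy as np
import pandas as pd
import pytest

from lungesym import PARAMETERS

MIDLINE = {"HD": "poll", "WD": "withers", "PD": "sacrum"}


def features_frame(
    stride=0,
    mins=(-45.0, -45.0),
    maxs=(45.0, 45.0),
    hikes=(45.0, 45.0),
    roms=(60.0, 60.0),
    per_landmark=None,
):
    """Tidy one-stride feature frame as produced by extract_stride_features.

    ``mins``/``maxs`` are (left, right) values applied to all midline
    landmarks unless ``per_landmark`` overrides them as
    {landmark: (minL, minR, maxL, maxR)}.
    """
    rows = []
    for lm in MIDLINE.values():
        minL, minR = mins
        maxL, maxR = maxs
        if per_landmark and lm in per_landmark:
            minL, minR, maxL, maxR = per_landmark[lm]
        for side, mn, mx in (("left", minL, maxL), ("right", minR, maxR)):
            rows.append((stride, lm, "min", side, mn))
            rows.append((stride, lm, "max", side, mx))
            rows.append((stride, lm, "up", side, mx - mn))
    rows.append((stride, "left_tuber_coxae", "hike", "left", hikes[0]))
    rows.append((stride, "right_tuber_coxae", "hike", "right", hikes[1]))
    rows.append((stride, "left_tuber_coxae", "rom", "left", roms[0]))
    rows.append((stride, "right_tuber_coxae", "rom", "right", roms[1]))
    return pd.DataFrame(rows, columns=["stride", "landmark", "feature", "side", "value_mm"])


def wide_record(horse, surface="hard", speed="slow", direction="straight", **values):
    """One row of the wide condition-table schema, defaulting to zeros."""
    row = {"horse": horse, "surface": surface, "speed": speed, "direction": direction}
    for p in PARAMETERS:
        row[p] = float(values.get(p, 0.0))
    row["stride_time"] = float(values.get("stride_time", 750.0))
    row["n_strides"] = int(values.get("n_strides", 30))
    return row


def wide_table(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def small_study():
    """A small simulated study table with mixed-sided horses."""
    from lungesym import StudyEffects, simulate_study

    effects = StudyEffects(n_horses=8)
    return simulate_study(effects, seed=123)
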